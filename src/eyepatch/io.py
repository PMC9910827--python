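"""On-disk formats.

EEG travels as a raw-array CSV (one column per channel, one row per
sample) with a JSON sidecar holding ``sample_rate``, ``channel_labels``,
``condition`` and optional ``trial_boundaries``. EDF recordings can be
read through mne when it is installed (``pip install eyepatch[edf]``).
Behavioral tables use plain tidy CSVs:

- phase trials: subject, condition, timepoint, configuration,
  reported_phase_deg
- rivalry intervals: subject, condition, timepoint, configuration,
  percept, duration_s
- constant stimuli: subject, condition, eye, timepoint, level,
  n_trials, n_correct
- cohort metrics: subject, condition, timepoint, metric, value
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binocular import PhaseSession, RivalryRecord
from .errors import DataError
from .spectral import EEGRecording

__all__ = [
    "save_eeg_csv",
    "load_eeg_csv",
    "read_edf",
    "phase_session_to_frame",
    "frame_to_phase_session",
    "rivalry_to_frame",
    "frame_to_rivalry",
]


def save_eeg_csv(rec: EEGRecording, csv_path: str | Path) -> Path:
    """Write a recording as CSV plus a ``.json`` sidecar; returns the sidecar path."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_labels)
    df.to_csv(csv_path, index=False, float_format="%.6f")
    sidecar = csv_path.with_suffix(".json")
    meta = {
        "sample_rate": rec.sample_rate,
        "channel_labels": rec.channel_labels,
        "condition": rec.condition,
        "trial_boundaries": rec.trial_boundaries,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def load_eeg_csv(csv_path: str | Path,
                 sidecar: str | Path | None = None) -> EEGRecording:
    """Read a CSV + JSON-sidecar recording written by :func:`save_eeg_csv`."""
    csv_path = Path(csv_path)
    sidecar = Path(sidecar) if sidecar else csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise DataError(f"sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(csv_path)
    boundaries = meta.get("trial_boundaries")
    return EEGRecording(
        samples=df.to_numpy().T,
        sample_rate=float(meta["sample_rate"]),
        channel_labels=list(meta.get("channel_labels", df.columns)),
        condition=meta.get("condition", "PE_open_rest"),
        trial_boundaries=[tuple(b) for b in boundaries] if boundaries else None,
    )


def read_edf(path: str | Path, condition: str = "PE_open_rest",
             trial_boundaries=None) -> EEGRecording:
    """Read an EDF recording into an :class:`EEGRecording` (requires mne).

    Channel values are converted from volts (mne's unit) to microvolts.
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError(
            "reading EDF requires mne; install with 'pip install eyepatch[edf]'"
        ) from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(
        samples=raw.get_data() * 1e6,
        sample_rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        condition=condition,
        trial_boundaries=trial_boundaries,
    )


def phase_session_to_frame(session: PhaseSession, subject: str = "S01",
                           condition: str = "PE_open",
                           timepoint: str = "baseline") -> pd.DataFrame:
    return pd.DataFrame({
        "subject": subject,
        "condition": condition,
        "timepoint": timepoint,
        "configuration": session.configurations,
        "reported_phase_deg": session.reported_phase,
    })


def frame_to_phase_session(frame: pd.DataFrame,
                           stimulus_phase: float = 22.5) -> PhaseSession:
    return PhaseSession(
        configurations=frame["configuration"].to_numpy(),
        reported_phase=frame["reported_phase_deg"].to_numpy(),
        stimulus_phase=stimulus_phase,
    )


def rivalry_to_frame(rec: RivalryRecord, subject: str = "S01",
                     condition: str = "PE_open",
                     timepoint: str = "baseline") -> pd.DataFrame:
    return pd.DataFrame({
        "subject": subject,
        "condition": condition,
        "timepoint": timepoint,
        "configuration": rec.configuration,
        "percept": rec.percepts,
        "duration_s": rec.durations,
    })


def frame_to_rivalry(frame: pd.DataFrame,
                     block_duration: float | None = None) -> RivalryRecord:
    durations = frame["duration_s"].to_numpy(dtype=float)
    config = int(frame["configuration"].iloc[0])
    if block_duration is None:
        block_duration = float(np.ceil(durations.sum()))
    return RivalryRecord(
        percepts=list(frame["percept"]),
        durations=durations,
        configuration=config,
        block_duration=block_duration,
    )
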