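"""Ocular-dominance indices from the two binocular tasks.

Binocular phase combination: gratings with equal and opposite phase
shifts (±22.5°) are shown dichoptically in two configurations (the sign
assignment to the eyes is swapped between configurations, cancelling any
positional bias). The perceived phase of the fused grating is summarized
as half the difference of the configuration means, so a balanced
observer reads 0° and a fully monocular (unpatched-eye-only) observer
reads +22.5°. A strengthening patched eye drives the index negative.

Binocular rivalry: orthogonal gratings are shown dichoptically; the eye
dominance ratio is the total time the unpatched eye's percept dominates
divided by the total time the patched eye's dominates, pooled across
the two 90 s sub-block configurations by summing durations before
dividing. Mixed percepts are excluded from both totals.

Change metrics subtract the pre-deprivation baseline per post-patching
timepoint; the cumulative change averages the first four post
timepoints (0', 3', 6', 9').
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import DataError, ParameterError

__all__ = [
    "PhaseSession",
    "RivalryRecord",
    "DominanceTimeline",
    "perceived_phase",
    "phase_change",
    "dominance_ratio",
    "ratio_change",
    "cumulative_change",
]

PERCEPTS = ("UPE", "PE", "mixed")


@dataclass
class PhaseSession:
    """Trial-level phase-combination reports.

    ``configurations`` holds 1 or 2 per trial (which eye carried the
    +22.5° grating); ``reported_phase`` the adjusted/reported perceived
    phase in degrees.
    """

    configurations: np.ndarray
    reported_phase: np.ndarray
    stimulus_phase: float = 22.5

    def __post_init__(self) -> None:
        self.configurations = np.asarray(self.configurations, dtype=int)
        self.reported_phase = np.asarray(self.reported_phase, dtype=float)
        if self.configurations.shape != self.reported_phase.shape:
            raise ParameterError("configuration/report length mismatch")
        if not np.isin(self.configurations, (1, 2)).all():
            raise ParameterError("configurations must be 1 or 2")
        if not np.isfinite(self.reported_phase).all():
            raise ParameterError("reported phases must be finite")


@dataclass
class RivalryRecord:
    """Ordered percept intervals from one rivalry sub-block."""

    percepts: list[str]
    durations: np.ndarray
    configuration: int = 1
    block_duration: float = 90.0

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if len(self.percepts) != self.durations.size:
            raise ParameterError("percept/duration length mismatch")
        if any(p not in PERCEPTS for p in self.percepts):
            raise ParameterError(f"percepts must be in {PERCEPTS}")
        if (self.durations <= 0).any():
            raise ParameterError("durations must be positive")
        if self.durations.sum() > self.block_duration + 1e-9:
            raise ParameterError("intervals exceed block duration")

    def total(self, percept: str) -> float:
        """Total seconds spent in ``percept``."""
        mask = np.array([p == percept for p in self.percepts])
        return float(self.durations[mask].sum()) if mask.any() else 0.0


@dataclass
class DominanceTimeline:
    """One metric's trajectory: baseline plus post-patching timepoints.

    ``post`` maps minutes after patch removal to metric values. Any
    subset of post timepoints is allowed (the monocular contrast
    experiment used {0, 30}; the binocular experiments {0, 3, 6, 9,
    30}), but the baseline must be present.
    """

    metric: str
    condition: str
    baseline: float
    post: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.baseline):
            raise DataError("baseline value missing or non-finite")
        self.post = {float(t): float(v) for t, v in sorted(self.post.items())}


def perceived_phase(session: PhaseSession) -> float:
    """Binocular perceived phase: half-difference of configuration means.

    ``(mean reported phase in configuration 1 − mean in configuration
    2) / 2``. The halving undoes the sign flip between configurations,
    so the index equals the true combined phase and is bounded by the
    ±22.5° monocular limits; any constant positional bias common to
    both configurations cancels exactly.
    """
    c1 = session.reported_phase[session.configurations == 1]
    c2 = session.reported_phase[session.configurations == 2]
    if c1.size == 0 or c2.size == 0:
        raise DataError("both configurations must be present")
    return float((c1.mean() - c2.mean()) / 2.0)


def phase_change(timeline: DominanceTimeline) -> dict[float, float]:
    """Per-timepoint perceived-phase change from baseline (degrees)."""
    return {t: v - timeline.baseline for t, v in timeline.post.items()}


def dominance_ratio(records: Iterable[RivalryRecord]) -> float:
    """Eye dominance ratio: UPE dominant time / PE dominant time.

    Durations are pooled (summed) across the supplied sub-blocks —
    normally the two stimulus configurations — before dividing. Mixed
    percepts count toward neither eye.
    """
    records = list(records)
    if not records:
        raise DataError("no rivalry records supplied")
    upe = sum(r.total("UPE") for r in records)
    pe = sum(r.total("PE") for r in records)
    if pe <= 0:
        raise DataError("patched eye never dominant; ratio undefined")
    return upe / pe


def ratio_change(timeline: DominanceTimeline) -> dict[float, float]:
    """Per-timepoint dominance-ratio change from baseline."""
    return {t: v - timeline.baseline for t, v in timeline.post.items()}


def cumulative_change(
    timeline: DominanceTimeline,
    points: Iterable[float] = (0.0, 3.0, 6.0, 9.0),
) -> float:
    """Mean change from baseline over the early post timepoints.

    The per-subject summary used to compare the two patching
    conditions: the arithmetic mean of the change at 0', 3', 6' and 9'.
    """
    points = [float(t) for t in points]
    missing = [t for t in points if t not in timeline.post]
    if missing:
        raise DataError(f"timepoints {missing} missing from timeline")
    return float(
        np.mean([timeline.post[t] - timeline.baseline for t in points])
    )


def combined_phase(weight_upe: float, weight_pe: float,
                   stimulus_phase: float = 22.5) -> float:
    """Closed-form fused phase of a gain-weighted binocular observer.

    For gratings at ±``stimulus_phase`` with interocular contrast gains
    ``weight_upe`` (eye seeing +phase in configuration 1) and
    ``weight_pe``, the linear-sum percept has phase

        arctan(((w_u − w_p) / (w_u + w_p)) · tan(stimulus_phase))

    in degrees. Equal gains give 0°; a single active eye gives the full
    ±``stimulus_phase``.
    """
    if weight_upe < 0 or weight_pe < 0 or weight_upe + weight_pe == 0:
        raise ParameterError("weights must be non-negative, not both zero")
    g = (weight_upe - weight_pe) / (weight_upe + weight_pe)
    return float(np.degrees(np.arctan(g * np.tan(np.radians(stimulus_phase)))))


def timeline_from_table(
    values: Mapping[str, float] | Mapping[float, float],
    metric: str,
    condition: str,
    baseline_key="baseline",
) -> DominanceTimeline:
    """Build a timeline from a {timepoint: value} mapping.

    ``values`` maps the baseline key plus minute offsets (numbers or
    numeric strings) to metric values.
    """
    if baseline_key not in values:
        raise DataError("baseline value required")
    post = {
        float(k): float(v) for k, v in values.items() if k != baseline_key
    }
    return DominanceTimeline(
        metric=metric,
        condition=condition,
        baseline=float(values[baseline_key]),
        post=post,
    )
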