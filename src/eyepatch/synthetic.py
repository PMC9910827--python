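"""Seeded synthetic-data generators for every stage of the pipeline.

These generators emulate the statistical structure of a short-term
monocular-deprivation study so the full analysis chain can be exercised
without any recorded data:

- resting/SSVEP EEG: 1/f^k Gaussian background plus a band-limited
  alpha component (8-13 Hz) and, for SSVEP sessions, a deterministic
  15 Hz sinusoid (the second harmonic of 7.5 Hz counterphase flicker);
- 2AFC constant-stimuli observers obeying a Quick psychometric
  function, and adjustment-method observers with log-normal settling
  noise;
- gain-weighted binocular phase-combination observers (percept phase =
  arctan of the gain-weighted tangent of the ±22.5° stimulus phase);
- rivalry percept timelines with gamma-distributed dominance
  durations;
- whole cohorts in which deprivation produces a per-metric effect at
  patch removal that decays exponentially back to baseline across the
  post timepoints {0', 3', 6', 9', 30'}.

Every generator draws all randomness from one explicit integer seed;
fixed seed means bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binocular import PhaseSession, RivalryRecord, combined_phase
from .errors import ParameterError
from .psychometrics import AdjustmentData, ConstantStimuliData, quick_probability
from .spectral import EEGRecording

__all__ = [
    "EEGGenParams",
    "PsychoObserverParams",
    "PhaseObserverParams",
    "RivalryGenParams",
    "CohortDesign",
    "gen_eeg",
    "gen_ssvep_recording",
    "gen_constant_stimuli",
    "gen_adjustment",
    "gen_phase_session",
    "gen_rivalry",
    "gen_cohort",
]


@dataclass
class EEGGenParams:
    """EEG generator settings.

    Defaults describe a realistic occipital resting recording: 1000 Hz
    sampling, a 10 Hz alpha component of 10 microvolt sinusoid-
    equivalent amplitude with 1 Hz linewidth, clearly above a 1/f
    background of 15 microvolts broadband RMS.
    """

    sample_rate: float = 1000.0
    duration: float = 300.0
    n_channels: int = 4
    alpha_freq: float = 10.0
    alpha_amp: float = 10.0
    alpha_bandwidth: float = 1.0
    noise_exponent: float = 1.0
    noise_scale: float = 15.0
    ssvep_freq: float = 15.0
    ssvep_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0 or self.n_channels < 1:
            raise ParameterError("duration, sample_rate, n_channels invalid")
        if self.sample_rate <= 2 * max(self.alpha_freq, self.ssvep_freq):
            raise ParameterError("sample rate below Nyquist for components")
        if not 8.0 <= self.alpha_freq <= 13.0:
            raise ParameterError("alpha_freq must lie in the 8-13 Hz band")
        if min(self.alpha_amp, self.noise_scale, self.ssvep_amp) < 0:
            raise ParameterError("amplitudes must be non-negative")
        if self.alpha_bandwidth < 0:
            raise ParameterError("alpha_bandwidth must be non-negative")


@dataclass
class PsychoObserverParams:
    """Ground-truth Quick-function observer for 2AFC simulation."""

    true_alpha: float = 0.01
    true_beta: float = 3.0
    guess_rate: float = 0.5
    lapse_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.true_alpha <= 1:
            raise ParameterError("true_alpha must lie in (0, 1]")
        if self.true_beta <= 0:
            raise ParameterError("true_beta must be positive")
        if not 0 <= self.guess_rate < 1:
            raise ParameterError("guess_rate must lie in [0, 1)")
        if not 0 <= self.lapse_rate <= 0.1:
            raise ParameterError("lapse_rate must lie in [0, 0.1]")


@dataclass
class PhaseObserverParams:
    """Gain-weighted binocular phase-combination observer.

    The fused percept phase is the closed form
    ``arctan(((w_upe - w_pe)/(w_upe + w_pe)) * tan(stimulus_phase))``,
    sign-flipped in configuration 2; per-trial reports add Gaussian
    noise of ``report_noise_sd`` degrees.
    """

    weight_upe: float = 1.0
    weight_pe: float = 1.0
    stimulus_phase: float = 22.5
    report_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_upe < 0 or self.weight_pe < 0:
            raise ParameterError("weights must be non-negative")
        if self.weight_upe + self.weight_pe == 0:
            raise ParameterError("at least one eye must have nonzero gain")
        if not 0 < self.stimulus_phase < 90:
            raise ParameterError("stimulus_phase must lie in (0, 90) degrees")
        if self.report_noise_sd < 0:
            raise ParameterError("report_noise_sd must be non-negative")


@dataclass
class RivalryGenParams:
    """Alternating-percept generator with gamma-distributed durations."""

    mean_dur_upe: float = 2.0
    mean_dur_pe: float = 2.0
    gamma_shape: float = 3.0
    mixed_fraction: float = 0.0
    block_duration: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mean_dur_upe, self.mean_dur_pe) <= 0:
            raise ParameterError("mean durations must be positive")
        if self.gamma_shape <= 0:
            raise ParameterError("gamma_shape must be positive")
        if not 0 <= self.mixed_fraction < 0.3:
            raise ParameterError("mixed_fraction must lie in [0, 0.3)")
        if self.block_duration <= 0:
            raise ParameterError("block_duration must be positive")


#: Per-metric deprivation effects at patch removal (0'), calibrated to
#: the group means of the study being emulated: perceived phase dropped
#: by 14.0 deg (patched eye open) / 6.14 deg (closed); the rivalry
#: dominance ratio by 0.487 / 0.414; unpatched-eye contrast sensitivity
#: by about a third (open) and a quarter (closed) of a baseline of 100.
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "perceived_phase_deg": {"PE_open": -14.0, "PE_closed": -6.143},
    "dominance_ratio": {"PE_open": -0.487, "PE_closed": -0.414},
    "contrast_sensitivity": {"PE_open": -33.1, "PE_closed": -23.3},
}

DEFAULT_BASELINES: dict[str, float] = {
    "perceived_phase_deg": -0.2,
    "dominance_ratio": 0.93,
    "contrast_sensitivity": 100.0,
}

DEFAULT_BETWEEN_SD: dict[str, float] = {
    "perceived_phase_deg": 4.0,
    "dominance_ratio": 0.15,
    "contrast_sensitivity": 20.0,
}

DEFAULT_WITHIN_SD: dict[str, float] = {
    "perceived_phase_deg": 2.0,
    "dominance_ratio": 0.08,
    "contrast_sensitivity": 6.0,
}


@dataclass
class CohortDesign:
    """Design of a synthetic deprivation cohort.

    Per-subject trajectories follow ``baseline + effect_at_0 *
    exp(-t / recovery_tau)`` plus between-subject offsets (shared
    across conditions) and per-cell measurement noise. The baseline
    timepoint carries no effect by construction.
    """

    n_subjects: int = 14
    conditions: tuple[str, ...] = ("PE_open", "PE_closed")
    timepoints: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 30.0)
    effect_at_0: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECTS.items()}
    )
    recovery_tau: float = 10.0
    between_subject_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_SD)
    )
    within_subject_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WITHIN_SD)
    )
    baselines: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("need at least two subjects")
        if self.recovery_tau <= 0:
            raise ParameterError("recovery_tau must be positive")


def _colored_noise(rng: np.random.Generator, n: int, sample_rate: float,
                   exponent: float, rms: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^k.

    Synthesized in the frequency domain; the shaping is flat below 1 Hz
    to keep the variance finite, and the output is rescaled to the
    requested RMS.
    """
    if rms == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    shape = np.ones_like(freqs)
    above = freqs >= 1.0
    shape[above] = freqs[above] ** (-exponent / 2.0)
    spec = (rng.standard_normal(freqs.size)
            + 1j * rng.standard_normal(freqs.size)) * shape
    x = np.fft.irfft(spec, n)
    std = x.std()
    return x * (rms / std) if std > 0 else x


def _alpha_component(rng: np.random.Generator, n: int, sample_rate: float,
                     freq: float, amp: float, bandwidth: float) -> np.ndarray:
    """Band-limited alpha oscillation.

    A Gaussian process with a Gaussian spectral envelope centred on
    ``freq`` with FWHM ``bandwidth``, scaled to the RMS of a sinusoid
    of amplitude ``amp`` (i.e. amp/sqrt(2)). Zero bandwidth degenerates
    to a pure sinusoid of amplitude ``amp`` with random phase.
    """
    if amp == 0:
        return np.zeros(n)
    t = np.arange(n) / sample_rate
    if bandwidth == 0:
        phase = rng.uniform(0, 2 * np.pi)
        return amp * np.sin(2 * np.pi * freq * t + phase)
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    sigma_f = bandwidth / 2.355  # FWHM -> Gaussian sigma
    env = np.exp(-((freqs - freq) ** 2) / (2 * sigma_f**2))
    spec = (rng.standard_normal(freqs.size)
            + 1j * rng.standard_normal(freqs.size)) * env
    x = np.fft.irfft(spec, n)
    std = x.std()
    target_rms = amp / np.sqrt(2.0)
    return x * (target_rms / std) if std > 0 else x


def gen_eeg(
    params: EEGGenParams,
    condition: str = "PE_open_rest",
    trial_boundaries: list[tuple[float, float]] | None = None,
) -> EEGRecording:
    """Synthesize a multichannel EEG recording.

    Each channel receives independent 1/f noise and an independent
    alpha component; the SSVEP sinusoid (if any) is phase-locked and
    identical across channels, as a stimulus-driven response would be.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sample_rate))
    t = np.arange(n) / params.sample_rate
    ssvep = params.ssvep_amp * np.sin(2 * np.pi * params.ssvep_freq * t)
    chans = np.empty((params.n_channels, n))
    for c in range(params.n_channels):
        chans[c] = (
            _colored_noise(rng, n, params.sample_rate,
                           params.noise_exponent, params.noise_scale)
            + _alpha_component(rng, n, params.sample_rate, params.alpha_freq,
                               params.alpha_amp, params.alpha_bandwidth)
            + ssvep
        )
    return EEGRecording(
        samples=chans,
        sample_rate=params.sample_rate,
        condition=condition,
        trial_boundaries=trial_boundaries,
    )


def gen_ssvep_recording(
    params: EEGGenParams,
    n_trials: int = 12,
    trial_duration: float = 10.0,
    condition: str = "PE_open_ssvep",
) -> EEGRecording:
    """SSVEP session: back-to-back trials with boundary metadata.

    The recording length is ``n_trials * trial_duration`` (overriding
    ``params.duration``) and trial boundaries are attached so
    :func:`eyepatch.spectral.epoch_ssvep` can trim each trial.
    """
    if n_trials < 1 or trial_duration <= 0:
        raise ParameterError("need n_trials >= 1 and positive trial_duration")
    p = EEGGenParams(**{**params.__dict__,
                        "duration": n_trials * trial_duration})
    boundaries = [
        (i * trial_duration, (i + 1) * trial_duration) for i in range(n_trials)
    ]
    return gen_eeg(p, condition=condition, trial_boundaries=boundaries)


def gen_constant_stimuli(
    obs: PsychoObserverParams, levels, n_per_level: int = 75
) -> ConstantStimuliData:
    """Binomial 2AFC responses at fixed contrast levels."""
    levels = np.sort(np.asarray(levels, dtype=float))
    if levels.size == 0 or (levels <= 0).any() or (levels > 1).any():
        raise ParameterError("levels must be non-empty, in (0, 1]")
    rng = np.random.default_rng(obs.seed)
    p = quick_probability(levels, obs.true_alpha, obs.true_beta,
                          obs.guess_rate, obs.lapse_rate)
    n_correct = rng.binomial(n_per_level, p)
    return ConstantStimuliData(
        levels, np.full(levels.shape, n_per_level), n_correct
    )


def gen_adjustment(
    true_threshold: float,
    jitter_sd: float = 0.1,
    n_trials: int = 40,
    seed: int = 0,
    p_incorrect: float = 0.05,
) -> AdjustmentData:
    """Adjustment-method trials: log-normal settles around the threshold.

    Settled contrasts are ``threshold * exp(N(0, jitter_sd))``
    (clipped into (0, 1]); each trial is flagged incorrect with a small
    fixed probability, emulating occasional wrong orientation reports.
    """
    if not 0 < true_threshold <= 1:
        raise ParameterError("true_threshold must lie in (0, 1]")
    if n_trials < 1:
        raise ParameterError("n_trials must be at least 1")
    if jitter_sd < 0 or not 0 <= p_incorrect < 1:
        raise ParameterError("invalid jitter_sd or p_incorrect")
    rng = np.random.default_rng(seed)
    contrasts = true_threshold * np.exp(rng.normal(0, jitter_sd, n_trials))
    contrasts = np.clip(contrasts, np.nextafter(0, 1), 1.0)
    correct = rng.random(n_trials) >= p_incorrect
    return AdjustmentData(trial_contrast=contrasts, correct=correct)


def gen_phase_session(
    obs: PhaseObserverParams, n_per_config: int = 8
) -> PhaseSession:
    """Phase-combination session with interleaved configurations.

    The true combined phase follows the gain-weighted closed form,
    positive in configuration 1 (unpatched eye carries +phase) and
    negated in configuration 2; reports add Gaussian noise.
    """
    if n_per_config < 1:
        raise ParameterError("n_per_config must be at least 1")
    rng = np.random.default_rng(obs.seed)
    true = combined_phase(obs.weight_upe, obs.weight_pe, obs.stimulus_phase)
    configs = np.repeat([1, 2], n_per_config)
    signs = np.where(configs == 1, 1.0, -1.0)
    reports = signs * true + rng.normal(0, obs.report_noise_sd, configs.size)
    order = rng.permutation(configs.size)  # interleaved presentation
    return PhaseSession(
        configurations=configs[order],
        reported_phase=reports[order],
        stimulus_phase=obs.stimulus_phase,
    )


def gen_rivalry(params: RivalryGenParams, configuration: int = 1) -> RivalryRecord:
    """Alternating rivalry percepts with gamma-distributed durations.

    Eyes alternate (starting eye randomized); each dominance duration
    is gamma(shape, mean/shape). With nonzero ``mixed_fraction`` an
    exponential mixed interval follows each dominance interval, its
    mean set so mixed percepts occupy that fraction of time in
    expectation. The final interval is truncated so the intervals tile
    ``block_duration`` exactly.
    """
    rng = np.random.default_rng(params.seed)
    means = {"UPE": params.mean_dur_upe, "PE": params.mean_dur_pe}
    mean_dom = (params.mean_dur_upe + params.mean_dur_pe) / 2.0
    mixed_mean = (
        params.mixed_fraction * mean_dom / (1.0 - params.mixed_fraction)
        if params.mixed_fraction > 0
        else 0.0
    )
    eye = "UPE" if rng.random() < 0.5 else "PE"
    percepts: list[str] = []
    durations: list[float] = []
    elapsed = 0.0
    while elapsed < params.block_duration:
        d = rng.gamma(params.gamma_shape, means[eye] / params.gamma_shape)
        d = min(d, params.block_duration - elapsed)
        if d > 0:
            percepts.append(eye)
            durations.append(d)
            elapsed += d
        if mixed_mean > 0 and elapsed < params.block_duration:
            m = min(rng.exponential(mixed_mean),
                    params.block_duration - elapsed)
            if m > 0:
                percepts.append("mixed")
                durations.append(m)
                elapsed += m
        eye = "PE" if eye == "UPE" else "UPE"
    return RivalryRecord(
        percepts=percepts,
        durations=np.asarray(durations),
        configuration=configuration,
        block_duration=params.block_duration,
    )


def _phase_weights(target_phase: float, stimulus_phase: float) -> tuple[float, float]:
    """Invert the gain-weighted phase model: weights giving ``target_phase``."""
    limit = 0.97 * stimulus_phase
    phi = float(np.clip(target_phase, -limit, limit))
    g = np.tan(np.radians(phi)) / np.tan(np.radians(stimulus_phase))
    # g = (wu - wp)/(wu + wp) with wp = 1  =>  wu = (1 + g)/(1 - g)
    return (1.0 + g) / (1.0 - g), 1.0


def gen_cohort(
    design: CohortDesign, include_raw: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Synthesize a full cohort of metric trajectories.

    Returns a tidy table (subject, condition, timepoint, metric,
    value); the ``timepoint`` column holds ``"baseline"`` or the
    post-removal minutes as a string. With ``include_raw=True`` a dict
    keyed by ``(subject, condition, timepoint, metric)`` of raw trial
    data (phase sessions, rivalry sub-block pairs, constant-stimuli
    tables) parameterized to the same latent values is returned
    alongside, so the whole pipeline — not only the statistics — can
    run on the cohort.
    """
    rng = np.random.default_rng(design.seed)
    metrics = list(design.effect_at_0)
    rows = []
    raw: dict = {}
    tp_labels = ["baseline"] + [f"{t:g}" for t in design.timepoints]
    for s in range(design.n_subjects):
        subj = f"S{s + 1:02d}"
        offsets = {
            m: rng.normal(0, design.between_subject_sd.get(m, 0.0))
            for m in metrics
        }
        for cond in design.conditions:
            for label in tp_labels:
                for m in metrics:
                    base = design.baselines.get(m, 0.0) + offsets[m]
                    if label == "baseline":
                        effect = 0.0
                    else:
                        t = float(label)
                        effect = design.effect_at_0[m].get(cond, 0.0) * np.exp(
                            -t / design.recovery_tau
                        )
                    noise = rng.normal(0, design.within_subject_sd.get(m, 0.0))
                    value = base + effect + noise
                    if m == "dominance_ratio":
                        value = max(value, 0.05)
                    elif m == "contrast_sensitivity":
                        value = max(value, 2.0)
                    rows.append((subj, cond, label, m, value))
                    if include_raw:
                        raw[(subj, cond, label, m)] = _raw_for(
                            m, value, rng
                        )
    table = pd.DataFrame(
        rows, columns=["subject", "condition", "timepoint", "metric", "value"]
    )
    return (table, raw) if include_raw else table


def _raw_for(metric: str, value: float, rng: np.random.Generator):
    """Raw trial data whose analysis reproduces ``value`` up to noise."""
    sub_seed = int(rng.integers(0, 2**31 - 1))
    if metric == "perceived_phase_deg":
        wu, wp = _phase_weights(value, 22.5)
        return gen_phase_session(
            PhaseObserverParams(weight_upe=wu, weight_pe=wp,
                                report_noise_sd=2.0, seed=sub_seed),
            n_per_config=8,
        )
    if metric == "dominance_ratio":
        ratio = max(value, 0.05)
        params = {"mean_dur_pe": 2.0, "mean_dur_upe": 2.0 * ratio,
                  "gamma_shape": 3.0, "block_duration": 90.0}
        return (
            gen_rivalry(RivalryGenParams(**params, seed=sub_seed),
                        configuration=1),
            gen_rivalry(RivalryGenParams(**params, seed=sub_seed + 1),
                        configuration=2),
        )
    if metric == "contrast_sensitivity":
        alpha = 1.0 / max(value, 2.0)
        levels = np.clip(
            alpha * np.array([0.3, 0.55, 0.8, 1.1, 1.6, 2.4]), None, 1.0
        )
        obs = PsychoObserverParams(true_alpha=min(alpha, 1.0), true_beta=3.0,
                                   seed=sub_seed)
        return gen_constant_stimuli(obs, levels, n_per_level=75)
    raise ParameterError(f"no raw generator for metric {metric!r}")
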