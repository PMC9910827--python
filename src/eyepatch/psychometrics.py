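"""Contrast-threshold psychometrics.

Threshold estimation from two-alternative forced-choice constant-stimuli
data via maximum-likelihood fitting of a Quick (Weibull-family)
psychometric function, parametric bootstrap standard errors, the
adjustment-method threshold, and the derived sensitivity change metrics
(dB change, interocular sensitivity ratio, relative open/closed effect).

The psychometric function is the natural-exponential Weibull form

    P(c) = guess + (1 - guess - lapse) * (1 - exp(-(c / alpha)^beta))

so that with a 0.5 guess rate and zero lapse the threshold parameter
``alpha`` corresponds to 81.6% correct, the convention used throughout.
(The classical base-2 Quick form would put 75% at ``alpha``; only the
natural-exponential base matches the 81.6% threshold convention.)
Contrast is represented as a fraction in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.optimize import minimize

from .errors import DataError, FitError, ParameterError

__all__ = [
    "ConstantStimuliData",
    "QuickFit",
    "AdjustmentData",
    "quick_probability",
    "fit_quick",
    "bootstrap_quick",
    "adjustment_threshold",
    "cs_change_db",
    "cs_ratio",
    "relative_effect",
]


@dataclass
class ConstantStimuliData:
    """2AFC correct/total counts at fixed contrast levels."""

    levels: np.ndarray
    n_trials: np.ndarray
    n_correct: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        self.n_correct = np.asarray(self.n_correct, dtype=int)
        if not (self.levels.shape == self.n_trials.shape == self.n_correct.shape):
            raise ParameterError("levels/n_trials/n_correct length mismatch")
        if (self.levels <= 0).any() or (self.levels > 1).any():
            raise ParameterError("contrast levels must lie in (0, 1]")
        if (np.diff(self.levels) <= 0).any():
            raise ParameterError("levels must be strictly increasing")
        if ((self.n_correct < 0) | (self.n_correct > self.n_trials)).any():
            raise ParameterError("need 0 <= n_correct <= n_trials")


@dataclass
class QuickFit:
    """Maximum-likelihood Quick-function fit.

    ``alpha`` is the contrast threshold (81.6% correct for guess 0.5,
    lapse 0), ``beta`` the slope. ``alpha_se`` / ``alpha_ci`` are
    filled in by :func:`bootstrap_quick`.
    """

    alpha: float
    beta: float
    log_likelihood: float
    guess: float = 0.5
    lapse: float = 0.0
    alpha_se: float | None = None
    alpha_ci: tuple[float, float] | None = None
    n_boot: int = 0
    seed: int | None = None


@dataclass
class AdjustmentData:
    """Per-trial settled contrasts from the adjustment method."""

    trial_contrast: np.ndarray
    correct: np.ndarray

    def __post_init__(self) -> None:
        self.trial_contrast = np.asarray(self.trial_contrast, dtype=float)
        self.correct = np.asarray(self.correct, dtype=bool)
        if self.trial_contrast.shape != self.correct.shape:
            raise ParameterError("trial_contrast/correct length mismatch")
        if ((self.trial_contrast <= 0) | (self.trial_contrast > 1)).any():
            raise ParameterError("contrasts must lie in (0, 1]")


def quick_probability(contrast, alpha, beta, guess=0.5, lapse=0.0):
    """Probability correct at ``contrast`` under the Quick function.

    Vectorized over ``contrast``. Strictly increasing in contrast;
    ``P(alpha) = guess + (1 - guess - lapse) * (1 - 1/e)`` (0.816 for
    guess 0.5, lapse 0) independent of beta.
    """
    if alpha <= 0 or beta <= 0:
        raise ParameterError("alpha and beta must be positive")
    if not 0 <= guess < 1 or not 0 <= lapse < 1 - guess:
        raise ParameterError("invalid guess/lapse rates")
    c = np.asarray(contrast, dtype=float)
    if (c < 0).any():
        raise ParameterError("contrast must be non-negative")
    p = guess + (1.0 - guess - lapse) * (1.0 - np.exp(-((c / alpha) ** beta)))
    return p if p.ndim else float(p)


# Optimizer search box (log-spaced); alpha bounds are further tied to
# the observed level range in fit_quick.
_BETA_BOUNDS = (0.5, 10.0)


def _nll(log_params, data: ConstantStimuliData, guess: float, lapse: float):
    alpha, beta = np.exp(log_params)
    p = quick_probability(data.levels, alpha, beta, guess, lapse)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -np.sum(
        data.n_correct * np.log(p)
        + (data.n_trials - data.n_correct) * np.log1p(-p)
    )


def fit_quick(
    data: ConstantStimuliData,
    guess: float = 0.5,
    lapse: float = 0.0,
    init: tuple[float, float] | None = None,
) -> QuickFit:
    """Maximum-likelihood Quick-function fit to constant-stimuli data.

    Maximizes the product-binomial likelihood over (alpha, beta) with a
    bounded multi-start quasi-Newton search in log-parameter space.
    Alpha is constrained to [min level / 10, max level * 10], beta to
    [0.5, 10].

    Raises
    ------
    FitError
        If the data are non-identifiable: responses at (or below) the
        guessing floor everywhere, or at ceiling everywhere.
    """
    if data.levels.size < 2:
        raise DataError("need at least two contrast levels to fit")
    frac = data.n_correct / data.n_trials
    if (frac <= guess).all():
        raise FitError("responses never exceed the guessing floor")
    if (frac >= 1.0 - lapse - 1e-12).all():
        raise FitError("responses at ceiling at every level")

    alpha_lo = data.levels.min() / 10.0
    alpha_hi = data.levels.max() * 10.0
    bounds = [
        (np.log(alpha_lo), np.log(alpha_hi)),
        (np.log(_BETA_BOUNDS[0]), np.log(_BETA_BOUNDS[1])),
    ]
    starts = []
    if init is not None:
        starts.append((np.log(init[0]), np.log(init[1])))
    for a0 in np.linspace(np.log(alpha_lo * 2), np.log(alpha_hi / 2), 4):
        for b0 in (1.0, 2.0, 3.5, 6.0):
            starts.append((a0, np.log(b0)))

    best = None
    for x0 in starts:
        res = minimize(
            _nll,
            x0,
            args=(data, guess, lapse),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta = np.exp(best.x)
    return QuickFit(
        alpha=float(alpha),
        beta=float(beta),
        log_likelihood=float(-best.fun),
        guess=guess,
        lapse=lapse,
    )


def bootstrap_quick(
    fit: QuickFit,
    data: ConstantStimuliData,
    n_boot: int = 500,
    seed: int | None = None,
) -> QuickFit:
    """Parametric bootstrap SE and CI for the threshold estimate.

    Simulates ``n_boot`` datasets from the fitted psychometric function
    at the observed levels and trial counts, refits each, and reports
    the standard deviation of the bootstrap threshold estimates as
    ``alpha_se`` and their 2.5/97.5 percentiles as ``alpha_ci``.
    Returns a new :class:`QuickFit` with the bootstrap fields filled.

    Warns if more than 10% of bootstrap replicates are non-identifiable
    (those replicates are dropped from the SE/CI).
    """
    rng = np.random.default_rng(seed)
    p = quick_probability(data.levels, fit.alpha, fit.beta, fit.guess, fit.lapse)
    alphas = []
    n_failed = 0
    for _ in range(n_boot):
        sim_correct = rng.binomial(data.n_trials, p)
        sim = ConstantStimuliData(data.levels, data.n_trials, sim_correct)
        try:
            refit = fit_quick(sim, guess=fit.guess, lapse=fit.lapse,
                              init=(fit.alpha, fit.beta))
        except FitError:
            n_failed += 1
            continue
        alphas.append(refit.alpha)
    if n_failed > 0.1 * n_boot:
        warnings.warn(
            f"{n_failed}/{n_boot} bootstrap refits were non-identifiable",
            stacklevel=2,
        )
    alphas = np.asarray(alphas)
    if alphas.size < 2:
        raise FitError("too few successful bootstrap refits")
    return QuickFit(
        alpha=fit.alpha,
        beta=fit.beta,
        log_likelihood=fit.log_likelihood,
        guess=fit.guess,
        lapse=fit.lapse,
        alpha_se=float(alphas.std(ddof=1)),
        alpha_ci=(
            float(np.percentile(alphas, 2.5)),
            float(np.percentile(alphas, 97.5)),
        ),
        n_boot=n_boot,
        seed=seed,
    )


def adjustment_threshold(data: AdjustmentData, method: str = "geometric") -> float:
    """Threshold from adjustment-method trials.

    Averages the settled contrast over trials on which the orientation
    judgment was correct (incorrect trials are excluded). The default
    is the geometric mean — thresholds are positive and approximately
    log-normal; ``method="arithmetic"`` is available.
    """
    kept = data.trial_contrast[data.correct]
    if kept.size == 0:
        raise DataError("no correct trials; threshold undefined")
    if method == "geometric":
        return float(np.exp(np.mean(np.log(kept))))
    if method == "arithmetic":
        return float(np.mean(kept))
    raise ParameterError(f"unknown method {method!r}")


def cs_change_db(baseline_cs: float, post_cs: float) -> float:
    """Contrast-sensitivity change in decibels: 20*log10(post/baseline)."""
    if baseline_cs <= 0 or post_cs <= 0:
        raise ParameterError("sensitivities must be positive")
    return 20.0 * np.log10(post_cs / baseline_cs)


def cs_ratio(upe_cs: float, pe_cs: float) -> float:
    """Interocular contrast-sensitivity ratio, unpatched / patched eye."""
    if pe_cs == 0:
        raise ParameterError("patched-eye sensitivity must be nonzero")
    return upe_cs / pe_cs


def relative_effect(open_value: float, closed_value: float) -> float:
    """Relative eye-closed vs eye-open effect: (closed - open) / open."""
    if open_value == 0:
        raise ParameterError("open_value must be nonzero")
    return (closed_value - open_value) / open_value


def expected_counts(
    levels, n_trials, alpha, beta, guess=0.5, lapse=0.0
) -> ConstantStimuliData:
    """Noise-free dataset with counts equal to their binomial expectation.

    Useful for self-consistency checks: fitting these data recovers
    (alpha, beta) exactly up to optimizer tolerance. Expected counts
    are real numbers; they are kept exact by scaling trials so each
    expectation is (close to) an integer only if it already is one —
    otherwise counts are rounded, which perturbs the maximizer by at
    most the rounding error.
    """
    levels = np.asarray(levels, dtype=float)
    n_trials = np.broadcast_to(np.asarray(n_trials, dtype=int), levels.shape)
    p = quick_probability(levels, alpha, beta, guess, lapse)
    return ConstantStimuliData(levels, n_trials, np.round(n_trials * p))
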