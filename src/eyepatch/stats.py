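"""Group-level inferential statistics.

The inferential layer applied to cohort metric tables: two-tailed
paired t-tests with Holm-Bonferroni correction, Wilcoxon signed-rank
(normal-approximation Z), Pearson correlation, and one-/two-way
repeated-measures ANOVA with partial eta squared and Mauchly-gated
Greenhouse-Geisser correction. Thin, validated wrappers around
scipy.stats, statsmodels and pingouin that return a uniform
:class:`TestResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ParameterError

__all__ = [
    "TestResult",
    "paired_t",
    "holm_bonferroni",
    "wilcoxon_signed_rank",
    "pearson",
    "rm_anova_oneway",
    "rm_anova_twoway",
    "posthoc_bonferroni",
]


@dataclass
class TestResult:
    """Uniform container for one statistical test result."""

    name: str
    statistic: float
    p_value: float
    df: float | None = None
    df2: float | None = None
    p_adjusted: float | None = None
    effect_size: float | None = None
    effect_size_name: str | None = None
    correction: str = "none"
    degenerate: bool = False
    extras: dict = field(default_factory=dict)


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D and equal length")
    if x.size < 2:
        raise DataError("need at least two pairs")
    return x, y


def paired_t(x, y) -> TestResult:
    """Two-tailed paired-samples t-test.

    Zero variance of the differences is flagged degenerate: identical
    vectors give t = 0, p = 1; a constant nonzero shift gives an
    infinite t with p = 0.
    """
    x, y = _paired(x, y)
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
        return TestResult("paired_t", float(t),
                          1.0 if d.mean() == 0 else 0.0,
                          df=n - 1, degenerate=True)
    res = sps.ttest_rel(x, y)
    # Cohen's d for paired data: mean difference / SD of differences
    return TestResult(
        "paired_t",
        float(res.statistic),
        float(res.pvalue),
        df=float(n - 1),
        effect_size=float(d.mean() / sd),
        effect_size_name="cohen_dz",
    )


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the original order.

    The i-th smallest p is multiplied by (k - i + 1), the running
    maximum enforced (monotone non-decreasing in the sorted order) and
    values capped at 1. Uniformly less conservative than Bonferroni
    except at the smallest p, where the two agree.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Wilcoxon signed-rank test with normal-approximation Z.

    Zero differences are dropped, ties mid-ranked, two-tailed p from
    the normal approximation with tie correction. The Z statistic is
    signed so that x tending below y gives negative Z (swapping the
    arguments flips the sign).
    """
    x, y = _paired(x, y)
    d = (x - y)[x != y]
    if d.size == 0:
        return TestResult("wilcoxon", 0.0, 1.0, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    n = d.size
    mean_w = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var_w = (n * (n + 1) * (2 * n + 1)) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    if var_w <= 0:
        return TestResult("wilcoxon", 0.0, 1.0, degenerate=True)
    z = (w_pos - mean_w) / np.sqrt(var_w)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult("wilcoxon", float(z), float(min(p, 1.0)),
                      extras={"W": float(min(w_pos, w_neg))})


def pearson(x, y) -> TestResult:
    """Pearson correlation with two-tailed t-distributed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ParameterError("need at least three paired observations")
    if x.std() == 0 or y.std() == 0:
        return TestResult("pearson", np.nan, np.nan, degenerate=True)
    res = sps.pearsonr(x, y)
    return TestResult(
        "pearson", float(res.statistic), float(res.pvalue),
        df=float(x.size - 2),
        effect_size=float(res.statistic), effect_size_name="r",
    )


def _require_complete(table: pd.DataFrame, dv: str, subject: str,
                      factors: list[str]) -> None:
    counts = table.groupby([subject, *factors], observed=True)[dv].count()
    sizes = [table[f].nunique() for f in factors]
    n_subj = table[subject].nunique()
    expected = n_subj * int(np.prod(sizes))
    if (counts != 1).any() or len(counts) != expected:
        raise DataError("design must be complete and balanced "
                        "(one value per subject x cell)")


def rm_anova_oneway(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "timepoint",
    subject: str = "subject",
    sphericity_alpha: float = 0.05,
) -> TestResult:
    """One-way repeated-measures ANOVA with partial eta squared.

    Degrees of freedom are (L-1, (L-1)(S-1)). When Mauchly's test
    rejects sphericity (p < ``sphericity_alpha``; only possible with
    three or more levels) the Greenhouse-Geisser correction is applied,
    yielding fractional degrees of freedom; epsilon is always reported
    in ``extras``.
    """
    _require_complete(table, dv, subject, [within])
    if table[within].nunique() < 2:
        raise DataError("need at least two within-subject levels")
    wide = table.pivot(index=subject, columns=within, values=dv).to_numpy()
    n_s, n_l = wide.shape
    grand = wide.mean()
    ss_effect = n_s * np.sum((wide.mean(axis=0) - grand) ** 2)
    ss_error = np.sum(
        (wide - wide.mean(axis=0) - wide.mean(axis=1, keepdims=True) + grand)
        ** 2
    )
    if ss_error < 1e-12 * max(1.0, abs(grand)):
        if ss_effect < 1e-12 * max(1.0, abs(grand)):
            # flat table: no effect, no error variance
            return TestResult("rm_anova_oneway", 0.0, 1.0,
                              df=float(n_l - 1),
                              df2=float((n_l - 1) * (n_s - 1)),
                              effect_size=0.0,
                              effect_size_name="partial_eta_sq",
                              degenerate=True)
        raise DataError("zero error variance with nonzero effect; "
                        "F statistic undefined")
    aov = pg.rm_anova(dv=dv, within=within, subject=subject, data=table,
                      correction=True, effsize="np2", detailed=False)
    row = aov.iloc[0]
    n_levels = table[within].nunique()
    has_spher = "p_spher" in aov.columns and pd.notna(row.get("p_spher"))
    violated = has_spher and row["p_spher"] < sphericity_alpha
    eps = float(row["eps"]) if "eps" in aov.columns and pd.notna(row["eps"]) else 1.0
    df1, df2 = float(row["ddof1"]), float(row["ddof2"])
    if violated and n_levels > 2:
        return TestResult(
            "rm_anova_oneway", float(row["F"]), float(row["p_GG_corr"]),
            df=df1 * eps, df2=df2 * eps,
            effect_size=float(row["np2"]), effect_size_name="partial_eta_sq",
            correction="greenhouse_geisser",
            extras={"eps": eps, "mauchly_p": float(row["p_spher"]),
                    "p_uncorrected": float(row["p_unc"])},
        )
    return TestResult(
        "rm_anova_oneway", float(row["F"]), float(row["p_unc"]),
        df=df1, df2=df2,
        effect_size=float(row["np2"]), effect_size_name="partial_eta_sq",
        extras={"eps": eps,
                "mauchly_p": float(row["p_spher"]) if has_spher else np.nan},
    )


def rm_anova_twoway(
    table: pd.DataFrame,
    dv: str = "value",
    within: tuple[str, str] = ("condition", "timepoint"),
    subject: str = "subject",
) -> dict[str, TestResult]:
    """Two-way fully-within repeated-measures ANOVA.

    Each effect (two main effects and the interaction) is tested
    against its own effect-by-subject error term; partial eta squared
    is reported per effect. Returns a dict keyed by effect name
    (factor A, factor B, "A * B"). Uncorrected degrees of freedom and
    p-values are primary; Greenhouse-Geisser p-values and epsilons are
    available in ``extras``.
    """
    factors = list(within)
    if len(factors) != 2:
        raise ParameterError("exactly two within factors required")
    _require_complete(table, dv, subject, factors)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # exactly additive tables make some error terms zero; the
        # resulting 0/0 rows are repaired below
        _warnings.simplefilter("ignore", RuntimeWarning)
        aov = pg.rm_anova(dv=dv, within=factors, subject=subject, data=table,
                          effsize="np2")
    out: dict[str, TestResult] = {}
    total_ss = float(np.abs(aov["SS"]).sum())
    for _, row in aov.iterrows():
        negligible = abs(row["SS"]) < 1e-9 * max(total_ss, 1.0)
        if negligible or not np.isfinite(row["F"]):
            if negligible:
                out[str(row["Source"])] = TestResult(
                    "rm_anova_twoway", 0.0, 1.0,
                    df=float(row["ddof1"]), df2=float(row["ddof2"]),
                    effect_size=0.0, effect_size_name="partial_eta_sq",
                    degenerate=True,
                )
                continue
            # nonzero effect over a zero error term: unbounded evidence
            out[str(row["Source"])] = TestResult(
                "rm_anova_twoway", np.inf, 0.0,
                df=float(row["ddof1"]), df2=float(row["ddof2"]),
                effect_size=1.0, effect_size_name="partial_eta_sq",
                degenerate=True,
            )
        extras = {}
        if "p_GG_corr" in aov.index.names or "p_GG_corr" in row.index:
            if pd.notna(row.get("p_GG_corr", np.nan)):
                extras["p_GG_corr"] = float(row["p_GG_corr"])
            if pd.notna(row.get("eps", np.nan)):
                extras["eps"] = float(row["eps"])
        out[str(row["Source"])] = TestResult(
            "rm_anova_twoway", float(row["F"]), float(row["p_unc"]),
            df=float(row["ddof1"]), df2=float(row["ddof2"]),
            effect_size=float(row["np2"]), effect_size_name="partial_eta_sq",
            extras=extras,
        )
    return out


def posthoc_bonferroni(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "timepoint",
    subject: str = "subject",
) -> pd.DataFrame:
    """Bonferroni-corrected pairwise paired t-tests across levels.

    Raw two-tailed p-values are multiplied by the number of pairwise
    comparisons and capped at 1.
    """
    _require_complete(table, dv, subject, [within])
    wide = table.pivot(index=subject, columns=within, values=dv)
    levels = list(wide.columns)
    rows = []
    n_comp = len(levels) * (len(levels) - 1) // 2
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            res = paired_t(wide[a].to_numpy(), wide[b].to_numpy())
            rows.append(
                (a, b, res.statistic, res.p_value,
                 min(res.p_value * n_comp, 1.0))
            )
    return pd.DataFrame(
        rows, columns=["level_a", "level_b", "t", "p_unc", "p_bonf"]
    )
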