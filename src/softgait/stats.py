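"""Paired pre/post cohort statistics.

The statistical plan for the 10 m gait cohort:

1. A Shapiro-Wilk normality gate routes each variable to a parametric or
   nonparametric comparison (the cohort variables are typically non-normal,
   so the nonparametric branch is what matters here).
2. The Wilcoxon signed-rank test compares pre vs post for each normalized
   metric. The default method is the tie-corrected normal approximation
   (appropriate at cohort sizes of a few hundred), with z and a two-sided p;
   an exact sign-flip enumeration method is available for small samples.
   Zero differences are dropped before ranking (the classical Wilcoxon
   convention; Pratt's zero-rank variant is available via ``zero_method``).
3. The paired effect size is r = |z| / sqrt(n), with n the number of pairs
   supplied (not the post-zero-removal count), matching how such tables are
   customarily reported.
4. Post/pre change ratios of step length and upward acceleration are
   correlated with Spearman's rank coefficient (average-rank ties).
5. An ordinary least-squares regression of normalized upward acceleration on
   step-length ratio, cadence and speed, with standardized betas
   (beta_j = B_j * sd(x_j) / sd(y)) and per-predictor variance inflation
   factors VIF_j = 1 / (1 - R^2_j).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import StatisticsError
from .io import paired_frames, validate_cohort

__all__ = [
    "PairedTestResult",
    "ChangeRatios",
    "RegressionResult",
    "normality_gate",
    "wilcoxon_signed_rank",
    "effect_size_r",
    "change_ratios",
    "spearman_change_correlation",
    "regress_upward_accel",
    "summarize_cohort",
]

#: Metrics compared pre vs post in the cohort summary (column name -> label).
SUMMARY_METRICS = {
    "step_length_ratio_norm": "Step length (body height ratio)",
    "steps_per_min_norm": "Step counts (per minute)",
    "upward_accel_norm": "Upward acceleration (m/s^2)",
    "speed_m_s": "Walking speed (m/s)",
}


@dataclasses.dataclass(frozen=True)
class PairedTestResult:
    """Wilcoxon signed-rank outcome for one paired metric."""

    statistic: float          # W+, sum of ranks of positive (post - pre) differences
    z_score: float            # signed; positive means post > pre
    p_value: float
    effect_size_r: float      # |z| / sqrt(n)
    n: int                    # pairs supplied
    n_used: int               # pairs after zero-difference handling
    median_pre: float
    median_post: float
    iqr_pre: tuple[float, float]
    iqr_post: tuple[float, float]
    method: str


@dataclasses.dataclass(frozen=True)
class ChangeRatios:
    """Per-participant post/pre ratios, paired by participant."""

    step_length_ratio: np.ndarray
    upward_accel: np.ndarray

    def __post_init__(self) -> None:
        sl = np.asarray(self.step_length_ratio, dtype=float)
        ua = np.asarray(self.upward_accel, dtype=float)
        object.__setattr__(self, "step_length_ratio", sl)
        object.__setattr__(self, "upward_accel", ua)
        if sl.shape != ua.shape:
            raise StatisticsError("change-ratio vectors must be paired (equal length)")
        if np.any(sl <= 0) or np.any(ua <= 0):
            raise StatisticsError("post/pre ratios must be positive")


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    """OLS fit of upward acceleration on gait predictors."""

    params: pd.Series          # B, including 'const'
    bse: pd.Series             # standard errors
    pvalues: pd.Series
    beta: pd.Series            # standardized coefficients (no const)
    vif: pd.Series             # variance inflation factors (no const)
    r_squared: float
    nobs: int


def normality_gate(values: Sequence[float], alpha: float = 0.05
                   ) -> tuple[Literal["normal", "non_normal"], float]:
    """Shapiro-Wilk gate: route to parametric vs nonparametric comparison.

    Returns ``("normal" | "non_normal", p_value)``; non-normal when
    p < alpha.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise StatisticsError(f"normality test needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        raise StatisticsError("normality test undefined for constant input")
    p = float(sps.shapiro(x).pvalue)
    return ("non_normal" if p < alpha else "normal"), p


def _signed_rank_core(diffs: np.ndarray, zero_method: str) -> tuple[float, float, float, int]:
    """Return (W+, mu, sigma, n_used) for the signed-rank statistic."""
    if zero_method == "wilcox":
        diffs = diffs[diffs != 0.0]
        n = diffs.size
        ranks = sps.rankdata(np.abs(diffs))
        w_plus = float(ranks[diffs > 0].sum())
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
    elif zero_method == "pratt":
        n_all = diffs.size
        ranks = sps.rankdata(np.abs(diffs))
        w_plus = float(ranks[diffs > 0].sum())
        n_zero = int(np.sum(diffs == 0.0))
        n = n_all
        mu = (n * (n + 1) - n_zero * (n_zero + 1)) / 4.0
        var = (n * (n + 1) * (2 * n + 1) - n_zero * (n_zero + 1) * (2 * n_zero + 1)) / 24.0
        diffs = diffs  # ranks over all; zeros contribute no sign
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    # tie correction: subtract sum(t^3 - t)/48 over groups of tied |d| (nonzero)
    nonzero_abs = np.abs(diffs[diffs != 0.0]) if zero_method == "pratt" else np.abs(diffs)
    _, counts = np.unique(nonzero_abs, return_counts=True)
    var -= np.sum(counts.astype(float) ** 3 - counts) / 48.0
    return w_plus, mu, math.sqrt(var) if var > 0 else 0.0, int((diffs != 0.0).sum())


def _exact_p(diffs: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of the 2^n sign assignments
    over the observed (average) ranks of |d|. Zero differences must already
    be removed."""
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    total = 2 ** len(ranks)
    n_le = n_ge = 0
    for signs in itertools.product((0.0, 1.0), repeat=len(ranks)):
        w = float(np.dot(signs, ranks))
        if w <= w_obs:
            n_le += 1
        if w >= w_obs:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def wilcoxon_signed_rank(pre: Sequence[float], post: Sequence[float],
                         method: Literal["approx", "exact"] = "approx",
                         zero_method: Literal["wilcox", "pratt"] = "wilcox",
                         ) -> PairedTestResult:
    """Paired Wilcoxon signed-rank test of post vs pre.

    Differences are ``post - pre``; the reported z is signed (positive when
    post exceeds pre), the p two-sided. ``method="approx"`` uses the
    tie-corrected normal approximation without continuity correction;
    ``method="exact"`` additionally replaces the p-value by full sign-flip
    enumeration (feasible up to n of ~20).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise StatisticsError("pre and post must be equal-length 1-D vectors")
    n_pairs = pre.size
    diffs = post - pre
    if np.all(diffs == 0.0):
        raise StatisticsError("all paired differences are zero; test undefined")
    w_plus, mu, sigma, n_used = _signed_rank_core(diffs, zero_method)
    if n_used < 5:
        raise StatisticsError(
            f"need >= 5 nonzero paired differences, got {n_used}")
    if sigma == 0.0:
        raise StatisticsError("zero variance of the signed-rank statistic")
    z = (w_plus - mu) / sigma
    if method == "approx":
        p = 2.0 * sps.norm.sf(abs(z))
    elif method == "exact":
        nz = diffs[diffs != 0.0]
        if nz.size > 20:
            raise StatisticsError("exact enumeration infeasible for n > 20")
        p = _exact_p(nz)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PairedTestResult(
        statistic=w_plus,
        z_score=float(z),
        p_value=float(p),
        effect_size_r=effect_size_r(z, n_pairs),
        n=n_pairs,
        n_used=n_used,
        median_pre=float(np.median(pre)),
        median_post=float(np.median(post)),
        iqr_pre=(float(np.percentile(pre, 25)), float(np.percentile(pre, 75))),
        iqr_post=(float(np.percentile(post, 25)), float(np.percentile(post, 75))),
        method=method,
    )


def effect_size_r(z: float, n: int) -> float:
    """Nonparametric paired effect size r = |z| / sqrt(n).

    Reported to 2 decimals in summary tables; full precision here.
    """
    if n < 1:
        raise StatisticsError(f"n must be >= 1, got {n}")
    return abs(z) / math.sqrt(n)


def change_ratios(cohort: pd.DataFrame) -> ChangeRatios:
    """Per-participant post/pre ratios of normalized step length and impact."""
    wide = paired_frames(cohort, ["step_length_ratio_norm", "upward_accel_norm"])
    return ChangeRatios(
        step_length_ratio=(wide["step_length_ratio_norm_post"]
                           / wide["step_length_ratio_norm_pre"]).to_numpy(),
        upward_accel=(wide["upward_accel_norm_post"]
                      / wide["upward_accel_norm_pre"]).to_numpy(),
    )


def spearman_change_correlation(ratios: ChangeRatios) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties) between the two change
    ratios; returns (rho, two-sided p)."""
    x, y = ratios.step_length_ratio, ratios.upward_accel
    if x.size < 5:
        raise StatisticsError(f"need >= 5 paired ratios, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatisticsError("rank correlation undefined for a constant vector")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


_PREDICTORS = ["step_length_ratio_norm", "steps_per_min_norm", "speed_m_s"]


def regress_upward_accel(cohort: pd.DataFrame,
                         labels: Literal["pooled", "pre", "post"] = "pooled",
                         predictors: Sequence[str] = tuple(_PREDICTORS),
                         response: str = "upward_accel_norm") -> RegressionResult:
    """OLS of normalized upward acceleration on gait predictors.

    ``labels`` selects which rows enter the fit (both labels pooled by
    default). Standardized betas and VIFs are attached; a rank-deficient
    design raises :class:`StatisticsError`.
    """
    validate_cohort(cohort, require_paired=False)
    rows = cohort if labels == "pooled" else cohort[cohort["label"] == labels]
    if len(rows) < 10:
        raise StatisticsError(f"regression needs >= 10 rows, got {len(rows)}")
    X = rows[list(predictors)].astype(float)
    y = rows[response].astype(float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise StatisticsError("rank-deficient design matrix (collinear predictors)")
    fit = sm.OLS(y, design).fit()
    sd_y = float(np.std(y, ddof=1))
    beta = pd.Series(
        {p: fit.params[p] * float(np.std(X[p], ddof=1)) / sd_y for p in predictors})
    vif = {}
    for p in predictors:
        others = [q for q in predictors if q != p]
        aux = sm.OLS(X[p], sm.add_constant(X[others], has_constant="add")).fit()
        vif[p] = 1.0 / (1.0 - aux.rsquared)
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        beta=beta,
        vif=pd.Series(vif),
        r_squared=float(fit.rsquared),
        nobs=int(fit.nobs),
    )


def summarize_cohort(cohort: pd.DataFrame,
                     metrics: dict[str, str] | None = None) -> pd.DataFrame:
    """Summary table of the paired comparisons, one row per metric.

    Columns: median (IQR) pre and post, two-sided p, signed z and effect
    size r, rounded the way such tables are printed (medians/IQR to 2
    decimals, 3 for ratios; r to 2 decimals).
    """
    metrics = metrics or SUMMARY_METRICS
    wide = paired_frames(cohort, list(metrics))
    rows = []
    for col, label in metrics.items():
        res = wilcoxon_signed_rank(wide[f"{col}_pre"], wide[f"{col}_post"])
        nd = 3 if "ratio" in col else 2
        fmt = f"{{:.{nd}f}}"

        def med_iqr(m, iqr):
            return (f"{fmt.format(m)}({fmt.format(iqr[0])}"
                    f"–{fmt.format(iqr[1])})")

        rows.append({
            "measurement": label,
            "pre": med_iqr(res.median_pre, res.iqr_pre),
            "post": med_iqr(res.median_post, res.iqr_post),
            "p_value": res.p_value,
            "z_score": round(abs(res.z_score), 3),
            "effect_size_r": round(res.effect_size_r, 2),
            "n": res.n,
        })
    return pd.DataFrame(rows)
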