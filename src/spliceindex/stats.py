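"""Reliability and association statistics used to evaluate the biomarker:
test-retest ICC, Pearson/Spearman correlations with Fisher-z intervals,
Bland-Altman agreement, OLS regression with adjusted R-squared, paired
t / one-way ANOVA with Tukey correction, and the LCA preprocessing steps
(collinearity-based indicator selection, mean-dichotomization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

__all__ = [
    "IccResult",
    "CorrelationResult",
    "BlandAltmanResult",
    "LinearModelResult",
    "icc_agreement",
    "correlate",
    "bland_altman",
    "fit_linear_model",
    "compare_groups",
    "dichotomize",
    "select_lca_indicators",
]


# ---------------------------------------------------------------------------
# reliability

@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    defined: bool


def icc_agreement(ratings) -> IccResult:
    """Single-measure, absolute-agreement, two-way ICC (McGraw-Wong
    ICC(A,1)) on an n x 2 table of paired measurements, with an F-based
    95% CI.  Absolute agreement penalizes systematic shifts, so a constant
    offset between columns yields ICC < 1.
    """
    arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("ratings must be an n x 2 table")
    arr = arr[~np.isnan(arr).any(axis=1)]
    n = arr.shape[0]
    if n < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.allclose(arr.var(), 0.0):
        return IccResult(float("nan"), float("nan"), float("nan"), n, defined=False)
    k = 2
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((arr - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else float("nan")
    # F-based CI for the absolute-agreement single-measure coefficient
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
        if np.isfinite(a) and (a * msc + b * mse) > 0:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_l = st.f.ppf(0.975, n - 1, v)
            f_u = st.f.ppf(0.975, v, n - 1)
            lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        else:  # perfect agreement: interval degenerates
            lo = hi = icc
    return IccResult(float(icc), float(lo), float(hi), n, defined=True)


# ---------------------------------------------------------------------------
# correlation

@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    method: str
    defined: bool


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a two-tailed p and 95% CI.

    Pearson CI: Fisher z, tanh(atanh r +- z* / sqrt(n - 3)).  Spearman is
    computed on mid-ranked ties; its CI uses Fisher z with Fieller's
    rank-based standard error 1.03 / sqrt(n - 3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError("need >= 4 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), float("nan"), float("nan"),
                                 n, method, defined=False)
    if method == "pearson":
        r, p = st.pearsonr(x, y)
        se = 1.0 / np.sqrt(n - 3)
    elif method == "spearman":
        r, p = st.spearmanr(x, y)
        se = 1.03 / np.sqrt(n - 3)
    else:
        raise ValueError(f"unknown method {method!r}")
    zcrit = st.norm.ppf(0.975)
    with np.errstate(divide="ignore"):
        z = np.arctanh(r)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return CorrelationResult(float(r), float(lo), float(hi), float(p), n, method, defined=True)


# ---------------------------------------------------------------------------
# agreement

@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd: float
    n: int


def bland_altman(x, y) -> BlandAltmanResult:
    """Bias (mean of y - x) and 95% limits of agreement (bias +- 1.96 SD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    d = y - x
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd, d.size)


# ---------------------------------------------------------------------------
# regression

@dataclass
class LinearModelResult:
    params: pd.Series
    r2: float
    adjusted_r2: float
    resid_normality_p: float
    n: int
    n_covariates: int
    fitted: np.ndarray
    residuals: np.ndarray


def fit_linear_model(outcome, covariate_table: pd.DataFrame) -> LinearModelResult:
    """OLS of outcome on the covariate columns (intercept added).

    Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1).  A rank-deficient
    design raises, naming the collinear columns.  Residual normality is
    reported as a Shapiro-Wilk p-value.
    """
    X = pd.DataFrame(covariate_table).astype(float)
    y = np.asarray(outcome, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        bad = []
        for col in X.columns:
            others = X.drop(columns=[col])
            if others.shape[1] == 0:
                continue
            resid = sm.OLS(X[col], sm.add_constant(others)).fit().resid
            if np.allclose(resid, 0.0, atol=1e-10):
                bad.append(str(col))
        raise ValueError(f"rank-deficient design; collinear columns: {bad or list(map(str, X.columns))}")
    fit = sm.OLS(y, design).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shapiro_p = float(st.shapiro(fit.resid).pvalue) if n >= 3 else float("nan")
    return LinearModelResult(
        params=fit.params,
        r2=float(fit.rsquared),
        adjusted_r2=float(fit.rsquared_adj),
        resid_normality_p=shapiro_p,
        n=n,
        n_covariates=p,
        fitted=np.asarray(fit.fittedvalues),
        residuals=np.asarray(fit.resid),
    )


# ---------------------------------------------------------------------------
# group comparisons

def compare_groups(values, grouping=None, design: str = "oneway_anova_tukey") -> dict:
    """Paired t test, or one-way ANOVA with Tukey's HSD correction.

    paired_t: ``values`` is a (baseline, followup) pair of equal-length
    vectors; identical vectors give t = 0, p = 1.  oneway_anova_tukey:
    ``values``/``grouping`` are flat vectors; groups with n < 2 are
    excluded with a warning (as a single-sample group is in the source
    cohort's ANOVA).
    """
    if design == "paired_t":
        a, b = (np.asarray(v, dtype=float) for v in values)
        if a.size != b.size or a.size < 2:
            raise ValueError("paired t needs >= 2 complete pairs")
        d = b - a
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d, 0.0):
                return {"design": "paired_t", "t": 0.0, "df": a.size - 1, "p": 1.0, "n": a.size}
        t, p = st.ttest_rel(b, a)
        return {"design": "paired_t", "t": float(t), "df": a.size - 1, "p": float(p), "n": a.size}

    if design == "oneway_anova_tukey":
        values = np.asarray(values, dtype=float)
        grouping = np.asarray(grouping)
        groups, arrays = [], []
        for g in pd.unique(grouping):
            arr = values[grouping == g]
            arr = arr[~np.isnan(arr)]
            if arr.size < 2:
                warnings.warn(f"group {g!r} excluded (n={arr.size} < 2)", stacklevel=2)
                continue
            groups.append(g)
            arrays.append(arr)
        if len(arrays) < 2:
            raise ValueError("need >= 2 groups with n >= 2")
        f, p = st.f_oneway(*arrays)
        hsd = st.tukey_hsd(*arrays)
        pairwise = []
        for i, j in combinations(range(len(arrays)), 2):
            pairwise.append(
                {
                    "group_a": groups[i],
                    "group_b": groups[j],
                    "mean_diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
        return {
            "design": "oneway_anova_tukey",
            "F": float(f),
            "p": float(p),
            "groups": [str(g) for g in groups],
            "pairwise": pairwise,
        }

    raise ValueError(f"unknown design {design!r}")


# ---------------------------------------------------------------------------
# LCA preprocessing

def dichotomize(values, means) -> pd.DataFrame | np.ndarray:
    """Binary indicators: 1 iff value strictly greater than the per-column
    mean (values equal to the mean code 0)."""
    if isinstance(values, pd.DataFrame):
        return (values > pd.Series(means)).astype(int)
    values = np.asarray(values, dtype=float)
    means = np.asarray(means, dtype=float)
    return (values > means).astype(int)


def select_lca_indicators(
    psi_matrix: pd.DataFrame,
    max_abs_corr: float = 0.8,
    prefer: tuple[str, ...] = (),
) -> list[str]:
    """Greedy low-collinearity subset of events for latent class analysis.

    Events are admitted in preference order (``prefer`` first, then by
    ascending mean absolute correlation) as long as every pairwise
    |correlation| with already-selected events stays within
    ``max_abs_corr``.  LCA assumes conditional independence, so strongly
    collinear indicator pairs are pruned to one representative.
    """
    if psi_matrix.shape[1] < 2:
        raise ValueError("need >= 2 events")
    corr = psi_matrix.corr().abs()
    mean_corr = corr.where(~np.eye(len(corr), dtype=bool)).mean()
    preferred = [e for e in prefer if e in psi_matrix.columns]
    rest = sorted(
        (c for c in psi_matrix.columns if c not in preferred),
        key=lambda c: (float(mean_corr[c]), str(c)),
    )
    selected: list[str] = []
    for cand in preferred + rest:
        if all(corr.loc[cand, s] <= max_abs_corr for s in selected):
            selected.append(cand)
    if len(selected) < 2:
        raise ValueError(f"no subset of >= 2 events with |corr| <= {max_abs_corr}")
    return selected
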