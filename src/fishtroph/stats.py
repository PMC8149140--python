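"""Generic statistical kernel shared by the analysis stages.

Thin, validated wrappers around scipy/numpy routines (one-way ANOVA, Tukey
HSD, OLS) plus the two ecology staples — Shannon-Wiener diversity and
Bray-Curtis dissimilarity — and a Pillai-trace MANOVA for bivariate
responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "shannon_diversity", "bray_curtis", "anova_oneway", "tukey_hsd",
    "manova_pillai", "linear_regression", "AnovaResult", "RegressionResult",
    "ManovaResult",
]


def shannon_diversity(abundances, base: float | None = None) -> float:
    """Shannon-Wiener diversity H = -sum p_i log p_i over positive
    proportions.

    Natural log by default (the convention of the ecology packages this
    mirrors); pass ``base`` to change it.  H is invariant to rescaling the
    abundance vector.
    """
    a = np.asarray(abundances, dtype=float)
    if a.ndim != 1:
        raise ValueError("abundances must be a 1-D vector")
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("at least one abundance must be positive")
    p = a[a > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return max(h, 0.0)


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum(min(a,b)) / (sum a + sum b).

    0 for identical compositions, 1 for disjoint ones.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("abundances must be non-negative")
    denom = a.sum() + b.sum()
    if denom <= 0:
        raise ValueError("both vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / denom)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    return gs


def anova_oneway(groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA."""
    gs = _check_groups(groups)
    res = sps.f_oneway(*gs)
    n = sum(g.size for g in gs)
    return AnovaResult(F=float(res.statistic), df1=len(gs) - 1,
                       df2=n - len(gs), p=float(res.pvalue))


def tukey_hsd(groups):
    """All-pairs Tukey HSD adjusted p-values.

    Returns a dict mapping ``(i, j)`` group-index pairs (i < j) to the
    studentized-range adjusted p-value.
    """
    gs = _check_groups(groups)
    res = sps.tukey_hsd(*gs)
    out = {}
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            out[(i, j)] = float(res.pvalue[i, j])
    return out


@dataclass(frozen=True)
class ManovaResult:
    pillai: float
    F: float
    df1: int
    df2: int
    p: float


def manova_pillai(responses, groups) -> ManovaResult:
    """One-way MANOVA, Pillai's trace V = tr(H (H + E)^-1).

    ``responses`` is an n x p matrix (p >= 1), ``groups`` a length-n label
    vector.  Uses Pillai's F approximation with s = min(p, k-1),
    m = (|p - k + 1| - 1)/2, n* = (N - k - p - 1)/2.
    """
    y = np.asarray(responses, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    labels = np.asarray(groups)
    if labels.shape[0] != y.shape[0]:
        raise ValueError("responses and groups must have equal length")
    uniq = np.unique(labels)
    k = uniq.size
    n, p = y.shape
    if k < 2:
        raise ValueError("need at least 2 groups")
    if n <= k + p:
        raise ValueError("too few observations for the group count")
    grand = y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for g in uniq:
        yg = y[labels == g]
        diff = yg.mean(axis=0) - grand
        H += yg.shape[0] * np.outer(diff, diff)
        resid = yg - yg.mean(axis=0)
        E += resid.T @ resid
    T = H + E
    if np.linalg.matrix_rank(E) < p:
        raise np.linalg.LinAlgError(
            "within-group cross-product matrix is singular; "
            "collect more data or use fewer groups")
    V = float(np.trace(H @ np.linalg.inv(T)))
    s = min(p, k - 1)
    m = (abs(p - k + 1) - 1) / 2.0
    nn = (n - k - p - 1) / 2.0
    df1 = int(round(s * (2 * m + s + 1)))
    df2 = int(round(s * (2 * nn + s + 1)))
    F = (V / (s - V)) * (df2 / df1) if s - V > 0 else np.inf
    pval = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return ManovaResult(pillai=V, F=float(F), df1=df1, df2=df2, p=pval)


@dataclass(frozen=True)
class RegressionResult:
    intercept: float
    slope: float
    se_slope: float
    r_squared: float
    residuals: np.ndarray
    p_slope: float
    n: int


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with slope inference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    fitted = res.intercept + res.slope * x
    return RegressionResult(
        intercept=float(res.intercept), slope=float(res.slope),
        se_slope=float(res.stderr),
        r_squared=float(res.rvalue) ** 2,
        residuals=y - fitted,
        p_slope=float(res.pvalue), n=x.size)
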