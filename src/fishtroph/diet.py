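"""Gut-content analysis by the relative-fullness method.

Covers the vacuity index and mean fullness, the Costello feeding-strategy
statistics in their prey-specific-abundance form (Fi% against Pi%),
per-fish Shannon diet diversity, the arcsine-square-root transform,
distance-based multivariate tests (PERMANOVA on Bray-Curtis distances,
SIMPER decomposition) and exact sample-based prey accumulation
(rarefaction) curves.  Ordination (nMDS) and core-niche ellipses live in
:mod:`fishtroph.ordination`.

All composition statistics are computed over fish with non-empty guts
only; empty guts enter the vacuity index and, optionally, mean fullness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.spatial.distance import pdist, squareform

from .records import DistanceMatrix, GutSample
from .stats import bray_curtis, shannon_diversity

__all__ = [
    "DEFAULT_CATEGORIES", "DietMatrix", "build_diet_matrix",
    "vacuity_index", "mean_fullness", "occurrence_frequency",
    "prey_specific_abundance", "amundsen_points", "diet_diversity",
    "transform_arcsine_sqrt", "diet_distance_matrix", "permanova",
    "PermanovaResult", "simper", "SimperResult", "prey_accumulation",
]

DEFAULT_CATEGORIES = (
    "Chironomidae", "Simuliidae", "Hydropsychidae", "other_Trichoptera",
    "Mollusca", "terrestrial", "other_aquatic_BMI", "fish_bones", "plants",
)


@dataclass
class DietMatrix:
    """Fish-by-category volume-percent matrix for fish with gut contents.

    ``values.loc[fish, cat]`` is the volume percent of ``cat`` in that
    fish's gut; row sums equal each fish's fullness.
    """

    values: pd.DataFrame               # rows fish_id, columns categories
    fullness: pd.Series                # per retained fish
    populations: pd.Series             # per retained fish
    n_total: int                       # including empty guts
    n_empty: int

    def proportions(self, denominator: str = "fullness") -> pd.DataFrame:
        """Row compositions in [0, 1].

        ``denominator='fullness'`` divides each row by the fish's own
        fullness (a composition of what was eaten); ``'hundred'`` divides
        by 100 (share of a full gut).
        """
        if denominator == "fullness":
            return self.values.div(self.fullness, axis=0)
        if denominator == "hundred":
            return self.values / 100.0
        raise ValueError("denominator must be 'fullness' or 'hundred'")


def build_diet_matrix(guts: list[GutSample],
                      categories=None) -> DietMatrix:
    """Assemble the diet matrix from gut samples, dropping empty guts.

    ``categories`` fixes the column set (unknown items raise); defaults to
    the union of observed categories ordered by ``DEFAULT_CATEGORIES``
    first, extras alphabetically after.
    """
    if not guts:
        raise ValueError("no gut samples")
    observed = sorted({c for g in guts for c in g.items})
    if categories is None:
        cats = [c for c in DEFAULT_CATEGORIES if c in observed]
        cats += [c for c in observed if c not in DEFAULT_CATEGORIES]
    else:
        cats = list(categories)
        unknown = [c for c in observed if c not in cats]
        if unknown:
            raise ValueError(f"items outside the category list: {unknown}")
    full = [g for g in guts if not g.is_empty]
    values = pd.DataFrame(
        [[g.items.get(c, 0.0) for c in cats] for g in full],
        index=[g.fish_id for g in full], columns=cats, dtype=float)
    return DietMatrix(
        values=values,
        fullness=pd.Series([g.fullness for g in full],
                           index=values.index, dtype=float),
        populations=pd.Series([g.population_id for g in full],
                              index=values.index),
        n_total=len(guts), n_empty=len(guts) - len(full))


def vacuity_index(guts: list[GutSample]) -> float:
    """Percentage of fish with empty guts (I%)."""
    if not guts:
        raise ValueError("no gut samples")
    n_empty = sum(g.is_empty for g in guts)
    return 100.0 * n_empty / len(guts)


def mean_fullness(guts: list[GutSample],
                  include_empty: bool = True) -> tuple[float, float]:
    """Mean and SD of gut fullness (percent).

    Empty guts are included by default; set ``include_empty=False`` to
    summarise feeding fish only.
    """
    if not guts:
        raise ValueError("no gut samples")
    vals = np.array([g.fullness for g in guts
                     if include_empty or not g.is_empty])
    if vals.size == 0:
        raise ValueError("no non-empty guts")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    return float(vals.mean()), sd


def occurrence_frequency(matrix: DietMatrix, category: str) -> float:
    """Fi% — percent of fish with contents whose guts hold the category."""
    if category not in matrix.values.columns:
        raise KeyError(f"unknown category {category!r}")
    col = matrix.values[category]
    return float(100.0 * (col > 0).sum() / len(col))


def prey_specific_abundance(matrix: DietMatrix, category: str) -> float:
    """Pi% — the category's share of total gut volume, restricted to the
    guts that contain it."""
    if category not in matrix.values.columns:
        raise KeyError(f"unknown category {category!r}")
    col = matrix.values[category]
    holders = col > 0
    if not holders.any():
        raise ValueError(f"category {category!r} occurs in no gut")
    si = float(col[holders].sum())
    sti = float(matrix.values.loc[holders].to_numpy().sum())
    return 100.0 * si / sti


def amundsen_points(matrix: DietMatrix) -> pd.DataFrame:
    """Feeding-strategy (Costello-type) plot coordinates.

    One row per category present in at least one gut, with its frequency
    of occurrence Fi% and prey-specific abundance Pi%.  High-Fi/high-Pi
    points mark dominant generalist prey; low-Fi/high-Pi points mark
    within-phenotype specialisation.
    """
    rows = []
    for cat in matrix.values.columns:
        fi = occurrence_frequency(matrix, cat)
        if fi > 0:
            rows.append({"category": cat, "Fi": fi,
                         "Pi": prey_specific_abundance(matrix, cat)})
    return pd.DataFrame(rows, columns=["category", "Fi", "Pi"])


def diet_diversity(matrix: DietMatrix) -> dict:
    """Per-fish Shannon H of diet composition plus population summaries."""
    h = matrix.values.apply(
        lambda row: shannon_diversity(row.to_numpy()), axis=1)
    summary = h.groupby(matrix.populations).agg(["mean", "std", "size"])
    summary.columns = ["mean_H", "sd_H", "n"]
    return {"per_fish": h, "by_population": summary}


def transform_arcsine_sqrt(mat) -> np.ndarray | pd.DataFrame:
    """Elementwise arcsine-square-root transform of proportions in [0, 1]."""
    arr = mat.to_numpy() if isinstance(mat, pd.DataFrame) else \
        np.asarray(mat, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("entries must be proportions in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    if isinstance(mat, pd.DataFrame):
        return pd.DataFrame(out, index=mat.index, columns=mat.columns)
    return out


def diet_distance_matrix(matrix: DietMatrix, transform: bool = True,
                         denominator: str = "fullness") -> DistanceMatrix:
    """Bray-Curtis distances between fish diet compositions.

    By default rows are the arcsine-sqrt-transformed compositions, the
    preprocessing under which the multivariate tests are run; set
    ``transform=False`` for raw volume percentages.
    """
    data = matrix.proportions(denominator)
    if transform:
        data = transform_arcsine_sqrt(data)
    vals = squareform(pdist(data.to_numpy(), metric="braycurtis"))
    return DistanceMatrix(labels=tuple(data.index), values=vals)


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p: float
    n_permutations: int
    df1: int
    df2: int
    seed: int


def permanova(dist: DistanceMatrix | np.ndarray, groups,
              n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """Distance-based one-way PERMANOVA (the adonis pseudo-F).

    SS_total = sum of squared distances / n; SS_within sums the analogous
    quantity per group; pseudo-F = (SS_among/(k-1)) / (SS_within/(n-k)).
    The p-value counts label permutations with pseudo-F >= observed,
    including the identity: p = (count + 1) / (n_perm + 1).
    """
    dm = dist.values if isinstance(dist, DistanceMatrix) else \
        np.asarray(dist, dtype=float)
    labels = np.asarray(groups)
    n = dm.shape[0]
    if labels.shape[0] != n:
        raise ValueError("groups length must match the distance matrix")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    uniq, inv = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValueError("need >= 2 groups")
    sizes = np.bincount(inv)
    if np.any(sizes < 2):
        import warnings
        warnings.warn("a group has a single member; its within-group SS "
                      "is zero", RuntimeWarning)
    d2 = dm ** 2
    ss_total = d2.sum() / (2.0 * n)

    def ss_within(perm_inv: np.ndarray) -> float:
        ss = 0.0
        for g in range(k):
            idx = np.flatnonzero(perm_inv == g)
            ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
        return ss

    ssw = ss_within(inv)
    ssa = ss_total - ssw
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore"):
        f_obs = (ssa / df1) / (ssw / df2)

    rng = np.random.default_rng(seed)
    count = 0
    with np.errstate(divide="ignore"):
        for _ in range(n_perm):
            p_inv = rng.permutation(inv)
            ssw_p = ss_within(p_inv)
            f_p = ((ss_total - ssw_p) / df1) / (ssw_p / df2)
            if f_p >= f_obs - 1e-12:
                count += 1
    return PermanovaResult(pseudo_F=float(f_obs),
                           r_squared=float(ssa / ss_total),
                           p=(count + 1) / (n_perm + 1),
                           n_permutations=n_perm, df1=df1, df2=df2,
                           seed=seed)


@dataclass
class SimperResult:
    """Per category contributions to between-group Bray-Curtis
    dissimilarity, per group pair."""

    contributions: pd.DataFrame   # pair, category, contribution, cum. pct
    overall: pd.DataFrame         # pair, average dissimilarity


def simper(data, groups) -> SimperResult:
    """SIMPER decomposition of average between-group dissimilarity.

    For each pair of groups, each category's contribution is the mean over
    cross-group sample pairs of its share of the Bray-Curtis numerator
    ``|x_i - x_j| / sum(x_i + x_j)``; the per-category contributions sum
    exactly to the pair's average dissimilarity.
    """
    if isinstance(data, DietMatrix):
        mat = data.values
        labels = data.populations.to_numpy()
        cats = list(mat.columns)
        arr = mat.to_numpy(dtype=float)
    elif isinstance(data, pd.DataFrame):
        cats = list(data.columns)
        arr = data.to_numpy(dtype=float)
        labels = np.asarray(groups)
    else:
        arr = np.asarray(data, dtype=float)
        cats = [f"v{j}" for j in range(arr.shape[1])]
        labels = np.asarray(groups)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need >= 2 groups")
    contrib_rows, overall_rows = [], []
    for a_i in range(uniq.size):
        for b_i in range(a_i + 1, uniq.size):
            ga = arr[labels == uniq[a_i]]
            gb = arr[labels == uniq[b_i]]
            # cross-pair |x - y| shares, vectorised over all pairs
            diff = np.abs(ga[:, None, :] - gb[None, :, :])
            denom = ga.sum(axis=1)[:, None] + gb.sum(axis=1)[None, :]
            per_cat = (diff / denom[:, :, None]).mean(axis=(0, 1))
            total = float(per_cat.sum())
            order = np.argsort(per_cat)[::-1]
            cum = 0.0
            pair = f"{uniq[a_i]} vs {uniq[b_i]}"
            for idx in order:
                cum += per_cat[idx]
                contrib_rows.append({
                    "pair": pair, "category": cats[idx],
                    "contribution": float(per_cat[idx]),
                    "cumulative_pct": 100.0 * cum / total if total else 0.0})
            overall_rows.append({"pair": pair,
                                 "average_dissimilarity": total})
    return SimperResult(
        contributions=pd.DataFrame(contrib_rows),
        overall=pd.DataFrame(overall_rows))


def prey_accumulation(presence, m_values=None) -> pd.DataFrame:
    """Exact sample-based rarefaction of prey categories over guts.

    ``presence`` is a fish x category boolean/abundance matrix (non-empty
    guts).  The expected richness among ``m`` guts drawn without
    replacement is ``S_obs - sum_i C(N - N_i, m) / C(N, m)`` with ``N_i``
    the number of guts containing category i.
    """
    if isinstance(presence, DietMatrix):
        pres = (presence.values.to_numpy() > 0)
    else:
        pres = np.asarray(presence) > 0
    n = pres.shape[0]
    if n < 2:
        raise ValueError("need >= 2 guts")
    ni = pres.sum(axis=0)
    ni = ni[ni > 0]
    s_obs = ni.size
    if m_values is None:
        m_values = np.arange(1, n + 1)
    m_values = np.asarray(m_values, dtype=int)
    if np.any(m_values < 1) or np.any(m_values > n):
        raise ValueError("m must be in 1..N")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    exp_s = np.empty(m_values.size)
    for j, m in enumerate(m_values):
        ok = (n - ni) >= m
        absent = np.zeros(ni.size)
        absent[ok] = np.exp(log_comb(n - ni[ok], m) - log_comb(n, m))
        exp_s[j] = s_obs - absent.sum()
    return pd.DataFrame({"n_guts": m_values, "expected_richness": exp_s})
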