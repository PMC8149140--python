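"""Somatic growth and length-weight analysis.

Von Bertalanffy growth curves ``TL = Linf * (1 - exp(-K (t - t0)))`` are
fitted to population mean length-at-age, under all eight ways of sharing
the three parameters across populations (each of Linf, K, t0 either common
to all populations or population-specific).  Models are ranked by a
least-squares AIC.  The module also covers the log10 length-weight
regression (LWR), the t-test against isometric growth (b = 3), an ANCOVA
for slope heterogeneity, and residual body condition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .records import FishRecord
from .stats import AnovaResult, anova_oneway, linear_regression

__all__ = [
    "VBParams", "VBModelSpec", "VBFitResult", "LWRFit",
    "as_fish_frame", "mean_length_at_age", "predict_vb", "aic_ls",
    "fit_vb", "vb_model_selection", "fit_lwr", "test_isometry",
    "ancova_lwr", "body_condition", "all_model_specs",
]

_PARAM_NAMES = ("Linf", "K", "t0")


@dataclass(frozen=True)
class VBParams:
    """Von Bertalanffy parameters: asymptotic length Linf (cm), growth
    coefficient K (1/yr), theoretical age at zero length t0 (yr)."""

    Linf: float
    K: float
    t0: float

    def __post_init__(self) -> None:
        if not (self.Linf > 0 and self.K > 0):
            raise ValueError("Linf and K must be positive")


@dataclass(frozen=True, order=True)
class VBModelSpec:
    """Which of (Linf, K, t0) are shared across populations."""

    share_Linf: bool
    share_K: bool
    share_t0: bool

    @property
    def shared(self) -> frozenset[str]:
        return frozenset(name for name, flag in zip(
            _PARAM_NAMES,
            (self.share_Linf, self.share_K, self.share_t0)) if flag)

    def n_params(self, n_pops: int) -> int:
        return sum(1 if f else n_pops for f in
                   (self.share_Linf, self.share_K, self.share_t0))

    def is_restriction_of(self, other: "VBModelSpec") -> bool:
        """True when this spec shares a (weak) superset of ``other``'s
        parameters, i.e. is nested inside it."""
        return self.shared >= other.shared

    def label(self) -> str:
        shared = sorted(self.shared)
        return "shared:" + ("+".join(shared) if shared else "none")


def all_model_specs() -> list[VBModelSpec]:
    """The 8 sharing structures, from fully shared to fully free."""
    specs = [VBModelSpec(*flags) for flags in
             itertools.product((True, False), repeat=3)]
    return sorted(specs, key=lambda s: -len(s.shared))


def predict_vb(p: VBParams, t) -> np.ndarray | float:
    """Evaluate TL = Linf (1 - exp(-K (t - t0)))."""
    t = np.asarray(t, dtype=float)
    out = p.Linf * (1.0 - np.exp(-p.K * (t - p.t0)))
    return float(out) if out.ndim == 0 else out


def as_fish_frame(fish) -> pd.DataFrame:
    """Coerce a list of FishRecord (or an equivalent DataFrame) to a frame
    with columns population_id, status, total_length, weight, age."""
    if isinstance(fish, pd.DataFrame):
        return fish
    rows = [{"fish_id": f.fish_id, "population_id": f.population_id,
             "status": f.status, "total_length": f.total_length,
             "weight": f.weight, "age": f.age} for f in fish]
    return pd.DataFrame(rows)


def mean_length_at_age(fish, max_age: int) -> pd.DataFrame:
    """Population mean total length per age class, ages 0..max_age.

    Age classes above ``max_age`` are dropped (the study design excludes
    ages not present in every population).  Rows with a single fish get a
    missing SD.
    """
    if max_age < 1:
        raise ValueError("max_age must be >= 1")
    df = as_fish_frame(fish)
    df = df.dropna(subset=["age"])
    df = df[df["age"] <= max_age]
    if df.empty:
        raise ValueError("no aged fish at or below max_age")
    grouped = df.groupby(["population_id", "age"])["total_length"]
    out = grouped.agg(mean_tl="mean", sd="std", n="size").reset_index()
    out["age"] = out["age"].astype(int)
    return out.sort_values(["population_id", "age"]).reset_index(drop=True)


def aic_ls(sse: float, n: int, k: int) -> float:
    """AIC for a least-squares fit with Gaussian errors:
    ``n ln(SSE/n) + 2 (k + 1)``, the error variance counting as one extra
    parameter."""
    if n <= k:
        raise ValueError("need n > k")
    if sse < 0:
        raise ValueError("SSE must be non-negative")
    if sse == 0:
        warnings.warn("SSE is exactly 0; AIC is -inf", RuntimeWarning)
        return -np.inf
    return float(n * np.log(sse / n) + 2 * (k + 1))


@dataclass
class VBFitResult:
    """Least-squares fit of one sharing structure."""

    spec: VBModelSpec
    params: dict[str, VBParams]        # population_id -> parameters
    sse: float
    n_points: int
    k_params: int
    aic: float
    se: dict[str, dict[str, float]] = field(default_factory=dict)
    converged: bool = True

    @property
    def shared_K(self) -> float | None:
        if not self.spec.share_K:
            return None
        return next(iter(self.params.values())).K


def _pack_init(spec: VBModelSpec, pops, laa: pd.DataFrame,
               explicit: dict[str, VBParams] | None) -> np.ndarray:
    """Default or user-provided starting vector in packed order."""
    if explicit is not None:
        vals = {"Linf": [explicit[p].Linf for p in pops],
                "K": [explicit[p].K for p in pops],
                "t0": [explicit[p].t0 for p in pops]}
    else:
        linf0 = {p: 1.1 * laa.loc[laa.population_id == p, "mean_tl"].max()
                 for p in pops}
        vals = {"Linf": [linf0[p] for p in pops],
                "K": [0.3] * len(pops), "t0": [0.0] * len(pops)}
    x = []
    for name, flag in zip(_PARAM_NAMES, (spec.share_Linf, spec.share_K,
                                         spec.share_t0)):
        v = vals[name]
        x.extend([float(np.mean(v))] if flag else [float(u) for u in v])
    return np.asarray(x)


def _unpack(spec: VBModelSpec, pops, x: np.ndarray) -> dict[str, VBParams]:
    i = 0
    per: dict[str, list[float]] = {name: [] for name in _PARAM_NAMES}
    for name, flag in zip(_PARAM_NAMES, (spec.share_Linf, spec.share_K,
                                         spec.share_t0)):
        if flag:
            per[name] = [x[i]] * len(pops)
            i += 1
        else:
            per[name] = list(x[i:i + len(pops)])
            i += len(pops)
    return {p: VBParams(per["Linf"][j], per["K"][j], per["t0"][j])
            for j, p in enumerate(pops)}


def _bounds(spec: VBModelSpec, n_pops: int):
    lo, hi = [], []
    for name, flag in zip(_PARAM_NAMES, (spec.share_Linf, spec.share_K,
                                         spec.share_t0)):
        reps = 1 if flag else n_pops
        if name == "t0":
            lo += [-10.0] * reps
            hi += [10.0] * reps
        elif name == "K":
            lo += [1e-6] * reps
            hi += [10.0] * reps
        else:
            lo += [1e-6] * reps
            hi += [np.inf] * reps
    return np.asarray(lo), np.asarray(hi)


def fit_vb(laa: pd.DataFrame, spec: VBModelSpec,
           init: dict[str, VBParams] | None = None,
           extra_inits: list[np.ndarray] | None = None,
           n_restarts: int = 5, seed: int = 0,
           weighted: bool = False) -> VBFitResult:
    """Fit one sharing structure to a mean length-at-age table.

    Minimises the (optionally n-weighted) sum of squared deviations of the
    age means from the curve, with jittered multi-start local optimisation.
    Standard errors come from the Gauss-Newton covariance at the optimum.
    """
    pops = sorted(laa["population_id"].unique())
    if len(pops) < 1:
        raise ValueError("no populations in table")
    pop_idx = laa["population_id"].map({p: j for j, p in enumerate(pops)})
    t = laa["age"].to_numpy(dtype=float)
    y = laa["mean_tl"].to_numpy(dtype=float)
    w = np.sqrt(laa["n"].to_numpy(dtype=float)) if weighted \
        else np.ones_like(y)
    pidx = pop_idx.to_numpy()

    lo, hi = _bounds(spec, len(pops))

    n_pops = len(pops)
    # packed-column index of each (parameter, population) pair
    col_of = np.empty((3, n_pops), dtype=int)
    i = 0
    for row, flag in enumerate((spec.share_Linf, spec.share_K,
                                spec.share_t0)):
        if flag:
            col_of[row, :] = i
            i += 1
        else:
            col_of[row, :] = np.arange(i, i + n_pops)
            i += n_pops

    def residuals(x: np.ndarray) -> np.ndarray:
        params = _unpack(spec, pops, x)
        pred = np.empty_like(y)
        for j, p in enumerate(pops):
            m = pidx == j
            pred[m] = predict_vb(params[p], t[m])
        return w * (y - pred)

    def jacobian(x: np.ndarray) -> np.ndarray:
        params = _unpack(spec, pops, x)
        J = np.zeros((y.size, x.size))
        rows = np.arange(y.size)
        for j, p in enumerate(pops):
            m = pidx == j
            pp = params[p]
            e = np.exp(-pp.K * (t[m] - pp.t0))
            wj = w[m]
            J[rows[m], col_of[0, j]] += -wj * (1.0 - e)
            J[rows[m], col_of[1, j]] += -wj * pp.Linf * e * (t[m] - pp.t0)
            J[rows[m], col_of[2, j]] += wj * pp.Linf * e * pp.K
        return J

    x0 = _pack_init(spec, pops, laa, init)
    starts = [x0]
    if extra_inits:
        starts.extend(np.asarray(s, dtype=float) for s in extra_inits)
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        jit = x0 * rng.uniform(0.7, 1.3, size=x0.shape) \
            + rng.normal(0, 0.2, size=x0.shape)
        starts.append(np.clip(jit, lo + 1e-6, np.minimum(hi, 1e6)))

    best = None
    for s in starts:
        s = np.clip(s, lo, hi)
        try:
            sol = optimize.least_squares(residuals, s, jac=jacobian,
                                         bounds=(lo, hi),
                                         xtol=1e-10, ftol=1e-10, gtol=1e-10)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"von Bertalanffy fit failed for {spec.label()}")

    sse = float(2.0 * best.cost)
    k = spec.n_params(len(pops))
    n = y.size
    params = _unpack(spec, pops, best.x)

    se: dict[str, dict[str, float]] = {}
    if n > k:
        s2 = sse / (n - k)
        try:
            cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
            sig = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            sig = np.full(k, np.nan)
        i = 0
        per_se: dict[str, list[float]] = {}
        for name, flag in zip(_PARAM_NAMES, (spec.share_Linf, spec.share_K,
                                             spec.share_t0)):
            if flag:
                per_se[name] = [float(sig[i])] * len(pops)
                i += 1
            else:
                per_se[name] = [float(v) for v in sig[i:i + len(pops)]]
                i += len(pops)
        se = {p: {name: per_se[name][j] for name in _PARAM_NAMES}
              for j, p in enumerate(pops)}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        aic = aic_ls(max(sse, 1e-300), n, k) if n > k else np.nan
    return VBFitResult(spec=spec, params=params, sse=sse, n_points=n,
                       k_params=k, aic=aic, se=se,
                       converged=bool(best.success))


def _expand_packed(src: VBFitResult, dst_spec: VBModelSpec,
                   pops) -> np.ndarray:
    """Express a (more shared) fitted solution as a starting vector for a
    less-shared spec; the fit from this start can only lower the SSE."""
    x = []
    for name, flag in zip(_PARAM_NAMES, (dst_spec.share_Linf,
                                         dst_spec.share_K,
                                         dst_spec.share_t0)):
        vals = [getattr(src.params[p], name) for p in pops]
        x.extend([float(np.mean(vals))] if flag else vals)
    return np.asarray(x)


def vb_model_selection(laa: pd.DataFrame, seed: int = 0,
                       weighted: bool = False) -> list[VBFitResult]:
    """Fit all 8 sharing structures and rank by AIC (ascending; ties go to
    the model with fewer parameters).

    Structures are fitted from most to least shared, seeding each fit with
    the solutions of every structure nested inside it, which enforces the
    SSE nesting monotonicity of the hierarchy.
    """
    pops = sorted(laa["population_id"].unique())
    if len(pops) < 2:
        raise ValueError("model selection needs >= 2 populations")
    fits: dict[VBModelSpec, VBFitResult] = {}
    errors: dict[VBModelSpec, Exception] = {}
    for spec in all_model_specs():
        extra = [_expand_packed(f, spec, pops)
                 for done, f in fits.items() if done.is_restriction_of(spec)]
        try:
            # nested-fit inits already cover the landscape well; two
            # jittered restarts are insurance against a bad default start
            fits[spec] = fit_vb(laa, spec, extra_inits=extra, seed=seed,
                                n_restarts=2, weighted=weighted)
        except Exception as exc:   # rank whatever succeeded
            errors[spec] = exc
    if not fits:
        raise RuntimeError(f"all model fits failed: {errors}")

    def key(f: VBFitResult):
        # fits at the numerical noise floor are exact ties: rank them by
        # parsimony (the SSE=0 -inf sentinel, extended to ~0)
        aic = -np.inf if f.sse < 1e-8 else f.aic
        return (aic, f.k_params)

    return sorted(fits.values(), key=key)


@dataclass
class LWRFit:
    """Length-weight regression log10 W = log10 a + b log10 TL.

    ``a`` is reported on the multiplicative scale (W = a TL^b, W in g and
    TL in cm); residuals are on the log10 scale.
    """

    a: float
    b: float
    se_b: float
    r_squared: float
    residuals: np.ndarray
    n: int
    population_id: str | None = None


def fit_lwr(fish, population_id: str | None = None,
            min_n: int = 10) -> LWRFit:
    """OLS fit of the log10 length-weight relation for one population."""
    df = as_fish_frame(fish)
    if population_id is not None:
        df = df[df["population_id"] == population_id]
    df = df.dropna(subset=["weight"])
    bad = (df["total_length"] <= 0) | (df["weight"] <= 0)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} rows with non-positive "
                      "length or weight", RuntimeWarning)
        df = df[~bad]
    if len(df) < min_n:
        raise ValueError(f"need >= {min_n} fish with valid length and weight")
    reg = linear_regression(np.log10(df["total_length"].to_numpy()),
                            np.log10(df["weight"].to_numpy()))
    return LWRFit(a=float(10.0 ** reg.intercept), b=reg.slope,
                  se_b=reg.se_slope, r_squared=reg.r_squared,
                  residuals=reg.residuals, n=reg.n,
                  population_id=population_id)


def test_isometry(fit: LWRFit, alpha: float = 0.05) -> dict:
    """t-test of the LWR slope against isometric growth b = 3."""
    t = (fit.b - 3.0) / fit.se_b
    df = fit.n - 2
    p = float(2.0 * sps.t.sf(abs(t), df))
    if p >= alpha:
        verdict = "isometric"
    else:
        verdict = "allometric_negative" if fit.b < 3 else \
            "allometric_positive"
    return {"t": float(t), "df": df, "p": p, "verdict": verdict}


def ancova_lwr(fish) -> dict:
    """ANCOVA for heterogeneity of LWR slopes across populations.

    Compares the common-slope model (population intercepts + one slope) to
    the full model with population-specific slopes, on log10 scales.
    """
    df = as_fish_frame(fish).dropna(subset=["weight"])
    df = df[(df["total_length"] > 0) & (df["weight"] > 0)]
    pops = sorted(df["population_id"].unique())
    if len(pops) < 2:
        raise ValueError("ANCOVA needs >= 2 populations")
    x = np.log10(df["total_length"].to_numpy())
    y = np.log10(df["weight"].to_numpy())
    g = df["population_id"].map({p: j for j, p in enumerate(pops)}).to_numpy()
    n, k = y.size, len(pops)
    d = np.zeros((n, k))
    d[np.arange(n), g] = 1.0
    X_red = np.column_stack([d, x])                       # k + 1 params
    X_full = np.column_stack([d, d * x[:, None]])         # 2k params
    sse_r = _ols_sse(X_red, y)
    sse_f = _ols_sse(X_full, y)
    df1, df2 = k - 1, n - 2 * k
    F = ((sse_r - sse_f) / df1) / (sse_f / df2)
    return {"F": float(F), "df1": df1, "df2": df2,
            "p": float(sps.f.sf(F, df1, df2))}


def _ols_sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def body_condition(fish, mode: str = "per_population") -> dict:
    """Residual body condition: observed minus LWR-predicted log10 weight.

    ``mode='per_population'`` back-calculates each fish's weight from its
    own population's LWR (residual means then sit at ~0 by construction);
    ``mode='pooled'`` uses a single LWR over all fish, so the ANOVA across
    populations picks up genuine condition differences.
    """
    if mode not in ("per_population", "pooled"):
        raise ValueError("mode must be 'per_population' or 'pooled'")
    df = as_fish_frame(fish).dropna(subset=["weight"]).copy()
    df = df[(df["total_length"] > 0) & (df["weight"] > 0)]
    pops = sorted(df["population_id"].unique())
    resid = np.empty(len(df))
    if mode == "pooled":
        fit = fit_lwr(df)
        pred = np.log10(fit.a) + fit.b * np.log10(df["total_length"])
        resid = np.log10(df["weight"]).to_numpy() - pred.to_numpy()
    else:
        for p in pops:
            m = (df["population_id"] == p).to_numpy()
            fit = fit_lwr(df[df["population_id"] == p])
            pred = np.log10(fit.a) + fit.b * np.log10(
                df.loc[df["population_id"] == p, "total_length"])
            resid[m] = (np.log10(
                df.loc[df["population_id"] == p, "weight"]) - pred).to_numpy()
    df["condition_residual"] = resid
    groups = [df.loc[df["population_id"] == p, "condition_residual"]
              .to_numpy() for p in pops]
    anova = anova_oneway(groups) if len(pops) >= 2 else None
    means = {p: float(gr.mean()) for p, gr in zip(pops, groups)}
    return {"residuals": df[["fish_id", "population_id",
                             "condition_residual"]],
            "population_means": means, "anova": anova, "mode": mode}
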