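"""End-to-end orchestration: simulate (or load) the four study tables,
run the growth, diet, isotope and community stages with deterministic
per-stage seeds, and write the consolidated report bundle.

Each stage receives its own random stream derived from the global seed
and the stage name, so enabling or disabling one stage never perturbs
another's results.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import community as community_mod
from . import diet as diet_mod
from . import growth as growth_mod
from . import isotope as isotope_mod
from .io import read_table
from .ordination import core_ellipse, nmds
from .records import FishRecord, GutSample, IsotopeSample
from .simulate import derive_rng, simulate_study, write_tables

log = logging.getLogger("fishtroph")

__all__ = ["RunConfig", "run_all", "report_summary"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``input_dir`` points at the four CSV tables (fish.csv,
    gut.csv, isotope.csv, community.csv) or ``simulate=True`` generates
    them from the default study configuration.  ``tdf_c`` (the carbon
    discrimination factor) has no shipped default and must be set before
    the isotope stage runs.
    """

    outdir: str | Path = "results"
    seed: int = 0
    simulate: bool = True
    input_dir: str | Path | None = None
    max_age: int = 4
    categories: list[str] | None = None
    n_permutations: int = 999
    tdf_n: float = 4.2
    tdf_n_sd: float = 0.2
    tdf_c: float | None = None
    tdf_c_sd: float = 0.0
    mcmc_iters: int = 10_000
    stages: tuple[str, ...] = ("growth", "diet", "isotope", "community")

    def validate(self) -> None:
        if "isotope" in self.stages and self.tdf_c is None:
            raise ValueError("tdf_c (carbon discrimination factor) must "
                             "be set when the isotope stage is enabled")
        if not self.simulate and self.input_dir is None:
            raise ValueError("input_dir is required when simulate=False")


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    return int(derive_rng(cfg.seed, f"stage/{stage}").integers(2 ** 31))


def _load_inputs(cfg: RunConfig) -> dict:
    if cfg.simulate:
        study = simulate_study(cfg.seed)
        return study
    d = Path(cfg.input_dir)
    return {
        "fish": read_table(d / "fish.csv", "fish"),
        "guts": read_table(d / "gut.csv", "gut"),
        "isotopes": read_table(d / "isotope.csv", "isotope"),
        "community": read_table(d / "community.csv", "community"),
        "catches": None,
    }


def _growth_stage(cfg: RunConfig, fish: list[FishRecord]) -> dict:
    seed = _stage_seed(cfg, "growth")
    laa = growth_mod.mean_length_at_age(fish, max_age=cfg.max_age)
    ranked = growth_mod.vb_model_selection(laa, seed=seed)
    best = ranked[0]
    pops = sorted({f.population_id for f in fish})
    lwr_rows = []
    for p in pops:
        fit = growth_mod.fit_lwr(fish, population_id=p)
        iso = growth_mod.test_isometry(fit)
        lwr_rows.append({
            "population_id": p, "n": fit.n, "a": fit.a, "b": fit.b,
            "se_b": fit.se_b, "r_squared": fit.r_squared,
            "isometry_t": iso["t"], "isometry_p": iso["p"],
            "isometry_verdict": iso["verdict"]})
    cond = growth_mod.body_condition(fish, mode="per_population")
    model_rows = []
    best_aic = ranked[0].aic
    for f in ranked:
        model_rows.append({
            "model": f.spec.label(), "k": f.k_params, "sse": f.sse,
            "aic": f.aic, "delta_aic": f.aic - best_aic,
            "indistinguishable": bool(f.aic - best_aic < 2.0)})
    vb_rows = []
    for p, params in best.params.items():
        se = best.se.get(p, {})
        vb_rows.append({"population_id": p, "Linf": params.Linf,
                        "K": params.K, "t0": params.t0,
                        "se_Linf": se.get("Linf"), "se_K": se.get("K"),
                        "se_t0": se.get("t0")})
    return {
        "mean_length_at_age": laa,
        "model_selection": pd.DataFrame(model_rows),
        "best_model": best,
        "vb_params": pd.DataFrame(vb_rows),
        "lwr": pd.DataFrame(lwr_rows),
        "ancova": growth_mod.ancova_lwr(fish),
        "condition": cond,
        "manova": _length_age_manova(fish, cfg.max_age),
    }


def _length_age_manova(fish, max_age: int):
    from .stats import manova_pillai
    rows = [(f.population_id, f.total_length, f.age) for f in fish
            if f.age is not None and 1 <= f.age <= max_age]
    if len({r[0] for r in rows}) < 2:
        return None
    y = np.array([[r[1], r[2]] for r in rows], dtype=float)
    labels = np.array([r[0] for r in rows])
    res = manova_pillai(y, labels)
    return {"pillai": res.pillai, "F": res.F, "df1": res.df1,
            "df2": res.df2, "p": res.p}


def _diet_stage(cfg: RunConfig, guts: list[GutSample]) -> dict:
    seed = _stage_seed(cfg, "diet")
    pops = sorted({g.population_id for g in guts})
    by_pop = {p: [g for g in guts if g.population_id == p] for p in pops}
    matrix = diet_mod.build_diet_matrix(guts, categories=cfg.categories)
    div = diet_mod.diet_diversity(matrix)

    summary_rows = []
    amundsen = {}
    for p in pops:
        sub = diet_mod.build_diet_matrix(
            by_pop[p], categories=list(matrix.values.columns))
        amundsen[p] = diet_mod.amundsen_points(sub)
        mean_f, sd_f = diet_mod.mean_fullness(by_pop[p])
        h = div["by_population"]
        summary_rows.append({
            "population_id": p, "n": len(by_pop[p]),
            "vacuity_pct": diet_mod.vacuity_index(by_pop[p]),
            "mean_fullness": mean_f, "sd_fullness": sd_f,
            "mean_H": float(h.loc[p, "mean_H"]),
            "sd_H": float(h.loc[p, "sd_H"])})

    dist = diet_mod.diet_distance_matrix(matrix)
    groups = matrix.populations.to_numpy()
    perm = diet_mod.permanova(dist, groups, n_perm=cfg.n_permutations,
                              seed=seed)
    simp = diet_mod.simper(matrix.proportions().pipe(
        diet_mod.transform_arcsine_sqrt), groups)
    ord_res = nmds(dist, seed=seed)
    coords = pd.DataFrame(ord_res.coordinates, index=matrix.values.index,
                          columns=["nmds1", "nmds2"])
    coords["population_id"] = matrix.populations
    ellipse_rows = []
    ellipses = {}
    for p in pops:
        pts = coords.loc[coords.population_id == p,
                         ["nmds1", "nmds2"]].to_numpy()
        if pts.shape[0] >= 3:
            ell = core_ellipse(pts)
            ellipses[p] = ell
            ellipse_rows.append({"population_id": p, "area": ell.area,
                                 "center_1": ell.center[0],
                                 "center_2": ell.center[1]})
    curves = {p: diet_mod.prey_accumulation(
        diet_mod.build_diet_matrix(by_pop[p],
                                   categories=list(matrix.values.columns)))
        for p in pops if sum(not g.is_empty for g in by_pop[p]) >= 2}
    summary = pd.DataFrame(summary_rows)
    summary = summary.merge(pd.DataFrame(ellipse_rows)[
        ["population_id", "area"]].rename(
        columns={"area": "nmds_ellipse_area"}), on="population_id",
        how="left")
    return {"summary": summary, "amundsen": amundsen,
            "permanova": perm, "simper": simp, "nmds": ord_res,
            "nmds_coords": coords, "ellipses": ellipses,
            "accumulation": curves, "stress": ord_res.stress}


def _isotope_stage(cfg: RunConfig, samples: list[IsotopeSample]) -> dict:
    seed = _stage_seed(cfg, "isotope")
    tdf = isotope_mod.TDF(dN_mean=cfg.tdf_n, dN_sd=cfg.tdf_n_sd,
                          dC_mean=cfg.tdf_c, dC_sd=cfg.tdf_c_sd)
    pops = sorted({s.population_id for s in samples})
    screened = isotope_mod.screen_cn(
        [s for s in samples if s.c_to_n is not None])
    rows = []
    posteriors = {}
    seas = {}
    ellipses = {}
    rng = derive_rng(seed, "isotope-stage")
    for p in pops:
        cons = [s for s in samples
                if s.population_id == p and s.group == "consumer"]
        bmi = [s for s in samples
               if s.population_id == p and s.group == "baseline_bmi"]
        if len(cons) < 3 or len(bmi) < 2:
            continue
        base = isotope_mod.pool_baseline(bmi)
        d15 = np.array([s.d15N for s in cons])
        d13 = np.array([s.d13C for s in cons])
        tl = None
        tp_det = isotope_mod.tp_point(d15, base, tdf)
        cc = isotope_mod.c_corr(d13, base, tdf)
        post = isotope_mod.tp_bayes(
            d15, base, tdf, iters=cfg.mcmc_iters,
            seed=int(rng.integers(2 ** 31)))
        sea = isotope_mod.sea_bayes(d13, d15, iters=cfg.mcmc_iters,
                                    seed=int(rng.integers(2 ** 31)))
        posteriors[p] = post
        seas[p] = sea
        ellipses[p] = core_ellipse(np.column_stack([d13, d15]))
        rows.append({
            "population_id": p, "n": len(cons),
            "d15N_mean": float(d15.mean()), "d15N_sd": float(d15.std(ddof=1)),
            "d13C_mean": float(d13.mean()), "d13C_sd": float(d13.std(ddof=1)),
            "tp_median": post.median, "tp_ci_lo": post.ci95[0],
            "tp_ci_hi": post.ci95[1],
            "tp_point_mean": float(np.mean(tp_det)),
            "c_corr_mean": float(np.mean(cc)),
            "c_corr_sd": float(np.std(cc, ddof=1)),
            "sea_ml": sea.sea_ml, "sea_b_median": sea.median,
            "sea_b_ci_lo": sea.ci95[0], "sea_b_ci_hi": sea.ci95[1]})
    tp_probs, sea_probs = {}, {}
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            if a in posteriors and b in posteriors:
                tp_probs[(a, b)] = isotope_mod.posterior_prob_greater(
                    posteriors[a].tp_draws, posteriors[b].tp_draws)
                sea_probs[(a, b)] = isotope_mod.posterior_prob_greater(
                    seas[a].draws, seas[b].draws)
    overlap_rows = []
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            if a in ellipses and b in ellipses:
                ov = isotope_mod.ellipse_overlap(ellipses[a], ellipses[b])
                overlap_rows.append({
                    "pair": f"{a} vs {b}", "area": ov["area"],
                    "pct_of_first": ov["pct_of_first"],
                    "pct_of_second": ov["pct_of_second"]})
    return {"summary": pd.DataFrame(rows), "posteriors": posteriors,
            "sea": seas, "tp_prob_greater": tp_probs,
            "sea_prob_greater": sea_probs,
            "overlap": pd.DataFrame(overlap_rows),
            "n_flagged_cn": len(screened["flagged"])}


def _community_stage(cfg: RunConfig, counts, catches) -> dict:
    metrics = community_mod.community_metrics(counts)
    dissim = community_mod.community_dissimilarity(counts)
    removal_rows = []
    if catches:
        areas = {c.site_id: c.area for c in counts}
        for site, (c1, c2) in sorted(catches.items()):
            try:
                est = community_mod.zippin_two_pass(c1, c2)
                fallback = False
            except community_mod.DepletionError as exc:
                est = exc.fallback
                fallback = True
            removal_rows.append({
                "site_id": site, "c1": c1, "c2": c2,
                "n_hat": est.n_hat, "se": est.se,
                "capture_prob": est.capture_prob, "fallback": fallback,
                "density": community_mod.density(
                    est.n_hat, areas.get(site, np.nan))
                if site in areas else np.nan})
    return {"metrics": metrics, "dissimilarity": dissim,
            "removal": pd.DataFrame(removal_rows)}


def run_all(cfg: RunConfig) -> dict:
    """Run the configured stages; write CSV/JSON outputs under
    ``cfg.outdir`` and return the in-memory bundle."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    inputs = _load_inputs(cfg)
    if cfg.simulate:
        write_tables(inputs, outdir / "inputs")
    bundle: dict = {"config": cfg, "inputs": inputs}
    manifest = {"version": __version__, "seed": cfg.seed,
                "stages": {}, "stage_seeds": {}}
    runners = {"growth": lambda: _growth_stage(cfg, inputs["fish"]),
               "diet": lambda: _diet_stage(cfg, inputs["guts"]),
               "isotope": lambda: _isotope_stage(cfg, inputs["isotopes"]),
               "community": lambda: _community_stage(
                   cfg, inputs["community"], inputs["catches"])}
    for stage in cfg.stages:
        ts = time.time()
        log.info("running stage %s", stage)
        try:
            bundle[stage] = runners[stage]()
        except Exception:
            log.exception("stage %s failed", stage)
            _write_outputs(bundle, outdir, manifest)
            raise
        manifest["stages"][stage] = round(time.time() - ts, 3)
        manifest["stage_seeds"][stage] = _stage_seed(cfg, stage)
    manifest["total_seconds"] = round(time.time() - t0, 3)
    _write_outputs(bundle, outdir, manifest)
    return bundle


def _write_outputs(bundle: dict, outdir: Path, manifest: dict) -> None:
    if "growth" in bundle:
        g = bundle["growth"]
        g["model_selection"].to_csv(outdir / "growth_models.csv",
                                    index=False)
        g["vb_params"].to_csv(outdir / "growth_vb_params.csv", index=False)
        g["lwr"].to_csv(outdir / "growth_lwr.csv", index=False)
    if "diet" in bundle:
        d = bundle["diet"]
        d["summary"].to_csv(outdir / "diet_summary.csv", index=False)
        d["nmds_coords"].to_csv(outdir / "diet_nmds_coords.csv")
        d["simper"].contributions.to_csv(outdir / "diet_simper.csv",
                                         index=False)
    if "isotope" in bundle:
        bundle["isotope"]["summary"].to_csv(outdir / "isotope_summary.csv",
                                            index=False)
        bundle["isotope"]["overlap"].to_csv(outdir / "isotope_overlap.csv",
                                            index=False)
    if "community" in bundle:
        c = bundle["community"]
        c["metrics"].to_csv(outdir / "community_metrics.csv", index=False)
        if len(c["removal"]):
            c["removal"].to_csv(outdir / "community_removal.csv",
                                index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def report_summary(bundle: dict) -> str:
    """One-page plain-text summary of a complete bundle."""
    missing = [s for s in bundle["config"].stages if s not in bundle]
    if missing:
        return "incomplete bundle; missing stages: " + ", ".join(missing)
    lines = ["fishtroph run summary", "=" * 21, ""]
    if "growth" in bundle:
        g = bundle["growth"]
        lines.append("Growth model selection (AIC ascending):")
        for _, r in g["model_selection"].iterrows():
            lines.append(f"  {r['model']:<24} k={r['k']:>2} "
                         f"AIC={r['aic']:8.2f}  dAIC={r['delta_aic']:6.2f}")
        lines.append("Best-model parameters:")
        for _, r in g["vb_params"].iterrows():
            lines.append(f"  {r['population_id']}: Linf={r['Linf']:.1f} cm "
                         f"K={r['K']:.3f}/yr t0={r['t0']:.2f} yr")
        lines.append("")
    if "diet" in bundle:
        lines.append("Diet (per population):")
        for _, r in bundle["diet"]["summary"].iterrows():
            lines.append(
                f"  {r['population_id']}: I%={r['vacuity_pct']:.0f} "
                f"fullness={r['mean_fullness']:.0f}±{r['sd_fullness']:.0f} "
                f"H={r['mean_H']:.2f}±{r['sd_H']:.2f} "
                f"ellipse={r['nmds_ellipse_area']:.2f}")
        p = bundle["diet"]["permanova"]
        lines.append(f"  PERMANOVA: F={p.pseudo_F:.2f} R2={p.r_squared:.2f}"
                     f" p={p.p:.4f}")
        lines.append("")
    if "isotope" in bundle:
        lines.append("Isotopes (per population):")
        for _, r in bundle["isotope"]["summary"].iterrows():
            lines.append(
                f"  {r['population_id']}: d15N={r['d15N_mean']:.1f}"
                f"±{r['d15N_sd']:.1f} TP={r['tp_median']:.1f} "
                f"({r['tp_ci_lo']:.1f}-{r['tp_ci_hi']:.1f}) "
                f"SEA_B={r['sea_b_median']:.2f} "
                f"({r['sea_b_ci_lo']:.2f}-{r['sea_b_ci_hi']:.2f})")
        lines.append("")
    if "community" in bundle:
        lines.append("Community metrics:")
        for _, r in bundle["community"]["metrics"].iterrows():
            lines.append(f"  {r['site_id']}: density="
                         f"{r['total_density']:.2f}/m2 "
                         f"richness={r['richness']} "
                         f"H={r['shannon_H']:.2f}")
    return "\n".join(lines)
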