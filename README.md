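# fishtroph

Growth, diet and stable-isotope trophic analysis for riverine fish
populations, built to compare purebred and introgressed (hybrid)
populations of *Barbus* species after invasion by a congener.

When an invasive species hybridises with a native congener, the
introgressed populations may grow differently and occupy a different
trophic niche than their purebred parents. `fishtroph` implements the
complete quantitative toolchain used to test this:

- **Growth** — von Bertalanffy curves `TL = L∞(1 − exp(−K(t − t0)))`
  fitted to population mean length-at-age under all 8 ways of sharing
  (L∞, K, t0) across populations, ranked by least-squares AIC
  (`n·ln(SSE/n) + 2(k+1)`); log₁₀ length–weight regressions
  (`log₁₀W = a + b·log₁₀TL`) with t-tests against isometry (b = 3),
  ANCOVA across populations, and residual body condition with ANOVA.
- **Diet (gut contents)** — the relative-fullness method: vacuity index
  I%, mean fullness, prey-specific abundance vs occurrence (Costello
  feeding-strategy statistics, `Fi% = Nᵢ/N·100`,
  `Pi% = ΣSᵢ/ΣSₜᵢ·100`), per-fish Shannon H, arcsine-√ transform,
  Bray–Curtis distances, nMDS ordination with 40 % (standard) core-niche
  ellipses, PERMANOVA, SIMPER and exact sample-based prey accumulation
  curves.
- **Isotopes** — pooled macroinvertebrate baseline (λ = 2); per-fish
  trophic position `TP = λ + (δ¹⁵N_fish − δ¹⁵N_BMI)/Δ¹⁵N` with
  Δ¹⁵N = 4.2 ± 0.2 ‰; a Bayesian one-baseline TP model (MCMC); corrected
  carbon `C_corr = ((δ¹³C_fish − Δ¹³C) − δ¹³C_BMI)/CR_BMI`; standard
  ellipse areas SEA = π√det(S) with a conjugate Bayesian counterpart
  SEA_B, posterior comparisons and niche-overlap estimation.
- **Community** — Moran–Zippin two-pass removal abundance
  `N̂ = C1²/(C1 − C2)`, densities per m², richness, Shannon H and
  Bray–Curtis dissimilarity between sites.
- **Simulation** — a generator that reproduces the study's statistical
  structure (4 populations, 2 purebred / 2 introgressed, shared K,
  population-specific L∞, Dirichlet diets with population-specific
  vacuity, bivariate-normal isotope niches above normal baselines), so
  every stage is testable without the unpublished field data.

Lengths are centimetres, weights grams, isotope ratios per-mil.

## Worked example

Run the full pipeline on the bundled four-population study
configuration (PVp/TLp purebred, PVi/TLi introgressed):

```bash
fishtroph run --seed 42 --outdir results/ --tdf-c 1.5
```

which prints (abridged):

```
Growth model selection (AIC ascending):
  shared:K                 k= 9 AIC=  -26.90  dAIC=  0.00
  shared:none              k=12 AIC=  -23.90  dAIC=  3.00
  shared:Linf              k= 9 AIC=  -20.04  dAIC=  6.86
  ...
Best-model parameters:
  PVi: Linf=48.3 cm K=0.210/yr t0=-0.50 yr
  PVp: Linf=35.7 cm K=0.210/yr t0=-1.23 yr
  ...
Diet (per population):
  TLi: I%=21 fullness=35±24 H=1.08±0.21 ellipse=0.14
  TLp: I%=0 fullness=86±9 H=1.75±0.11 ellipse=0.02
  PERMANOVA: F=13.73 R2=0.37 p=0.0010
Isotopes (per population):
  PVi: d15N=10.8±1.1 TP=3.0 (2.8-3.2) SEA_B=1.69 (1.00-3.20)
  TLi: d15N=13.0±0.9 TP=2.6 (2.4-2.8) SEA_B=3.73 (2.21-7.11)
  ...
```

Reading the output: the AIC ranking selects the model with a growth
coefficient K shared across populations but population-specific
asymptotic lengths — the introgressed populations (PVi, TLi) reach
larger L∞ than their purebred parents. The TLi hybrids show the
highest vacuity (21 %), the lowest gut fullness and diet diversity, yet
the *widest* diet-niche ellipse (0.14) — a few individuals specialise
on fish and plants — and correspondingly the widest isotopic niche
(largest SEA_B) at the lowest trophic position (TP ≈ 2.6 vs ≥ 2.9
elsewhere). `--tdf-c` is the tissue-specific carbon discrimination
factor, which has no defensible universal default and must be supplied.

Per-stage subcommands (`fishtroph simulate/growth/diet/isotope/
community`) expose the same analyses on your own CSV tables; see
`fishtroph --help` and the column schemas in `fishtroph/io.py`.

## Library use

```python
from fishtroph import RunConfig, run_all
from fishtroph.isotope import pool_baseline, tp_bayes

bundle = run_all(RunConfig(outdir="out", seed=1, tdf_c=1.5))
bundle["isotope"]["summary"]          # Table of TP medians, SEA_B CIs…
```

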