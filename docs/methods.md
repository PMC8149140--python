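# Methods

This note documents the statistical models implemented in `fishtroph`,
the choices made where the methodology was genuinely open, and what the
simulation-based tests do and do not establish.

## Units and data model

Lengths are stored in centimetres and weights in grams; the CSV schemas
name the unit in the column (`total_length_cm`, `weight_g`). Published
parameter magnitudes for this system (asymptotic lengths of 34–46,
length–weight intercepts of ~0.011–0.016 g·cm⁻ᵇ) are dimensionally
consistent only with centimetres, even though field protocols usually
record millimetres; ingest code must convert. Isotope values are per-mil
(‰) against the international standards; `C_corr` is dimensionless
(units of the baseline carbon range).

Gut contents use the relative-fullness convention: a fish's fullness is
0–100 % of gut volume and the per-category volume percentages sum
exactly to the fullness. An empty gut (fullness 0, no items) enters the
vacuity index and, by default, mean fullness, but never any
compositional statistic.

## Growth

Von Bertalanffy curves are fitted to **population mean length-at-age**
(not individual fish; `fit_vb` accepts per-fish rows for an
individual-level fit, but no pipeline path uses that), with age classes
above `max_age` (default 4)
excluded so every population contributes the same age range. All eight
ways of sharing (L∞, K, t0) across populations are fitted and ranked by
the least-squares AIC `n·ln(SSE/n) + 2(k+1)`, counting the error
variance as a parameter; ΔAIC < 2 is flagged "indistinguishable" in the
report but the ranking stays strict, with exact ties (fits at the
numerical noise floor, SSE < 1e-8) broken by parsimony.

Optimisation is bounded trust-region least squares with an analytic
Jacobian, started from L∞⁰ = 1.1·max TL, K⁰ = 0.3, t0⁰ = 0 plus
jittered restarts. During model selection the structures are fitted from
most- to least-shared and every less-shared fit is additionally seeded
with the solutions of the structures nested inside it. Because the
optimiser never ends above its starting cost, SSE is monotone along
every nested chain *by construction* — the nesting property is
guaranteed, not hoped for. SSE is unweighted across age means (per-age
sample sizes are available behind `weighted=True`). Standard errors come
from the Gauss–Newton covariance at the optimum.

A caution on identifiability: over a short age range (0–4 years) a
common-L∞/free-K/free-t0 model can track four distinct von Bertalanffy
curves to within a fraction of a centimetre, so with ~1 cm noise on age
means, AIC cannot reliably distinguish it from the generating
shared-K structure (both have the same parameter count, leaving only an
SSE contest that the true structure wins barely more than half the
time). Model selection at this design is trustworthy only when the
noise on age means is small relative to the ~0.8 cm² structural
lack-of-fit — e.g. when means are computed from many fish per age.

Length–weight relations are OLS on log₁₀ scales; `a` is reported
multiplicatively (W = a·TLᵇ). Isometry is tested by
t = (b − 3)/SE(b) with n − 2 df. The ANCOVA compares the common-slope
model (population intercepts + one slope) against population-specific
slopes with a partial F-test. Body condition is the log₁₀ residual from
the LWR; the default back-calculates each fish from **its own
population's** LWR (residual means are then ~0 by OLS orthogonality and
the ANOVA is a within-population spread comparison), with
`mode="pooled"` for the cross-population contrast — the published
analysis is ambiguous between the two, so both are available and
labelled.

## Diet

Fi% uses fish with gut contents as the denominator; Pi% divides a
category's total volume by the total volume of **only those guts that
contain it** (the prey-specific abundance of the Costello method as
modified for feeding-strategy plots). Shannon H uses natural log
(configurable base).

Compositions for transforms and diversity are each fish's item volumes
divided by its own fullness (`denominator="hundred"` divides by 100
instead; the choice is not documented in the source methodology, so both
exist and the compositional view is the default). Multivariate analyses
run on arcsine-√-transformed compositions: Bray–Curtis distances →
PERMANOVA and nMDS; SIMPER runs on the same transformed matrix by
default (raw-scale SIMPER behind a flag).

PERMANOVA partitions the squared distances (SS_total = Σd²/n, within
groups analogously), with p = (#{F* ≥ F} + 1)/(n_perm + 1) under
unrestricted label permutations (999 by default, seed mandatory). In the
univariate-Euclidean case the pseudo-F equals the classical ANOVA F
exactly. SIMPER averages each category's share of the Bray–Curtis
numerator over cross-group pairs; per-pair contributions sum to the
pair's mean dissimilarity as an algebraic identity.

nMDS minimises Kruskal stress-1 by alternating isotonic regression of
configuration distances on dissimilarity ranks with a Guttman
(majorisation) update; 20 starts (1 classical-MDS + 19 random), 500
iterations maximum, stress tolerance 1e-6. Stress-1 is scale-invariant,
so each iteration renormalises the configuration to the dissimilarity
scale (otherwise the solution drifts toward the origin and downstream
ellipse areas lose meaning); the final configuration is centred and
rotated to principal axes with a deterministic sign convention.

"40 %" core-niche ellipses are Mahalanobis radius-1 standard ellipses of
the group's mean and covariance — for a bivariate normal they contain
1 − e^(−1/2) ≈ 39.35 % of the mass — with area π√det(S); they are not
empirically trimmed 40 % hulls. Ellipse overlap integrates the joint
membership indicator on a grid (default 1500², well under 0.5 % error on
lens-shaped intersections).

Prey accumulation curves use the exact sample-based rarefaction
formula E[S(m)] = S_obs − Σᵢ C(N−Nᵢ, m)/C(N, m), evaluated through log
gamma functions.

## Isotopes

Samples with C:N > 3.5 are flagged, never arithmetically corrected (the
screening rule for lipid bias in animal tissue). All macroinvertebrate
baseline samples at a site are pooled into a single baseline at trophic
level λ = 2; its carbon range CR = δ¹³C_max − δ¹³C_min comes from the
same pooled set.

The Bayesian trophic-position model is the one-baseline formulation:

    consumer δ¹⁵N ~ Normal(μ_b + Δ¹⁵N·(TP − λ), σ)
    baseline δ¹⁵N ~ Normal(μ_b, σ_b)
    TP ~ Uniform(λ, 8);  Δ¹⁵N ~ Normal(4.2, 0.2) ‰
    σ, σ_b ~ Half-Normal(0, 2);  μ_b ~ Normal(m̄_b, 10) (weak)

The prior on μ_b is deliberately weak: the pooled baseline data already
enter through the likelihood, and centring an *informative* prior on the
same data would double-count them and shrink credible intervals below
nominal coverage. The default Δ¹⁵N (4.2 ± 0.2 ‰) is the scale-tissue
value for barbel on an invertebrate diet; Δ¹³C has no comparable
published value and is a required input with no default. Sampling uses
the emcee affine-invariant ensemble (20 walkers, vectorised
log-posterior, 600 burn-in steps, thinning 4) retaining 10⁴ draws;
split-R-hat across walkers > 1.1 raises a warning on the result.
Simulation calibration: with n = 10 consumers, σ = 0.5 ‰, the 95 %
credible interval covers a true TP = 3 in ≈ 96/100 datasets with median
bias ≈ 0.01 (recomputed by `scripts/acceptance.py`).

SEA_B uses a vague conjugate Normal–Inverse-Wishart prior (ν₀ = 3,
scale 10⁻³·I): the covariance posterior is Inverse-Wishart and is
sampled exactly — no tuning, no convergence issues — with each draw
mapped to π√det. Posterior comparisons report P(A > B) over draws, with
≥ 0.95 (or ≤ 0.05) read as a significant difference, mirroring an
α = 0.05 convention.

Deterministic TP and C_corr are the closed formulas above; both are
invariant to common shifts of fish and baseline values, as the formulas
require.

## Community

The two-pass removal estimator N̂ = C1²/(C1 − C2),
p̂ = (C1 − C2)/C1, SE² = C1²C2²(C1+C2)/(C1−C2)⁴ assumes a closed
population and equal catchability across passes — exactly what the
bundled generator simulates (binomial thinning of survivors). When
C2 ≥ C1 the estimator is undefined; a `DepletionError` carries the
minimum-known-alive fallback C1 + C2 with an explicit flag. The
estimator equals the maximiser of the classical continuous-N (Stirling)
removal profile log-likelihood (`removal_loglik`); note that an exact
integer-N likelihood has its mode a few counts lower — a discreteness
correction, not a defect of either formulation. Site metrics are total
density (ind/m²), taxon richness and Shannon H; between-site
dissimilarity is Bray–Curtis on count vectors over the shared taxon
universe.

## The synthetic-data generator

`default_study_configs()` encodes the four study populations. Published
quantities are carried as-is: asymptotic lengths 34.4/45.7/35.9/41.1 cm
with shared K = 0.24/yr and the published t0s; LWR coefficients and
sample sizes (41/72/44/141 fish); gut sub-sample sizes (20/20/22/19),
vacuity levels (10/10/0/21 %), fullness distributions matched to the
reported means ± SDs via Beta parameters; isotope means per population;
introgressed populations truncated at age 4+ (PVi) and 3+ (TLi).

Quantities the source tables do not print were fixed once at values a
field ecologist would call realistic, and are **not** tuning dials:

- within-age length spread: multiplicative CV 0.08 on the curve mean
  (giving length-at-age SDs of ~1–2 cm, like typical error bars for
  this system); ages are evaluated at age + 0.5 yr (July sampling,
  mid growth season) — without this offset a population with t0 > 0
  would have negative mean length at age 0;
- LWR scatter σ_log10 = 0.04 (reproduces R² ≥ 0.96);
- Dirichlet diet concentrations: benthivore profiles dominated by
  Chironomidae/Simuliidae for PVp/PVi, a tighter, more even profile for
  TLp (highest H), and for TLi a low-total-concentration profile with
  piscivory (fish bones) and plant categories that are absent elsewhere
  — low total concentration means high between-fish variance, which is
  what widens the TLi diet niche;
- isotope covariances: the published bulk SDs (0.9–1.2 ‰) and the
  published ellipse areas (0.04–0.50 ‰²) cannot both describe the same
  raw data (the areas evidently come from corrected values), so the
  generator keeps the published means and encodes the *ratio* of niche
  widths instead: correlation 0.7 with the published marginal SDs for
  PVp/PVi/TLp, and an inflated uncorrelated covariance (σ = 1.6, 2.0 ‰)
  for TLi, reproducing the reported ~4–12× TLi contrast;
- baseline δ¹⁵N means are back-computed from the published trophic
  positions through TP = 2 + (δ¹⁵N_fish − δ¹⁵N_BMI)/4.2 (3.0/6.6/4.9/
  10.7 ‰ — the strong ¹⁵N enrichment at the TLi site is a reported
  feature), with SD 0.5 ‰ and n = 14 per site; baseline δ¹³C SDs give
  plausible site carbon ranges (~1.6–6 ‰);
- removal sampling uses capture probability 0.6 per pass; transect
  areas follow the published river widths × transect lengths.

Every table draws from its own named random stream derived from
(seed, population, table), so regenerating one table never perturbs
another, and identical (config, seed) pairs are bit-reproducible.

**What the generator does not emulate:** real gut compositions are not
Dirichlet (they have structural zeros and prey-size effects), isotope
clouds need not be bivariate normal, capture probability varies between
passes in real electrofishing, and growth variation is not purely
multiplicative. Passing calibration tests on this generator shows the
*estimators* are correct and calibrated under their stated assumptions;
it cannot show the assumptions hold for any particular river.

## Pipeline

`run_all` derives one sub-seed per stage from the global seed (stage
name keyed), so toggling a stage never changes another stage's stream;
rerunning a config + seed reproduces all CSV outputs byte-for-byte. The
isotope stage refuses to start without a carbon discrimination factor.
Reported problem sizes in the acceptance script (100 selection
replicates, 1000 isometry replicates, 500 PERMANOVA null datasets with
199 permutations, 100 TP calibration datasets at 4×10³ retained draws,
10⁶ Monte-Carlo points for ellipse coverage) were chosen as the smallest
runs at which the Monte-Carlo error is comfortably below the margins
being checked.

## Known limitations

- Growth model selection near-equivalence over short age ranges (see
  above): with few age classes and noisy means, AIC ranks among the
  equally-sized sharing structures close to chance; report ΔAIC, not
  just the winner.
- The Bayesian TP model is single-baseline by design; systems where
  littoral/pelagic carbon pathways must be separated need a two-baseline
  model that is out of scope here.
- SEA_B's vague conjugate prior shrinks areas by roughly (n−1)/n at
  small n; at n = 10 the posterior median sits visibly below the ML
  area. This matches the behaviour of standard Bayesian ellipse
  estimators but should be remembered when comparing across sample
  sizes.
- nMDS stress near 0.2 (typical for ~70 fish diet matrices) means the
  2-D configuration is a coarse summary; ellipse areas from it are
  comparative, not absolute.
- No lipid-normalisation arithmetic, no mixing models, no open-population
  or k > 2 pass removal designs in the public API.
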