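# Methods

This note documents the statistical models, the synthetic-data generator, and
the numerical and design choices behind `reefmpa`.

## Data model

Surveys are replicate 7 m-radius point counts (area π·7² ≈ 153.94 m²) nested
in reef × year. Fish records are one row per (species, length-to-nearest-cm)
with a count; benthic records are one row per replicate with percent cover of
six substrate categories and an ordinal 0–5 structural-complexity score.
Cover sums may fall below 100 (unscored substrate) and up to 100.5 (rounding);
anything larger is rejected. Every species must carry length–weight
coefficients (a > 0, 2 ≤ b ≤ 4) and a trophic group. Records with a count but
no length are rejected rather than imputed — silent imputation biases biomass.

Biomass: mass per record = count · a·Lᵇ grams; replicate biomass =
Σ grams / area · 10 kg ha⁻¹; the reef-year statistic is the arithmetic mean
over replicates (consistent with per-area units; a sum would scale with
replicate effort). Richness is reported per replicate — a density of species
per ~154 m² — not pooled per reef, because pooled richness confounds effort
with diversity when replicate counts vary (8–16 per reef-year).

## Regime classification

The ecological definition — "macroalgae overtakes coral and stays high" — is
operationalized deterministically: a reef is regime-shifted iff macroalgae >
coral in the final survey year AND macroalgae ≥ coral in at least half of the
post-disturbance years (surveys strictly after 1998). Ties favour
`recovering`, so an all-tied series is conservative about declaring a shift.
Because published labels for real campaigns may come from different upstream
criteria, `sites.csv` may carry a `regime` column that bypasses the rule.

## Reserve effects and the drop-one jackknife

Estimators operate on reef-level values: mean difference (protected − fished),
response ratio (P̄/F̄ − 1)·100, and log response ratio ln(P̄/F̄). The
jackknife is over *sites*, never replicates: each of the 21 reefs is left out
in turn and the chosen estimator recomputed directly (the ratio is jackknifed
on its own scale, not via the log). The reported interval is the min/max of
the leave-one-out estimates. This interval is an *influence diagnostic* — it
shows how much single reefs with exceptionally high or low values move the
estimate — and is systematically narrower than a confidence interval: the
extreme leave-one-out estimate deviates from the full estimate by at most
max|xᵢ − x̄|/(n_group − 1), which for 21 sites is roughly half the standard
error of the estimate itself. Under a true null effect such an interval
contains zero in well under half of repeated campaigns; users needing
calibrated coverage should treat the interval accordingly.

Pre-bleaching (1994) effects pool all 21 reefs; post-bleaching effects are
estimated separately within recovering and regime-shifted strata. Strata
leaving fewer than two reefs in either management group are skipped with a
warning. Pre-bleaching macroalgal cover (negligible everywhere) is excluded
from benthic effect output.

## Hierarchical models

### Recovery models (Normal likelihood)

Response: yᵢ = (post-bleaching biomass or richness) − (the reef's 1994
value), one observation per post-bleaching reef-year. Linear predictor:

μᵢ = β₀,ᵣ + β₁·habitatᵢ + β₂,ᵣ·yearᵢ + β₃·managementᵢ
     + β₄·habitat×yearᵢ + β₅·management×yearᵢ

with habitat (regime-shifted = 1), management (protected = 1) and survey year
mean-centered over the post-bleaching years ({2005…2014} → ±4.5, ±1.5).
β₀,ᵣ and β₂,ᵣ carry partially pooled per-reef deviations
(aᵣ ~ N(0, τ_int), bᵣ ~ N(0, τ_slope)), which absorb temporal correlation
within reefs; partial pooling stabilizes a 21-reef fit where per-reef slopes
from four points would otherwise be wild.

The response is **standardized internally** (z-scored) before fitting and
back-transformed afterwards. N(0, 10) priors are weakly informative only
relative to a unit-scale response; on raw kg ha⁻¹ differences (hundreds) they
would shrink effects severely. Posterior predictions are rescaled to percent
of the pre-bleaching level (0% = pre-bleaching); the denominator for
stratum-level curves and the per-year rate is the stratum-mean 1994 level per
habitat × management cell (per-reef curves would use per-reef baselines).
The per-year recovery rate is the posterior of the stratum slope
(β₂ + β₄·h + β₅·m), back-transformed and divided by the same denominator —
reef-level slope variation is deliberately not folded into this interval,
which therefore describes the stratum mean trend. Curves and rates are
summarized by the posterior median and central 95% interval.

### Trophic models (Gamma likelihood, log link)

Carnivore (piscivore + mixed-diet) and herbivore (grazer + scraper/excavator
+ browser) reef-year biomass is strictly positive and right-skewed, so it is
modelled as Gamma with mean μ and shape k (E = μ, Var = μ²/k); this
mean/shape parameterization maps to the standard one as shape k, rate k/μ.
A log link keeps μ positive and makes management effects multiplicative;
condition summaries are exp of linear-predictor posteriors. The pre-bleaching
design is intercept + management; the post-bleaching design adds habitat,
centered year and the two year interactions. Every fixed effect, the random
intercepts/slopes (per reef × functional group) and the shape k are indexed
by functional group. Condition posteriors (e.g. protected × recovering ×
herbivore) are evaluated at the centered-year origin for a typical reef
(random effects at zero); with a log-normal reef distribution the population
mean would exceed this typical-reef value by exp(τ²/2), a distinction that
matters only if τ is large.

### Priors, parameterization, sampling

* Fixed effects: N(0, 10). Scales (τ, σ): half-Cauchy(0, 2) — the positive
  half of the Cauchy(0, 2) family, since a scale cannot be negative. Gamma
  shape k: Exponential(1), weak on the k ∈ 1–10 range typical of reef-fish
  biomass.
* Random effects use the **non-centered parameterization** u = τ·z with
  z ~ N(0, 1). The centered form produced the classic funnel and R̂ ≈ 1.04;
  non-centering restored R̂ ≤ 1.002 at identical cost.
* Positive parameters are sampled as logs with the change-of-variables
  Jacobian included in the target density.
* Sampler: Hamiltonian Monte Carlo with hand-derived analytic gradients
  (verified against finite differences), a jittered number of leapfrog steps
  (uniform 1–24, breaking periodicity), dual-averaging step-size adaptation to
  a 0.8 acceptance target, and a diagonal mass matrix estimated from the
  middle warmup window (followed by a step-size re-adaptation). Defaults
  mirror the study settings: 7000 iterations, 1500 warmup, 3 chains. All
  randomness flows from one integer seed through `numpy.random.SeedSequence`;
  reruns are bit-identical. Non-finite log densities reject the proposal;
  post-warmup energy errors above 1000 are counted as divergences and
  reported.
* Convergence: split R̂ and effective sample size per parameter (via arviz);
  a fit passes when every |R̂ − 1| ≤ 0.01. Summaries use post-warmup draws
  only. Trajectory predictions subsample 1000 posterior draws.
* The headline curve summary is the posterior **median**; medians and means
  differ negligibly for these near-symmetric posteriors but the median is
  robust to the Gamma models' skew.

## Synthetic-data generator

The generator emulates the monitoring design so that every pipeline stage can
be tested against known truth: 21 reefs in the 7/5/5/4
management × regime layout, survey years {1994, 2005, 2008, 2011, 2014},
8–16 replicates per reef-year, 134 species in 16 families covering all seven
trophic groups with lw_a ∈ [0.005, 0.05], lw_b ∈ [2.8, 3.2].

Calibration is exact in expectation. Each species is present in a replicate
with probability p (shared within its trophic group); a present species
contributes 1 + (gamma-mixed Poisson) individuals, i.e. negative-binomial
overdispersion (mixing variance 0.5), at a length drawn from a discrete
±20% grid around its typical length. Because expected richness is then
exactly Σp and expected group biomass is exactly Σ p·E[count]·E[mass] (with
E[mass] computed from the same length grid and coefficients used for
drawing), the two knobs (presence, conditional count mean) are solved from
the biomass and richness targets; richness is water-filled across groups
subject to each group's biomass-feasibility cap, and genuinely infeasible
target combinations raise an error rather than silently degrade.

Ground-truth defaults are the study conditions: a 1.75× reserve multiplier on
every group pre-bleaching (a +75% total-biomass effect); richness 25 species
per replicate on fished reefs and 35 on protected (+10); fished pre-bleaching
group baselines (65/83/75/57/20/25/5 kg ha⁻¹) chosen so the protected
carnivore and herbivore pools equal 259 and 266 kg ha⁻¹; post-bleaching total
biomass following linear percent-of-pre-level trajectories with slopes
7/4/2/0% yr⁻¹ (fished-recovering / protected-recovering / fished-shifted /
protected-shifted) reaching +79/52/38/0% by 2014; richness slopes
3/2/0.9/−0.2% yr⁻¹; regime-specific post-bleaching trophic composition
(scrapers dominant on recovering reefs, browsers on shifted reefs); benthic
trajectories with +15 percentage points of pre-bleaching coral in reserves, a
1998 collapse, then piecewise-linear coral recovery (12→32%) or macroalgal
takeover (22→42%); and lognormal reef-level heterogeneity (σ = 0.12 biomass,
0.05 richness) constant within reef across years, acting as the reef
intercept the models partially pool.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: species-level abundance distributions and rarity
structure, size spectra within species, observer and detectability error,
temporal autocorrelation beyond a constant reef effect, spatial structure
among reefs, and management-dependent post-bleaching trophic composition.
Estimator checks on this generator validate arithmetic and statistical
machinery, not ecological realism.

## Numerical choices and degenerate inputs

* Aggregations zero-fill replicates that have benthic records but no fish
  (an empty point count is informative, not missing); reef-years with no
  replicates at all are excluded with a warning.
* Group biomasses partition totals to ~1e−9 relative; tests enforce this.
* The jackknife requires ≥2 sites per management group (dropping a site must
  not empty a group); classification requires ≥2 post-disturbance years.
* Gamma designs reject non-positive biomass rather than nudging it, keeping
  the likelihood's support honest.
* A zero-variance response (degenerate standardization) falls back to scale 1.

## Problem sizes used in checks

The bundled checks run the models at reduced but converged MCMC sizes
(e.g. 1500–4000 iterations, 2–3 chains) and the parameter-recovery experiment
at 50 replicates of the 21-reef design; the CLI defaults remain the full
7000/1500 × 3 configuration.

## Known limitations

* The jackknife min/max interval is not a confidence interval (see above);
  the package reports it because it is the design's standard summary, not
  because it has frequentist coverage.
* Percent-recovery denominators and rate intervals are stratum-level choices;
  alternative conventions (per-reef denominators, slope-variation-inclusive
  intervals) would widen or shift the printed rates.
* No model comparison (WAIC/LOO), no spatial or temporal autocorrelation
  beyond reef-level terms, no uncertain/intermediate regime class, and no
  bootstrap or Bayesian alternative to the jackknife — all out of scope.
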