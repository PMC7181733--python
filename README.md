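# reefmpa

Do no-take marine reserves keep working after climate-driven coral bleaching?
`reefmpa` is a Python package for analysing long-term underwater visual census
(UVC) monitoring of coral-reef fish and benthos under a
before–after-control-impact design: protected vs. fished reefs surveyed before
and repeatedly after a mass bleaching event, with reefs diverging into
coral-**recovering** and macroalgal-**regime-shifted** trajectories.

It is written for reef ecologists and quantitative conservation scientists who
have (or want to simulate) reef × year × replicate survey tables and need the
full inference chain as tested, reusable code.

## What it computes

1. **Biomass construction** (`reefmpa.biomass`). Fish counts and lengths become
   areal biomass through the length–weight allometry *W = a·Lᵇ* (g, cm), summed
   over each 7 m-radius point count (~154 m²) and scaled by
   1 g m⁻² = 10 kg ha⁻¹; species richness is counted per replicate. Trophic
   groups (piscivore, mixed-diet, scraper/excavator, grazer, browser,
   planktivore, corallivore) partition the total; carnivores = piscivores +
   mixed-diet, herbivores = grazers + scrapers/excavators + browsers.
2. **Regime classification** (`reefmpa.regime`). A reef is *regime-shifted*
   when post-disturbance macroalgal cover exceeds hard-coral cover in the final
   survey year and in at least half of the post-disturbance years; otherwise
   *recovering*. Externally supplied labels can bypass the rule.
3. **Reserve effects with drop-one jackknife** (`reefmpa.reserve_effects`).
   For any reef-level variable: the mean difference protected − fished, the
   response ratio (P̄/F̄ − 1)·100%, or its log. Uncertainty is the min/max of
   the 21 leave-one-site-out estimates per survey year. Pre-bleaching effects
   pool all reefs; post-bleaching effects stratify by regime.
4. **Bayesian hierarchical models** (`reefmpa.hier_models`). Two families,
   sampled by Hamiltonian Monte Carlo with analytic gradients:
   * a Normal model of each reef's *recovery* — the absolute difference
     y = (post-bleaching value) − (1994 value) of biomass or richness —
     with fixed effects μ = β₀ + β₁·habitat + β₂·year + β₃·management +
     β₄·habitat×year + β₅·management×year (year mean-centered) and partially
     pooled per-reef intercepts and year slopes; predictions are rescaled to
     percent of the pre-bleaching level (0% = pre-bleaching);
   * Gamma(mean μ, shape k) models of carnivore/herbivore biomass with a log
     link — management-only pre-bleaching, the full habitat × year ×
     management design post-bleaching — every coefficient indexed by
     functional group.
   Priors are weakly informative (fixed effects N(0, 10), scales
   half-Cauchy(0, 2), Gamma shape Exponential(1)); defaults are 7000
   iterations (1500 warmup) × 3 chains, and convergence requires every split
   R̂ within 0.01 of 1.
5. **Synthetic campaigns with known truth** (`reefmpa.synthetic_data`).
   A generator that reproduces the monitoring design — 21 reefs (9 protected /
   12 fished; 7+5 recovering, 5+4 regime-shifted), years
   {1994, 2005, 2008, 2011, 2014}, 8–16 replicates per reef-year, 134 species
   in 16 families — with exactly calibrated expected biomass and richness, so
   every estimator can be checked against ground truth.

## Worked example

```bash
reefmpa run-all --seed 1 --out demo_out
```

simulates a default campaign, summarizes it, classifies regimes, estimates
jackknifed reserve effects and fits all four models. Excerpts of the printed
report (seed 1):

```
Management x regime design:
regime      recovering  regime_shifted
fished               7               5
protected            5               4

Pre-bleaching reserve effects (response ratio %, [drop-one jackknife min, max]):
  total_biomass              +89%  [  +83,   +95]
  richness                   +41%  [  +40,   +43]

Posterior recovery rates (% of pre-bleaching level per year, median [95% CI]):
  biomass   recovering      fished      +8.8 [ +6.6, +11.0]
  biomass   recovering      protected   +4.0 [ +2.6,  +5.5]
  biomass   regime_shifted  fished      +0.2 [ -2.6,  +3.0]
  biomass   regime_shifted  protected   -0.8 [ -2.3,  +0.7]

Carnivore/herbivore biomass posteriors (kg/ha, median [95% CI]):
  pre   pre             protected  carnivore   266 [ 211,  344]
  pre   pre             protected  herbivore   270 [ 211,  353]
  post  recovering      protected  herbivore   452 [ 402,  509]

Convergence:
  recovery_biomass     PASS (max R-hat 1.0006, min ESS 4592)
```

Reading it: before bleaching this simulated world has ~75–90% more fish
biomass inside reserves (the generating truth is +75%; a single 21-reef
campaign scatters around it), protected carnivore and herbivore pools near
260–270 kg ha⁻¹, and post-bleaching biomass re-accumulating fastest on fished
recovering reefs (truth 7% yr⁻¹) and not at all on protected regime-shifted
reefs (truth 0% yr⁻¹) — the posterior medians and intervals recover those
conditions. Each estimate's bracket is the drop-one jackknife range
(frequentist contrasts) or the 95% certainty interval (posteriors).

The same stages are available piecemeal (`reefmpa simulate | summarize |
classify | effects | fit-recovery | fit-trophic`) and as library calls; real
survey data enter through four CSVs (`sites.csv`, `fish.csv`, `benthic.csv`,
`traits.csv` — see `reefmpa.survey_io`).

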