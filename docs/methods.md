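# Methods

## The model

`latdiv` simulates the diversification of a single clade along a
one-dimensional thermal gradient of `n_regions = 10` adjacent regions whose
environments descend linearly from 40 °C (region 1, the "tropical" end) to
0 °C (region 10, the "temperate" end).  The region index doubles as the
latitude proxy in all diagnostics, so a classical latitudinal richness
gradient appears as a *negative* latitude–richness correlation.

Each species carries a single heritable trait, its thermal optimum
(°C).  Its performance in region *k* is the Gaussian environmental-filter
weight

    w_ik = exp( -(τ_i - E_k)² / (2 ω²) )

with τ_i the species' optimum, E_k the regional environment and ω the
filter SD.  Time advances in discrete steps; within each step, in fixed
order:

1. **Population allocation.**  Populations are *attained*, not grown:
   under the zero-sum constraint region *k*'s carrying capacity K_k is
   split among its residents in proportion to their weights,
   N_ik = round(K_k · w_ik / Σ_j w_jk); without the constraint (the pure
   niche-conservatism scenario) every resident independently realises
   N_ik = round(K_k · w_ik), so individuals and species can accumulate
   without bound.  Rounding is half-to-even; a resident whose allocation
   rounds to zero is immediately locally extinct.
2. **Disturbance** (disturbance scenario only): every
   `disturbance_frequency` steps a fraction m_k of every population in
   region *k* is killed.  A population rounded to zero by the event is
   locally extinct outright — otherwise the next allocation phase would
   rebuild it from weights and the event would be a no-op for small
   populations.
3. **Speciation.**  Each population spawns Binomial(N_ik, p_k) daughter
   species; a daughter inherits the parental optimum plus a
   Normal(0, σ_E) deviation (niche conservatism) and is resident only in
   the parent's region.  It enters the allocation pool the next step.
4. **Dispersal.**  A species colonises an adjacent region it does not
   occupy when Binomial(N_ik, p_dispersal) ≥ 1, i.e. with probability
   1 − (1 − p)^N per occupied neighbour per step.
5. **Extinction.**  Each population dies with probability
   exp(−alpha_ext · N_ik); a species with no populations left is globally
   extinct, permanently.

A single seeded PCG64 generator drives all draws; rows are kept in
species-id order and regions are processed in index order, so a (config,
seed) pair reproduces a run bit-for-bit.

## Scenarios

The four presets vary one axis each while sharing the gradient geometry,
σ_E = 1 °C, and (for the three zero-sum presets) the same global number of
individuals, Σ_k K_k = 220,000:

| preset        | K per region      | p_speciation        | disturbance           | zero-sum |
|---------------|-------------------|---------------------|-----------------------|----------|
| `pure_nc`     | 40,000            | 1e-6                | —                     | no       |
| `energy`      | 40,000 → 4,000    | 1e-6                | —                     | yes      |
| `speciation`  | 22,000            | 3.2e-6 → 3.2e-7     | —                     | yes      |
| `disturbance` | 22,000            | 1e-6                | kills 75% → 99% / event | yes    |

Ranges read tropical end → temperate end.  Pure-NC runs stop once extant
richness exceeds 10,000 species (a few hundred steps); zero-sum runs
default to 100,000 steps.

## Package-owned parameters

Four knobs are not part of the published scenario table and are owned by
this package.  They were calibrated once, before the test suite was
frozen, against three behavioural requirements: the pure-NC runs must
reproduce the ±1.0 latitude–richness correlations at the richness stop;
zero-sum runs must colonise all ten regions well before 15,000 steps; and
equilibrium regional richness must be O(10–100) species.

* `omega = 1.2 °C` — the environmental-filter SD.  This is the main
  control on how many regions a species' realised range spans.  Wider
  filters (ω ≳ 2.5) let nearly every species register presence in the
  first three regions of a pure-NC run, flattening the richness profile
  into a plateau and weakening the gradient correlation to ≈ −0.93;
  narrower ones (ω ≲ 1.1) confine each species so tightly that marginal
  single-species stragglers dominate the occupied-region profile.  The
  default was selected on a 40-seed panel of pure-NC runs from both
  origins as the value whose gradient correlation is most stably at ±1.0
  after rounding.
* `p_dispersal = 3e-6` per individual per step.  Together with ω this
  sets the pace of range expansion.  It is deliberately of the same order
  as the per-lineage speciation rate, so colonisation of a neighbouring
  region is a meaningful event rather than instantaneous; with the
  founder population of 40,000 the per-step colonisation probability of
  an adjacent empty region is ≈ 0.11.
* `alpha_ext = 0.01` per individual.  Populations below ≈ 100 individuals
  face substantial per-step extinction risk; populations above ≈ 1,000
  are effectively safe.  This yields equilibrium richness of roughly 30–80
  species per region under K = 22,000–40,000 and, importantly, enough
  turnover that tip-level rate estimators reflect current conditions
  rather than colonisation history.  (Larger values, e.g. 0.03, raise
  richness and stabilise tree-shape statistics but freeze deep lineages in
  place, which suppresses the rate–latitude trend of the
  speciation-gradient scenario.)
* `disturbance_frequency = 100` steps — frequent relative to species
  lifetimes, so the disturbance gradient acts as a press of elevated
  temperate mortality rather than rare catastrophes.

## Diagnostics

All correlations run over occupied regions only, and statistics that are
undefined (too few occupied regions, zero variance) are NaN, never 0.

* **Latitude–richness correlation** — Pearson r of (region index,
  richness).  Two occupied regions suffice (r is then ±1; early in a
  clade's spread the sign is the whole story).
* **Time–richness correlation** — Pearson r between regional occupancy
  time (observation time minus the earliest colonisation time among the
  region's *extant* residents; local extinction erases tenure) and
  richness; needs ≥ 3 occupied regions.
* **MRD–richness slope** — per region, the mean number of internal nodes
  between root and resident tips, divided by the tree-wide maximum root
  distance (so values lie in (0, 1]); the reported statistic is the OLS
  slope of this scaled MRD on richness (plain richness as the predictor;
  log-richness would be defensible but is not used).
* **β imbalance** — the beta-splitting ML estimate on the extant tree.
  The likelihood of a clade of n splitting into (i, n−i) is
  q_n(i) ∝ Γ(β+i+1)Γ(β+n−i+1) / (Γ(i+1)Γ(n−i+1)), normalised over
  i = 1..n−1; two-tip clades are uninformative.  The optimiser is a
  coarse grid bracket followed by bounded golden-section/parabolic
  refinement to 1e-4 on [−2, 10]; optima pinned to either edge are
  reported as the boundary value with a flag.  β = 0 under the Yule
  model; on finite trees the ML estimate is right-skewed (64-tip Yule
  trees: median ≈ +0.14, mean ≈ +0.38 over 200 simulations), which
  matters when reading small positive values.
* **Tip speciation rates**, two estimators averaged over the species
  present in each region:
  * *equal-splits (DR)*: for root-ward branch lengths l_1 (pendant) … l_d,
    ES = Σ_j l_j 2^−(j−1), rate = 1/ES — a phylogeny-only proxy that
    weights recent branching most.
  * *realized*: the number of speciation events recorded along the tip's
    root-to-tip lineage path (each ancestral segment's budding events
    during its tenure on the path), divided by the elapsed time since the
    clade root.  This is a whole-history average: events acquired while a
    lineage adapted its way across the gradient are never forgotten.  As
    a consequence any clade that reached the far end of the gradient via
    ~σ_E-sized trait steps carries a permanent event surplus, and the
    regional mean of this estimator rises toward the colonisation
    frontier in *every* scenario.  It is therefore a sharp diagnostic
    where the underlying rates reinforce that trend (disturbance) or
    overwhelm it (a strong speciation gradient, given enough turnover),
    but it cannot certify the *absence* of a rate–latitude trend the way
    an instantaneous estimator could.

## Phylogeny construction

Speciation is budding: the parent persists, the daughter branches off.
The reconstructed tree of the extant species at time *t* keeps exactly
the speciation events with surviving descendants on both sides, suppresses
unary passages through extinct ancestors, and measures branch lengths in
steps, so the tree is ultrametric.  Simultaneous daughters of one parent
are attached in species-id order as zero-length binary splits.  The stem
below the first informative split is excluded from all shape statistics.

## What the simulations do and do not show

The generator *is* the study system: there is no external data, and every
reported number is a property of the model under the scenario
parameterisations above.  Passing tests show that the implementation
reproduces the qualitative multi-pattern fingerprints of the four
diversification hypotheses within this model world — they say nothing
about real clades, where gradients are two-dimensional, environments
fluctuate, niches are multivariate, and speciation is not a per-individual
lottery.  Known limitations:

* Regional populations re-equilibrate instantly each step; there are no
  growth dynamics, founder effects, or within-region structure.
* The realized tip-rate estimator's colonisation-history bias (above)
  makes the "no trend under the energy gradient" fingerprint unattainable
  for it; an instantaneous-rate method (e.g. Bayesian rate-shift
  inference, deliberately out of scope) would be required.
* β imbalance on equilibrium-turnover trees of a few hundred tips is
  noisy; the strongly negative β of the zero-sum scenarios is clearest
  while the clade is still spreading (the first ~10,000 steps) and decays
  toward 0 as turnover erases the expansion signature.
* Problem sizes used in the test suite — 25–30k-step zero-sum runs and
  three replicates per scenario — were chosen as the smallest runs that
  reach and comfortably pass the scenarios' equilibria.
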