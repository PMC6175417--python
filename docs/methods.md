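# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of the methods documentation of statsmodels or
msprime: what is computed, under which assumptions, with which defaults, and
what the synthetic validation does and does not demonstrate.

## Data model and filters

Survey data are long-format presence records: one row per
(plot, year, species) with a strictly positive cover percentage of the 1-m²
plot. Absence is encoded by the absence of a row; there is no trace/“+”
code, because the analyses derive presence/absence from the cover estimates
themselves. Since a 1-m² plot equals 100 dm², cover percent and cover in dm²
are numerically identical and no unit conversion is ever applied. Covers are
accepted as arbitrary positive floats (no fixed sub-percent precision is
assumed).

Dataset assembly applies three filters, each logged with counts in the
provenance record:

1. **Coverage** — only plots surveyed in *all* requested campaigns are kept.
   Presence-only records cannot distinguish "not visited" from "visited but
   bare", so the plot-attribute table is the coverage authority: an optional
   `surveyed_years` column restricts coverage explicitly; without it every
   listed plot is assumed visited in every campaign.
2. **Disturbance** — plots disturbed (rockfall, substrate movement) in any
   *requested* year are dropped. Disturbance is evaluated against the
   requested year set only, so a first-and-last-survey dataset can retain
   more plots than the all-surveys dataset built from the same records.
3. **Annual species** — species flagged `is_annual` are removed, because
   their strong inter-annual fluctuation would contaminate colonisation and
   disappearance rates that are meant to track decadal change.

Species identity is an opaque string key; taxonomic normalisation is out of
scope.

## Turnover accounting

Colonisations and disappearances are set differences of the per-plot
occupied-species sets between two surveys. The species universe is the
dataset's observed pool (the occupancy-matrix column set, constant across
years); species never observed in any dataset year contribute no at-risk
trials. Relative rates pool events over all species of an altitudinal rank:
relative colonisation = events / species×plot combinations unoccupied at the
start; relative disappearance likewise over occupied combinations. Pooling
(rather than averaging per-species rates) is the default because the
denominators are then exact event counts and the rates equal the means of
the emitted Bernoulli-trial table by construction; a per-species view is
available as a diagnostic (`pool_species=False`). Species recorded for the
first time in the whole study area are reported in a separate summary, not
excluded from trials.

## Community-weighted indicators

The thermic (altitudinal-rank) and soil-moisture indicators are
cover-weighted mean ranks per plot and survey. Plots with zero total cover
have no defined indicator; they are flagged and excluded from indicator
models rather than imputed, because the weighted mean divides by the cover
sum. Both raw per-plot deltas between consecutive surveys and the
model-based Δ indicator (the mixed-model year-contrast effect size, the
quantity of record) are exposed. A Spearman rank-correlation diagnostic
(midrank ties, via scipy) screens whether the two rank scales are confounded
at the species level.

The equivalence arithmetic translates indicator change into physical units:
one indicator unit ≈ one elevational vegetation belt, so Δ × 100 is the belt
percentage and Δ × belt extent (default 500 m) the elevation equivalent;
temperature trends are rescaled linearly across period lengths and converted
to metres with an environmental lapse rate (default 0.65 °C / 100 m, sign
ignored).

## Inference

All models honour the survey design: plots nested in transects nested in
blocks, resurveyed at decadal intervals. The package owns the
model-selection logic, dispersion statistic, contrast matrices, Tukey
adjustment and letter assignment; the optimisers are delegated to
statsmodels behind a fitting contract, and the backend that actually ran is
recorded in every result's metadata.

- **Gaussian responses** (cover sums, indicators, NMDS axes): `MixedLM`
  (REML) with the outermost level as groups and variance components for the
  inner levels. Fits are parametrised with treatment coding and converted to
  cell means with a contrast matrix (the no-intercept parametrisation is
  poorly conditioned for mixed models). The default optimiser is tried
  first, then Powell; a structure whose fit does not converge cleanly (or
  yields non-finite fixed-effect covariances) is collapsed innermost-level
  first, ending at OLS, each step logged. Any nesting level with fewer than
  two units is likewise collapsed — the standard treatment for subsites
  whose transects contain too few plots. Fixed-effect inference is Wald/z
  (large-sample); the degrees-of-freedom method is recorded in metadata
  rather than asserted.
- **Count and binomial responses**: GEE with working-independence
  correlation, clustered on the innermost surviving level (the plot — the
  dominant repeated-measures correlation) with robust sandwich standard
  errors. A nested exchangeable working covariance was rejected as
  numerically fragile on noise-dominated data; working independence with
  robust errors is consistent under the same clustering and stable.
- **Family selection**: Poisson and negative-binomial fits are compared by a
  1-df likelihood-ratio test (P < 0.05 → negative binomial, which
  accommodates the many zeros of turnover counts). Likelihoods are computed
  on fixed-effects (marginal) GLMs because the clustered estimating-equation
  fits have no likelihood; the chosen family is then used by the clustered
  backend, and the report says so. The chosen fit is screened with the
  Pearson χ²/df statistic; strictly above the threshold (default 1.2) an
  overdispersed Poisson is escalated to quasi-Poisson, i.e. a Poisson fit
  with dispersion-scaled standard errors (full penalised quasi-likelihood
  is a non-goal). A constant response short-circuits the ladder: Poisson
  with zero LRT and a degenerate-fit note, and contrasts return a single
  shared letter without fitting.
- **Pairwise comparison**: all level pairs of the contrast factor are tested
  with single-step Tukey adjustment via the studentized-range distribution
  on the estimated contrast covariance (residual df for OLS, large-sample df
  otherwise). Compact letters use the insert-and-absorb algorithm; two
  levels share a letter iff their pair is non-significant, ties broken by
  input level order with levels ordered by year/decade ascending.
- **Δ–Δ correlation**: the slope of Δ moisture on Δ thermic per plot and
  decade, with crossed random intercepts (block, transect, plot, decade)
  fitted as variance components in a single-group `MixedLM`; the random
  decade term is dropped with a warning when fewer than two decades are
  present, and a zero-variance predictor (frozen dynamics) returns a
  degenerate zero-slope result instead of a singular fit.

## Terrain

Ruggedness is the standard deviation of elevation over all non-nodata cells
whose centres fall in a window × window square (default 100 m) centred on
the plot, read from a plain-text ESRI ASCII grid. The sample (n−1)
denominator is the default; with hundreds of cells per window the choice is
immaterial, and it is configurable (`ddof`). The ordination matrix min–max
rescales surface-type covers, elevation, slope, ruggedness and aspect to
[0, 1]; aspect is circular and is decomposed into northness (cos) and
eastness (sin) before rescaling, which the scaling report flags. NMDS is
commodity ordination and is delegated to scikit-learn's SMACOF
(`metric_mds=False`) on Euclidean distances of the rescaled matrix (the
distance metric is configurable; neither metric nor dimensionality is
asserted as canonical). Because an NMDS axis has arbitrary sign, axis 1 is
oriented to correlate positively with elevation before the block contrast,
making the comparison invariant to backend sign flips.

## Synthetic community generator

The generator emulates a ~350-plot, three-campaign permanent-plot design at
the alpine–nival ecotone. What it models:

- **Design**: 4 blocks × 90 plots in 6 transects each; blocks tile the
  2900–3450 m elevation range in contiguous bands (lowest block first), so
  the marginal plot-elevation distribution is uniform. ~2% of plots are
  marked disturbed in one resurvey year to exercise the disturbance filter.
- **Species pool**: 6/20/18/6 species in altitudinal ranks 1–4 with uniform
  optimum elevations per rank (rank 1 highest). Occupancy probability is a
  Gaussian curve in elevation distance from the optimum (niche breadth
  200 m, ceiling 0.42); baseline cover is lognormal (σ = 0.9) with a
  rank-specific log-mean offset (+1.0, +0.3, −0.3, −0.8) so that cryophilic
  rank-1 species dominate cover at the ecotone while treeline-rank species
  occur only as small individuals, as in real ecotone communities. Moisture
  ranks are drawn independently of altitudinal ranks (the two scales are
  uncorrelated at the species level).
- **Dynamics**: warming is modelled on the elevation axis — species optima
  shift upward 60 m per decade (the lapse-rate view of warming; only the
  plot-vs-optimum displacement matters, and plot attributes keep physical
  elevations). Occupied cells update cover multiplicatively (rank 1 × 0.80,
  rank 2 × 1.20 per decade, truncated at 100%), colonise empty cells with
  probability 0.30 × the shifted occupancy curve (establishing at reduced
  cover, log-mean offset −1.0), and vacate occupied cells with probability
  scale × (1 − shifted curve), the scale starting at 0.05 and tripling per
  decade so a first-decade colonisation excess shifts towards disappearances
  in the second decade.
- **Defaults** were chosen once so that the baseline community falls in the
  plausibility windows of published ecotone resurveys — mean richness
  ~11–14 per plot (declared target window 10–14), plot vegetation cover
  roughly 10–30%, ~2 colonisations and 0.3→1.3 disappearances per plot per
  decade, and a clearly positive thermic drift of ~0.03–0.05 units per
  decade.
- **Reproducibility**: all randomness flows from the config seed through
  positionally indexed draw matrices (one `SeedSequence` spawn per survey
  step and draw purpose), so output is bit-identical for identical
  (config, seed) and independent of iteration order, and the identical
  simulation kernel serves both the survey generator and the truth oracle.

**Truth oracle.** `truth_delta_thermic` integrates the generating process
over a large plot ensemble (default 10⁵ plots, uniform elevations, fixed
internal seed) *conditional on the config's realised species parameters*,
returning per decade the mean paired difference of the cover-weighted
thermic indicator and its Monte-Carlo standard error. Parameter recovery
compares the pipeline's mixed-model year contrast against this truth within
3·√(se²_estimate + se²_MC); the estimate's own standard error dominates that
bound, since the MC error at 10⁵ plots is an order of magnitude smaller.

**What passing tests do not show.** The generator has no spatially explicit
dispersal, no interspecific competition kernel, no demographic structure, no
observer error in cover estimation, and block membership affects only
elevation band — real subsites differ in substrate, ruggedness and species
pools in ways the simulation does not reproduce. Validation on synthetic
data therefore demonstrates the correctness and statistical calibration of
the *pipeline*, not ecological conclusions about any real mountain.

## Problem sizes and numerical conventions

The test suite exercises the chain at 100–360 plots and the truth oracle at
10⁵ replicate plots; the acceptance script uses the full default design
(360 plots before disturbance filtering) and 100 selection replicates at
n = 500 per family. Dispersion threshold comparisons are strict (>).
Indicator equality tests use exact rational equality where the quantities
are ratios of integer counts. Tukey probabilities fall back to a 10⁶ df
studentized range when the backend provides only asymptotic inference.
Zero-cover rows in input CSVs are dropped with a logged count; duplicate
(plot, year, species) rows and plots mapped to two transects or blocks are
hard errors.
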