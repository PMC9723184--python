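# Methods

This note documents the models, defaults and design choices behind
`mangrovesdm`, and what the synthetic test-bed does and does not
demonstrate about real data.

## The analysis lattice

All stages share one planar lattice of square 1-km cells (default 75×75 =
5625 cells, matching the scale of a biosphere-reserve-sized study area of
~5600 grids). Coordinates are planar, registration is cell-center, and
cell membership is half-open — a point on a cell boundary belongs to
exactly one cell — stated once in `grids` and reused everywhere. LULC maps
may be supplied at an integer sub-grid factor (e.g. 30-m pixels under a
1-km cell); per-grid rates then use area fractions.

## Synthetic landscapes and what they emulate

`synthetic` generates the study conditions:

- **Predictors.** 36 layers in 6 groups of 6 (topographic, environmental,
  water, soil, bioclimatic, disturbance), each an independent Gaussian
  random field: white noise smoothed with a Gaussian kernel whose SD in
  cells is the `spatial_autocorrelation_range` (default 6; 0 gives
  white noise), then z-scored. Autocorrelation matters only in that it
  makes spatial rarefaction and pseudo-absence placement non-trivial.
  Layers are independent by default; collinearity tests build correlated
  copies explicitly.
- **Species truths.** Each of the 18 registry species responds
  logistically to two predictors (default +4.0 and −2.5 on the
  standardized layers, landscape prevalence 0.12; the intercept is
  solved so mean suitability equals the prevalence). These defaults were
  chosen so that ensemble evaluation scores on the synthetic data sit in
  the ~0.9 range characteristic of the study system the registry
  describes; weaker contrasts (±1–2) are used in the recovery tests where
  the property under test is stated at that effect size.
- **Occurrences.** Presence-only: n cells drawn without replacement with
  probability proportional to true suitability, placed at cell centers.
  Default per-species sample sizes follow the registry's archival +
  field record counts (707 + 853 over 18 species). No detection bias is
  modelled by default.
- **LULC pair.** The first date is drawn as clumped patches (per-class
  smoothed noise fields + log-prior weights, argmax); the second date
  applies a row-stochastic per-cell transition matrix. The default
  mangrove row loses ~24.5% of initial mangrove (13.7% to swamp, 9.4% to
  water, small flows to settlement/wetland/sandbar) with a 3%
  regeneration flow back from swamp and water — the relative magnitudes
  of the study system's 45-year change accounting. True transition
  counts are recorded and are, by construction, the exact change matrix.
- **Disturbance.** Built-up %, population, road density and agriculture %
  are clumped fields sharing a common "settlement pressure" component,
  mimicking their real mutual correlation.

What passing tests on these landscapes shows: the estimators, statistics
and the prioritization algebra are implemented correctly, and the full
pipeline recovers known structure at realistic sample sizes. What it does
not show: robustness to spatially biased sampling, label noise in LULC
classification, predictor measurement error, or niche shapes beyond
monotone logistic responses.

## Occurrence cleaning

Merging keeps the field-source copy of exact coordinate duplicates (field
records are GPS-verified). Rarefaction keeps exactly one record per
(species, cell): field preferred over archive, remaining ties uniform
under the seed. Rarefaction is idempotent and its output count per species
equals the number of distinct occupied cells.

## Learners

All ten learners sit behind one registry and return suitability in [0, 1]:

| name | implementation | notes |
|---|---|---|
| GLM | logistic regression, C = 1e6 | effectively unpenalized |
| GAM | per-feature cubic B-splines (4 knots) + ridge logistic | additive smooth terms |
| MARS | hinge pairs max(x−k,0), max(k−x,0) at quartile knots + L1 logistic | the L1 penalty performs the adaptive basis selection |
| RF | 100 bagged trees, min leaf 2 | vote fraction |
| GBM | 100 boosted depth-2 trees, lr 0.1 | |
| CTA | single tree, depth ≤ 6, min leaf 3 | |
| ANN | one hidden layer (8 units), ≤ 500 iterations | |
| FDA | quadratic basis expansion + LDA | basis-expanded discriminant |
| MAXENT-like | linear+quadratic+product features + L1 logistic (C = 1) | presence vs background |
| SRE | per-predictor [q, 1−q] presence quantile envelope, q = 0.025 | scores 0/1 |

Tree counts and iteration caps are deliberately small — the suite must run
18 species × 10 learners comfortably on one CPU — and all are
configurable. Pseudo-absences are uniform over unoccupied cells at a 1:1
ratio per species.

## Splits, gating, ensembling

The split is nested and stratified by class: 20% extrinsic holdout first,
then 75/25 of the remainder for training and intrinsic testing (an
ambiguity — whether the 75/25 applies to the remainder or the full set —
is resolved as nested, which keeps the three partitions disjoint and
exhaustive). Binary metrics use the max-TSS threshold scanned at midpoints
of sorted unique scores (smallest on ties). A learner qualifies iff κ,
TSS and AUC are all *strictly* above 0.75 on the intrinsic test. Ensemble
weights are the qualifiers' TSS values normalized to 1 (ROC or equal
weights are one config key away). The four suitability classes use fixed
cuts 0.25/0.50/0.75, left-closed on upgrade (0.75 is "highly").

When no learner passes the gate for a species, `run_all` falls back to the
single best learner by TSS and records the fallback in the manifest; the
`ensemble_weighted_mean` operation itself raises on an empty qualifier
set. The fallback keeps all species present downstream (overlap matrices
and the prioritization table are defined over all 18 species) while
leaving an auditable trace.

## Validation metrics

AUC is the Mann–Whitney probability with ties counted ½; TSS is
sensitivity + specificity − 1; κ is the chance-corrected agreement shared
with the LULC accuracy module. The continuous Boyce index computes P/E
ratios in suitability windows spanning [0, 1] and returns the Spearman
correlation between window midpoints and P/E, skipping windows with zero
expected fraction.

**Boyce windows.** The default is 50 disjoint windows of width 0.02 (an
exact partition of [0, 1]). The moving-window variant (e.g. 101 windows of
width 0.1) is available through parameters but is *not* the default: with
91% overlap between neighbouring windows the P/E ranks are strongly
correlated, and measured null distributions (presences resampled from the
background) leave |Boyce| < 0.3 only ~52% of the time — an uninformative
model is then routinely scored as if calibrated. With the disjoint
partition the same null concentrates (~95–96% within ±0.3) while monotone
P/E constructions still score exactly ±1.

## Niche overlap

D and I are computed on surfaces normalized to probability distributions
over cells; both are symmetric, lie in [0, 1], equal 1 iff the
distributions coincide, and are invariant to zero-probability cells.
Significance uses a niche-identity permutation test: pooled occurrence
cells are re-assigned to the two species preserving counts, a fast
surrogate model (GLM, or the SRE envelope for full-landscape runs where
hundreds of refits are needed) is refit per pseudo-species, and
p = (1 + #{D_perm ≤ D_obs})/(n_perm + 1) for the one-sided "lower overlap
than random" alternative (n_perm default 99; a two-sided option doubles
the smaller tail). Refitting the full 10-learner ensemble per permutation
is not desk-scale and would test the ensemble's stability rather than
niche identity.

## Change accounting

The change matrix is an exact cell cross-tabulation; its row/column
margins equal the two dates' class counts by construction. Per-grid
degradation is the share of the grid's *first-date* mangrove area lost;
accretion is the share of the *second-date* mangrove area newly gained
(the rates' denominators are not stated in the source workflow; these
choices make both rates bounded percentages, with zero-denominator grids
returning 0 under a flag).

## Restoration prioritization

The printed HDR formula sums heterogeneous units (percentages, counts,
km of road) and divides by "1 km"; it is read as a normalized 0–100
composite — each component min–max scaled over the grid population
(percentages by /100, counts and densities by their landscape maxima),
HDR = 100 × mean of the four. The normalization sits behind a spec object
so alternative readings (plain sum, weights) are a one-line change.

The species priority rank is the first principal component of the four
standardized species attributes (Levins-B niche breadth rescaled to
[0, 1], fraction of grids moderately-or-highly suitable, mean degradation
over occupied grids, IUCN status scored LC=1/NT=2/EN=3), signed so higher
conservation status maps to higher priority, ranked descending with ties
broken by status then code (the ranking key is rounded at 1e-9 so SVD
float noise cannot defeat the declared tie-break).

Indicator semantics: all comparisons strict, all thresholds config keys
(80% cover, 75 HDR, 75% accretion, 75% degradation, α = 0.05). The
combination rule is declared, not inherited: a (species, grid) is
prioritized iff **no veto** AND **suitable class** AND **at least one
further positive** among {top-half rank, significant overlap in the grid,
degradation > 75%}; count-based and veto-only modes are provided. The
"significant overlap in this grid" indicator holds where the species and a
significantly-overlapping partner are both moderately-or-highly suitable.

Categories 1–8 map species sets to restoration groupings
(family/status-based; 7 = mixed Avicennia–Rhizophoraceae community, 8 =
common pioneer assemblage). One registry species (LR) belongs to no
category; grid-level categorization ignores uncategorized species, and a
grid's category is the lowest-numbered category whose full species set is
prioritized there, else the lowest single-species category present.

## Problem sizes and determinism

Default sizes: 75×75 cells, 36 predictors, 18 species × 10 learners = 180
fits (~1 minute on one CPU); tests use 30×30 landscapes and reduced
learner sets where the property under test allows it, with permutation
counts of 19–49 in tests against 99 in production defaults. Every stage is
driven by `numpy.random.default_rng` seeds derived from the pipeline seed
via CRC-labelled `SeedSequence`s, so outputs are bit-reproducible across
processes; the manifest records the seed, sizes, fit count and every gate
decision.

## Known limitations

- Presence-only sampling with uniform pseudo-absences; no sampling-bias
  correction (target-group background, bias layers) is implemented.
- The MAXENT-like learner uses linear/quadratic/product features only —
  no hinge/threshold features or regularization paths of the reference
  MaxEnt machinery.
- Geographic-space overlap only; no environment-space equivalency or
  background-similarity tests.
- No spatial cross-validation; the extrinsic holdout is random, so
  spatial autocorrelation optimistically biases extrinsic scores, as it
  does in any non-blocked SDM evaluation.
- The LULC generator has exactly two dates and no process model (no
  erosion/accretion dynamics, no tidal forcing).
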