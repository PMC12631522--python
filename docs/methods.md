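# Methods

`paraniche` analyses the distribution and ecological niches of parasitic
plant functional types — euphytoid hemiparasites, obligate root parasites
and parasitic vines — in long-format vegetation-plot data. This note
documents the models and procedures, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was open.

## Cover aggregation

Records of one species in several vertical layers are combined into a
plot-level cover assuming independent overlap between layers
(Jennings–Fischer):

    combined = 100 · (1 − ∏ᵢ (1 − cᵢ/100)),   cᵢ ∈ (0, 100].

The combination is applied per species across its layers only; species
covers are then treated additively. Relative cover divides each species'
combined cover by the plot's summed species covers, and a functional type's
relative cover is the sum over its member species. Consequently the
parasitic types' relative covers plus the autotroph share always sum to 1.

## Spatial thinning

Plot pairs closer than `dist_km` (default 1 km; Euclidean on a planar km
frame, haversine with R = 6371 km for geographic coordinates) whose
cover-weighted Bray–Curtis similarity 1 − BC exceeds `sim_threshold`
(default 0.8) are treated as pseudoreplicates. Because "similarity > 0.8
(Bray–Curtis dissimilarity)" can be read two ways, a `mode` flag applies the
threshold either to the similarity (default) or to the dissimilarity
itself. Conflicts are resolved on the conflict graph: edges are visited in
seed-shuffled order and a uniformly random endpoint of each still-active
edge is dropped. This is reproducible, satisfies the pairwise rule exactly
(verified against a brute-force O(n²) pair scan), and is idempotent.
Candidate pairs are found with a KD-tree rather than an all-pairs scan; the
result is identical by construction and checked against the oracle in tests.

## Hexagonal cover maps

Mean relative cover per functional type is summarised on a grid of flat-top
hexagons whose flat-to-flat width runs north–south (default 50 km, cell area
(√3/2)·width² ≈ 2165 km²). Plots are assigned to cells by nearest hexagon
centre, which is exactly the point-in-polygon assignment of the hexagonal
tiling (its Voronoi partition) with deterministic boundary handling. Cells
with fewer than `min_plots` (default 5) plots get null means. Colour
classes use linear-interpolation quantile breaks over the non-zero cell
means only; zero cells are class 0. The class count is configurable
(default k = 5).

## Climate predictor selection

Because bioclim predictors are strongly intercorrelated, a forward RDA-style
selection reduces the climate set: columns are standardised, and at each
step the candidate maximising the trace R² of the remaining (unselected)
columns regressed on the selected set plus the candidate is added. The
cumulative criterion is the Ezekiel-adjusted R² of regressing the full
climate table on the selected set,

    R²_adj = 1 − (1 − R²)(n − 1)/(n − p − 1),

and selection stops at `stop_r2adj` (default 0.95) or when no candidate adds
variance (tolerance 1e-9). Ties within tolerance are broken by a priority
list, mirroring the ecological preference for growing-season variables
(e.g. bio10 over bio1); otherwise by column order. Plot size is
square-root transformed; missing plot sizes are median-imputed with a binary
missingness indicator column, since plots without size information should
not be discarded.

## Boosted regression trees

Occurrence of each functional type is modelled as a Bernoulli response with
stagewise gradient boosting of depth-`tree_complexity` regression trees
(default 5), learning rate 0.001, per-tree subsample (bag fraction) 0.5 —
the "training/test ratio" of the reference routine maps onto this per-tree
subsampling. Plot weights carry abundance information: raw weight 1 where
the type is absent, its relative cover where present, min–max scaled to

    scaled = (w − min w)/(max w − min w) · 100 + 1 ∈ [1, 101].

If all raw weights are equal the scaled weights are set to 1 (the formula is
0/0 there) with a warning. The tree count is selected by k-fold CV (default
10 folds): each fold's model is grown once to `max_trees`, staged held-out
Bernoulli deviance — weighted with the same observation weights used in
fitting — is recorded every `step_size` trees (default 50), and the count
minimising the mean curve is kept; this single-pass evaluation selects the
same size as stepwise growth. The final model is refit on all data at the
selected size. Relative influence is the normalised squared-error-reduction
importance (sums to 100). Partial dependence clamps one predictor to a grid
spanning its observed range and averages the model's logit over the training
rows. Whether raw presence weights start on a 0–1 or percent scale is
immaterial after min–max scaling.

Residual spatial autocorrelation is diagnosed with a Moran's I correlogram:
k = ⌈1 + log₂ n⌉ distance classes (Sturges), equal-width bins over (0, max
pairwise distance] (equal pair-count bins available by flag), binary
within-class weights, expectation −1/(n − 1), and two-sided permutation
p-values.

## Indicator-value permutation test

Plot community means of the five indicator values (N, M, R, T, L) are
unweighted means over species with data, excluding the focal functional
type's species. The observed statistic is Diff_real = mean(occupied) −
mean(unoccupied). The null shuffles indicator values among the species
possessing a value for that indicator (parasites included), with plot
composition fixed; each permutation reproduces the plot means and the
difference. Then

    SES = (Diff_real − mean Diff_rand) / SD(Diff_rand),

and the reported p is the fraction of permutations exceeding Diff_real in
the SES direction, with non-strict (≥/≤) counting and no +1 smoothing
(the divisor is exactly the number of permutations). Indicators are
permuted independently by default, since each indicator is tested
separately; a joint mode shuffles values as tuples over species with
complete data. Plots whose mean becomes missing after exclusion are dropped
from both groups. An exact mode enumerates all value permutations for small
pools and is verified against a brute-force oracle.

Because the reported p is one-sided in a direction chosen by the data, a
decision at level α must compare it to α/2 (equivalently use the provided
`p_two_sided` = 2p); comparing the directional p to α itself would double
the type-I error by construction. The calibration simulations use this
rule, and on null synthetic data the test attains the nominal 5% rate with
SES mean ≈ 0 and SD ≈ 1 across replicates.

## Species niches

For each parasitic species with at least `min_occurrences` (default 50)
plots, occurrence values of a gradient are weighted by square-rooted
relative cover, wᵢ = √cᵢ / Σⱼ√cⱼ. The niche optimum is the weighted
arithmetic mean (invariant to rescaling all covers). The 95% range comes
from a Gaussian kernel density evaluated on a 512-point grid spanning the
data range extended by 3 bandwidths; grid densities are normalised to sum
to 1 and the 0.025/0.975 quantiles of that discrete distribution are the
bounds (no continuous inverse CDF), so for multimodal densities only
lower ≤ upper is guaranteed. The bandwidth is Silverman's rule of thumb on
the weighted sample with effective sample size 1/Σwᵢ²; it is configurable
because standard density routines differ here. Observed minima and maxima
are reported alongside as metadata. For community-indicator gradients the
focal species is excluded from each plot's mean.

## Synthetic data generator

The generator emulates, at desk scale, the features the pipeline relies on:

* **Spatial frame** — plots uniform on a 1000 × 1000 km planar frame;
  environmental covariates are smooth fields (three random planar sinusoids
  with wavelengths 200–800 km plus white noise, ~56% spatial variance) with
  realistic marginal means and spreads (e.g. bio10 ≈ 16 ± 4 °C, bio12 ≈
  700 ± 250 mm, TRI ≈ 150 ± 120 m). A `spatially_iid` switch removes the
  spatial structure for autocorrelation null tests.
* **Species pool** — default 300 species; parasitic types keep the
  ~176:52:12 species-ratio of the European pool but are scaled up to
  8.8% / 2.6% / 0.6% of the pool so each type has enough species at desk
  scale. Species indicator values are a habitat optimum U(2, 8) plus
  N(0, 1) noise clipped to [0, 10], 10% missing at random.
* **Occupancy** — each type occupies plots with probability
  logistic(b + Σ βᵢ zᵢ) on standardised predictors (`effect_spec`; defaults
  mirror the qualitative driver structure: euphytoid occurrence decreasing
  with summer temperature and increasing with summer precipitation, root
  parasites and vines the reverse, all increasing with ruggedness). The
  intercept b is calibrated by root finding so realised prevalence matches
  the configured one (defaults 0.25 / 0.10 / 0.05, giving ≈18% of plots
  with any parasite). The null generator sets all effects to zero.
* **Indicator shifts** — autotroph species are drawn into occupied plots
  with exponentially tilted weights exp(λe); λ is solved per type and
  indicator against the pool so the community mean in occupied plots
  differs by the configured `eive_shift` (defaults −0.5/−0.4/−0.3 on
  N, M, T, L; soil reaction unshifted). Finite per-plot draws without
  replacement and co-occurring types attenuate the realised shift mildly
  (≈10–15% toward zero at the default scale), which recovery tests allow
  for. The null generator sets shifts to zero, making occupancy independent
  of species values — under which the permutation test is exactly valid.
* **Covers** — truncated log-normal (right-skewed, autotrophs ~10%,
  parasites ~3% median), split across 1–3 layers with Dirichlet shares.
* **Near-duplicates** — a fraction (default 5%) of plots is cloned within
  0.1–0.5 km with per-record cover perturbation U(0.92, 1.08), bounding the
  pairwise Bray–Curtis dissimilarity below ≈0.06.

Everything derives from one `numpy` generator seeded from the config, so a
given configuration is byte-reproducible.

What the generator does **not** emulate: taxonomic aggregates, phylogenetic
structure, realistic habitat classifications (codes are opaque labels),
geographic coordinate systems (planar km only), uneven plot-density
gradients, and observer or cover-scale heterogeneity. Passing tests
therefore demonstrate the correctness and calibration of the algorithms
under known structure, not the ecological conclusions one would draw from
real archive data.

## Problem sizes used in tests and the acceptance script

Simulation-based checks use deliberate desk scales: 2000-plot datasets for
prevalence, correlation and shift recovery; 200 replicate 500-plot null
datasets (199 permutations each) for type-I calibration; 10 seeded
3000-plot runs with learning rate 0.01 and 400 trees for boosted-tree
driver recovery (a scaled-down surrogate for the production learning rate
0.001 with thousands of trees); 20 replicate 1000-plot datasets for
thinning verification; n = 400 for Gaussian niche recovery; and n = 1000
for the correlogram class-count check.

## Known limitations

* The BRT backend is scikit-learn's gradient boosting; exact tree-level
  behaviour (split tie-breaks, bagging order) differs from other
  implementations, so selected tree counts and influence values match only
  statistically, not bit-for-bit, across ecosystems.
* The forward selection is greedy; it can pick a predictor set that ties
  rather than equals the exhaustive-search optimum when candidate sets are
  nearly collinear (the explained variance matches to ~1e-3 in tests).
* KDE-based niche bounds inherit bandwidth smoothing: intervals are wider
  than the underlying data quantiles by O(h²), visible for small samples.
* Haversine distances assume a spherical Earth (R = 6371 km).
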