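# paraniche

Niche and spatial-pattern analysis of **parasitic plant functional types**
— euphytoid hemiparasites, obligate root parasites, and parasitic vines —
in vegetation-plot data.

Parasitic plants attach to other plants' vascular tissue and occupy almost
every European habitat, but the three functional types differ sharply in
physiology (own photosynthesis vs. host carbon, xylem vs. phloem feeding)
and hence in where they occur. Quantifying that requires a chain of fairly
standard but easy-to-get-wrong steps over plot × species × layer cover
tables, and this package implements the chain as a tested, reusable
library for community ecologists working with archive-style plot data:

* **Cover aggregation** — per-species layer combination assuming
  independent overlap, `100·(1 − ∏(1 − cᵢ/100))`; relative cover; per-plot
  relative cover of each functional type.
* **Spatial thinning** — pairs of plots within 1 km whose cover-weighted
  Bray–Curtis similarity (1 − BC) exceeds 0.8 are reduced to one randomly
  retained plot, reproducibly.
* **Hexagonal cover maps** — mean relative cover per 50-km hexagonal cell
  (area (√3/2)·50² ≈ 2165 km²), null below 5 plots per cell, quantile
  colour classes over non-zero cells; GeoJSON output.
* **Predictor selection** — forward RDA-style selection of intercorrelated
  climate predictors against an adjusted-R² stopping rule.
* **Weighted boosted regression trees** — Bernoulli gradient boosting of
  occurrence with abundance-carrying plot weights min–max scaled to
  [1, 101], cross-validated tree-count selection, relative influence
  (sums to 100%), partial dependence, and a Moran's I correlogram on
  residuals (Sturges distance classes).
* **Indicator-value permutation test** — community means of ecological
  indicator values (soil N, moisture, reaction, temperature, light;
  0–10 scales) excluding the focal type, tested against a species-level
  permutation null: `SES = (Diff_real − mean Diff_rand)/SD(Diff_rand)`.
* **Species niches** — per species with ≥50 occurrences, a
  √cover-weighted optimum and a 95% range from a weighted Gaussian KDE
  (0.025/0.975 quantiles of the normalised grid density).
* **Synthetic data** — a seeded generator producing plot datasets with
  known occupancy drivers, indicator shifts and planted near-duplicates,
  so every stage is testable against ground truth.

See `docs/methods.md` for the models, parameter defaults, and numerical
choices.

## Worked example

```python
from paraniche import (SynthConfig, generate_dataset, aggregate_dataset,
                       type_cover_frame, thin_plots, modified_permutation_test,
                       prepare_predictors, scale_weights, presence_weights,
                       WeightedBoostedTrees, niche_table)

dataset, truth = generate_dataset(SynthConfig(n_plots=2000, seed=3))
agg = aggregate_dataset(dataset)
frame = type_cover_frame(agg)
print(f"plots: {len(dataset.headers)}  euphytoid prevalence: "
      f"{frame['presence_euphytoid'].mean():.3f}")

thin = thin_plots(dataset, agg, seed=3)
print(f"thinning removed {len(thin.dropped)} near-duplicate plots "
      f"(configured clones: {len(truth.duplicate_pairs)})")

res = modified_permutation_test(agg, dataset.trait_map(), "euphytoid", "N",
                                n_perm=999, seed=3)
print(f"soil-N shift: diff={res.diff_real:+.3f}  SES={res.ses:.2f}  p={res.p:.4f}")

X = prepare_predictors(dataset).frame.loc[frame.index]
y = frame["presence_euphytoid"].to_numpy()
w = scale_weights(presence_weights(frame["cover_euphytoid"].to_numpy()))
model = WeightedBoostedTrees(learning_rate=0.05, tree_complexity=5, n_folds=5,
                             step_size=25, max_trees=200, random_state=3)
model.fit(X, y, sample_weight=w)
top = sorted(model.relative_influence_.items(), key=lambda kv: -kv[1])[:3]
print("top influences:", ", ".join(f"{k}={v:.1f}%" for k, v in top),
      f"(selected {model.n_trees_} trees)")

table = niche_table(dataset, agg, ["bio10"], min_occurrences=50)
e = table[0]
print(f"niche of {e.taxon_id} on bio10: {e.lower:.1f} .. {e.optimum:.1f} .. "
      f"{e.upper:.1f} degC  (n={e.n_occurrences})")
```

prints

```
plots: 2100  euphytoid prevalence: 0.239
thinning removed 100 near-duplicate plots (configured clones: 100)
soil-N shift: diff=-0.469  SES=-5.64  p=0.0000
top influences: bio10=34.0%, bio12=24.9%, tri=13.1% (selected 25 trees)
niche of sp_vine_0000 on bio10: 12.2 .. 18.9 .. 25.9 degC  (n=70)
```

The generator planted a −0.5 soil-nitrogen shift for euphytoid
hemiparasites and made summer temperature (bio10) their main occupancy
driver: the permutation test recovers a strongly significant negative
shift, the boosted trees rank bio10 first, and the vine species' realised
temperature niche (optimum 18.9 °C, 95% range 12.2–25.9 °C) reflects its
warm-biased occupancy. All 100 planted near-duplicate clones are removed
by thinning.

The same pipeline is scriptable from the shell (`paraniche synth`,
`aggregate`, `thin`, `grid`, `select-predictors`, `brt`, `moran`,
`eive-test`, `niche`); run `paraniche --help`.

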