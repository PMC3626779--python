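# icmolar

Analysis of mammalian lower-molar proportions under the **inhibitory
cascade (IC) model** of tooth development.

Molars develop front to back, and the size of each developing molar is
set by the balance *a* between a mesenchymal activator and inhibition
from the next-anterior molar. Because the effect accumulates along the
row, the model predicts relative occlusal areas

```
(m1, m2, m3)  ∝  (1, a, 2a − 1)
```

so in the morphospace with axes *x* = m2/m1 and *y* = m3/m1 every taxon
should lie on the line **y = 2x − 1**, the second molar should never be
strictly the largest or smallest tooth in the row, and m2 should occupy
exactly one third of total molar area. `icmolar` takes per-specimen
molar length/width tables (mm, long format) to a genus-level
morphospace and tests these predictions:

- **`molar_data`** — validated ingestion, occlusal area as length ×
  width, sampling-rule filtering (no isolated-molar-only genera, no
  short tooth rows, adjacent molar pairs required) with a full
  exclusion log, and genus aggregation as the mean of per-specimen
  ratios.
- **`ic_model`** — the theoretical line, region (m2-intermediate /
  m2-largest / m2-smallest) and trend (decreasing / increasing / equal)
  classification, and the m2-share t-test against exactly 100/3 %.
- **`rma_regression`** — reduced major axis (standardized major axis)
  fit, slope = sign(r)·s_y/s_x, with analytic or bootstrap 95% CIs and
  CI-overlap comparison against the theoretical (2, −1) line and
  published murine, arvicoline, and canid fits.
- **`resampling_stats`** — tie-aware Spearman rank correlation with the
  classical S statistic, one-sample t-test, and one-way PERMANOVA
  (Euclidean distance, seeded label permutations).
- **`synthetic_data`** — a generator that simulates taxa under the
  cascade (group-structured *a*, measurement noise on each dimension,
  missing teeth, off-model "m2 bulge" deviation modes) plus replicated
  parameter-recovery and type-I-error studies.
- **`pipeline_cli`** — the `icmolar` command: `run`, `simulate`,
  `recover`.

## Worked example

Simulate a 132-genus dataset in which one "archaic ungulate" group has
its m2 inflated by 30% off the cascade line, then analyse it:

```sh
icmolar simulate --scenario condylarth --seed 42 --out data
icmolar run --measurements data/measurements.csv \
            --metadata data/metadata.csv --out report \
            --n-perm 999 --seed 42
# kept 259 of 262 specimens; 131 genera in morphospace
```

Selected lines of `report/summary.tsv`:

```
rma_slope              1.8592501044887961
rma_intercept          -0.9480942539748443
n_m2_intermediate      95
n_m2_largest           27
n_m2_smallest          9
pct_predicted_region   72.51908396946565
m2_share_mean_pct      34.284191439007344
m2_share_t             4.227742937206241
differs_from_ic        True
```

Reading: 72.5% of genera stay inside the predicted (m2-intermediate)
region, but the bulged group pushes 27 genera into the m2-largest
region, drags the RMA slope (1.859, 95% CI 1.754:1.971) significantly
off the theoretical slope 2, and raises the mean m2 share to 34.3%
(t = 4.23 against 100/3 %). `report/table4.tsv` shows the morphospace
clustering by taxonomic group and dietary guild (one-way PERMANOVA,
e.g. Diet F = 11.62, R² = 0.317, p = 0.001), and `report/table2.tsv`
places the fitted line alongside the theoretical model and published
murine/arvicoline/canid regressions.

With measurement noise switched off (`measurement_cv = 0`) and no
deviation modes, the pipeline reproduces the theory exactly: slope
2.000, intercept −1.000, 100% of genera in the predicted region.

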