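# Methods

## The model

The inhibitory cascade treats the sizes of the three lower molars as
the outcome of a single developmental balance *a* between a mesenchymal
activator and inhibition exerted by the next-anterior molar. The
inhibition accumulates along the row, giving relative occlusal areas
(1, *a*, 2*a* − 1) for m1, m2, m3, with m3 failing to form when
*a* ≤ 1/2. Three consequences are tested:

1. in the (x, y) = (m2/m1, m3/m1) area-ratio morphospace all taxa lie
   on y = 2x − 1, so m2 is always intermediate in size (or all molars
   equal);
2. m2 occupies exactly one third of total molar area
   (a/(1 + a + 2a − 1) = 1/3 for every a ≥ 1/2);
3. position along the line tracks diet, faunivores at the low end
   (a < 1) and folivores at the high end.

Occlusal area is estimated as maximum length × maximum width per tooth.
Each posterior tooth's area is scaled by the same specimen's m1 area,
and a genus's morphospace point is the arithmetic mean of its
per-specimen ratios — not the ratio of mean areas; the two differ under
noise, and averaging ratios keeps the per-specimen scaling exact.
Length is never used as a proxy for area; the Spearman correlation
table exists precisely to quantify how good such a proxy would be.

## Filtering rules

A specimen enters the analysis only if it preserves an adjacent molar
pair (m1–m2 or m2–m3) with both areas measurable. Whole genera are
dropped when represented solely by isolated molars (no control over
intraspecific variation) or when the tooth row has fewer than three
molar positions. Every exclusion carries exactly one primary reason, so
kept + excluded reconciles with the input row count, and every
downstream statistic reports its own achieved N (the Ns legitimately
differ between analyses: a genus lacking m3 contributes to m2/m1
statistics but not to the morphospace).

Unknown genera in the metadata are a hard error by default;
`missing_metadata="assume"` downgrades this for exploratory use because
silently guessed diet/group labels would corrupt the PERMANOVA.

## Region and trend classification

The morphospace is split by the lines x = 1 and y = x. m2-largest
requires *strictly* x > 1 and y < x; m2-smallest strictly x < 1 and
y > x; all boundary cases (any two molars exactly equal) count as
m2-intermediate, because equal sizes are a permitted cascade outcome.
The tolerance parameter (default 0) widens the predicted region
symmetrically and is exposed as a sensitivity diagnostic only. Within
the predicted region, trends are decreasing (m1 > m2 > m3), increasing
(m1 < m2 < m3), or all-equal; on real-valued data the all-equal bin is
expected to be empty at tolerance 0.

## RMA regression and intervals

Both axes carry measurement error, so the line is fitted by reduced
(standardized) major axis: slope b = sign(r)·s_y/s_x (n − 1
denominators, which cancel), intercept through the centroid. The
default 95% interval is the standard analytic SMA interval,
b(√(B+1) ± √B) with B = F(1−α; 1, n−2)(1 − r²)/(n − 2); the intercept
interval propagates the slope endpoints through the centroid and adds
the t-interval of ȳ in quadrature. A seeded case bootstrap (percentile
CIs, ≥999 replicates, degenerate resamples redrawn) is available as a
cross-check. Lines are compared by 95% CI overlap; a theoretical line
is a zero-width interval, so the test reduces to containment.

The m2-share test is a two-tailed one-sample t-test of per-genus mean
shares (in %) against exactly 100/3, not a rounded 33 or 33.33.

## PERMANOVA

One-way permutational MANOVA on the (x, y) coordinates with Euclidean
distance: the morphospace is an ordinary real plane, so an
abundance-style dissimilarity would be inappropriate. The partition
uses squared pairwise distances (ss_total = Σ_{i<j} d²/n;
ss_within = Σ_g Σ_{i<j∈g} d²/n_g), pseudo-F = (ss_between/(a−1)) /
(ss_within/(n−a)), and p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1) over
uniformly random relabellings from a seeded generator (default
n_perm = 999). Only F and R² are permutation-independent; p is
reproducible given the seed. The four shipped analyses are: Phylogeny
(all group labels), Phylogeny 5+ (after pooling Creodonta with
Carnivora and Plesiadapiformes with Primates, keeping pooled groups
with ≥5 genera), Diet, and Diet reduced (dropping the five extreme
herbivorous outlier genera, configurable).

Spearman correlations use midranks for ties, rho as the Pearson
correlation of rank vectors, S derived as (1 − rho)(n³ − n)/6 so the
printed statistic matches standard output (and equals Σd² exactly
without ties), and the t-approximation on n − 2 df for p.

## The synthetic generator

The generator emulates the structure of a broad fossil-mammal
comparative sample, and its defaults are the package's standard study
conditions:

- **132 genera in 12 taxonomic groups**, each group with its own
  truncated-normal (>0) distribution of *a*. Group means run from 0.75
  (carnivore-like) through 1.0 (basal insectivore-like) to 1.6 with the
  widest spread (folivorous artiodactyl-like, whose real counterparts
  reach several-fold m1→m3 area increases). A truncated normal rather
  than a lognormal keeps a = 1 (equal molars) a natural centre, where
  basal taxa sit.
- **1–3 specimens per genus** (uniform), matching the sparse specimen
  density of fossil datasets.
- **m1 area lognormal** (ln-mean 2.3, ln-sd 1.0, mm²): median ≈ 10 mm²
  spanning shrew-sized to large-ungulate teeth.
- **Aspect ratio** length/width ~ N(1.4, 0.2) per genus and tooth;
  areas are factored into length × width through it.
- **Measurement noise** is multiplicative and placed on each measured
  length and width (lognormal, cv 5% by default), not on areas —
  noise on what is actually measured induces the realistic correlated
  area noise, about 7% per area and 10% per area ratio.
- **Missing teeth** are deleted tooth rows at a configurable rate;
  genera with a ≤ 1/2 genuinely lack m3 and carry `molar_count = 2`, so
  the pipeline's exclusion rules are exercised.
- **Deviation modes**: `m2_bulge` multiplies the true m2 area of one
  group by (1 + δ) after cascade generation, producing the
  condylarth-like off-model cluster (m2-largest whenever
  (1+δ)a > max(1, 2a − 1)).

Three scenario bundles ship: `conforming` (all taxa on the line),
`condylarth` (one bulged group), and `null-diet` (all groups share one
*a* distribution, so diet labels are uninformative — the type-I-error
scenario). Everything is deterministic given the config seed;
replicate seeds in the studies are derived arithmetically and stay
below 2³¹.

What the generator does **not** emulate: phylogenetic autocorrelation
along a tree, within-genus species structure, premolar effects on m1,
taphonomic biases in which teeth survive, or non-multiplicative
digitisation error. Passing recovery tests therefore demonstrate
estimator correctness under the cascade-plus-noise model, not
robustness to every property of real fossil data.

## Recovery studies and what they show

`slope_recovery_study` (200 replicates by default) refits the RMA line
on fresh conforming datasets: the mean slope recovers 2.0 closely
(attenuated slightly downward, see below) and mean intercept −1.0.
`permanova_type1_study` (1000 replicates, n_perm = 199) confirms the
permutation test's size: rejection ≈ 5% at α = 0.05 under null diet
labels.

One property deserves emphasis. With multiplicative noise on both
axes, the SMA estimand is the population sd-ratio, which is *not*
exactly the generating slope: the noise-to-signal ratio is relatively
larger on x = m2/m1 than on y = m3/m1 (y has roughly twice the
coefficient of variation, because the line's −1 intercept stretches y's
spread), so the fitted slope is attenuated by roughly 2% at the default
noise level, and the group-structured mixture of *a* distributions
makes x heavier-tailed than normal, widening the true sampling
variability beyond the normal-theory interval. Consequently the
analytic CI — which covers its own estimand at its nominal rate, as the
test suite verifies on bivariate-normal data — covers the *theoretical*
slope 2.0 at well below 95% under the default study conditions. The
acceptance suite measures and reports this coverage rather than hiding
it; it is a property of error-in-variables line fitting at these
noise-to-signal ratios, not an implementation defect.

## Numerical choices

- Ratios and shares propagate missing values; nothing is imputed.
- Perfect rank agreement snaps Spearman rho to exactly ±1 (S = 0), so
  the S ⇔ rho identities hold exactly in the degenerate case.
- Zero within-group scatter gives an infinite pseudo-F rather than an
  error; infinite permuted F values compare ≥ correctly.
- A zero-variance t-test sample yields t = 0 (mean = mu) or ±∞ with
  p = 0 (mean ≠ mu), flagged rather than raised.
- r² = 1 collapses the analytic RMA interval to a point and flags the
  fit `degenerate_ci`.
- Convex hulls ("minimum-area polygons" of disparity studies) come from
  the standard quickhull; vertex lists are emitted CCW from the
  lowest-then-leftmost vertex, and labels with <3 distinct or collinear
  points are flagged degenerate instead of producing a sliver polygon.
- Genus-record TSVs write floats with `repr`, so a write/read
  round-trip is bit-exact.

## Known limitations

- No phylogenetically corrected regression; the genus is the exchange
  unit in all permutation tests.
- The analytic intercept CI is a quadrature approximation (slope
  endpoint propagation + ȳ uncertainty), adequate for overlap tests;
  use the bootstrap when the intercept interval itself is of interest.
- PERMANOVA is one-way only: no nesting, strata, or post-hoc pairwise
  tests.
- The published murine/arvicoline/canid comparison rows are literature
  constants; their raw data are not recomputed here.
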