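# Methods

This note documents the statistical model, the numerical choices, and the
known limits of `timepatterns`. It is the design record: anything stated
here as an empirical property is computed by the test suite or by
`scripts/acceptance.py`, not asserted from memory.

## Data model and preprocessing

The input is a genes × samples table whose sample identity
(condition, time point, replicate) is encoded in the column headers.
Replicates are collapsed to their arithmetic mean first, so every later
stage operates on the C × T analysis grid. Normalization is optional and
deliberately conservative:

* **microarray** — quantile normalization only; platform-level
  normalization is assumed done upstream.
* **RNA-seq** — `log2(x+1)`, then each sample's column sum scaled to the
  median column sum, then quantile normalization. The log stabilises the
  count scale so that cosine geometry is comparable across expression units
  (counts, TPM/FPKM); the median-sum scaling is the minimal reading of
  "sample normalization" and is documented as such rather than presented as
  canonical. Users who normalized upstream should disable the step.

Quantile normalization maps each column's rank to the mean of the sorted
columns; ties receive the mean of their spanned reference values (the usual
microarray convention, implemented on `scipy.stats.rankdata`).

Missing values are rejected, not imputed. Genes whose concatenated profile
has norm ≤ 1e-12 cannot be projected to the unit sphere and are dropped
with a report; they are the only genes that leave the analysis silently to
downstream consumers, so their count is carried in `summary.json`.

## Spherical K-means

Profiles live on the unit sphere in `R^{C·T}`; the fit maximises total
cosine similarity `Σ_g x_g·c_{a(g)}`, equivalent to minimising the Euclidean
within-cluster sum of squares, since on unit vectors
`‖x−c‖² = 2(1−x·c)` when `‖c‖ = 1`. The WCSS reported by `total_wcss`
satisfies `wcss = 2(n − objective)` to 1e-6, which the tests assert.

Numerical choices:

* **Seeding** — K-means++ D² sampling with cosine distance `1 − x·c`,
  restricted to a uniformly drawn `ceil(0.1·n)` subsample (all points when
  the subsample would be smaller than K). Subsampling keeps seeding cheap
  on genome-scale inputs without visibly hurting seed quality.
* **Iteration** — batch (Lloyd) alternation: assign to the
  highest-cosine centroid (ties toward the lowest cluster index, making
  runs reproducible), update centroids as renormalized means; stop when
  assignments are stable or after `max_iter` (300).
* **First-variation refinement** — batch iterations can stall in
  assignment-stable configurations that single-point moves still improve
  (observed on instances as small as n = 4). After Lloyd converges, a
  greedy sweep evaluates the exact objective change
  `(‖s_a − x‖ + ‖s_b + x‖) − (‖s_a‖ + ‖s_b‖)` of moving each point and
  applies improving moves, ping-ponging with Lloyd until neither phase
  improves. With this refinement, best-of-20 restarts matches exhaustive
  search (all 2^n labelings) on 100 random instances with n ≤ 8, K = 2 to
  1e-9.
* **Restarts** — best of 5 seeded restarts by objective (20 in the
  optimality check); all randomness flows from a single `rng_seed` through
  `numpy.random.SeedSequence`, so results are bit-reproducible.
* **Empty clusters** — dropped, not re-seeded; the reported number of
  clusters may be smaller than K. This is the desired behaviour for the
  recommended usage pattern of a generous K.

## Choosing K (elbow test)

For K on the grid `{2} ∪ {round(i·Kmax/10)}`, clustering is repeated
(default 5 runs) and the mean WCSS plotted against K; averaging smooths the
initialisation noise of individual runs. The recommended K maximises the
perpendicular distance to the chord from the first to the last point after
normalizing both axes to [0, 1] — the standard geometric elbow, and the
normalization makes the choice invariant to affine rescaling of either
axis. When the largest normalized chord distance is below 0.05 the curve is
effectively straight and the result carries a `no_clear_elbow` flag rather
than a confident recommendation. The grid rule requires Kmax ≥ 20; below
that the grid degenerates and the call errors out.

## DEP/ODEP/SEP classification

Each cluster's replicate-averaged tensor slice is rank-discretized per gene
and condition into 3 equal-frequency levels (ties share the lower level);
with T time points, T ≥ bins is required. Discretization makes the
comparison invariant to per-condition scale and monotone distortions.

For every condition pair the paired level sequences, pooled over the
cluster's genes and time points, yield:

* **NMI** — plug-in mutual information normalized by the mean marginal
  entropy (conventions: 1 for equal constant sequences, 0 when exactly one
  marginal is degenerate). NMI is reported descriptively. It is *not* the
  verdict statistic: MI is invariant to any relabelling of levels, so a
  perfectly value-inverted pattern scores NMI = 1, and pooled MI of any two
  time-structured patterns sits far above a time-shuffling null — a
  dependence score cannot separate "same pattern" from "related but
  different pattern".
* **Agreement** — the fraction of pooled positions where the two level
  sequences coincide. The verdict is *similar* when (a) agreement is
  significantly high against the permutation null that shuffles the second
  condition's T time labels independently within each gene
  (`p = (1 + #{null ≥ obs})/(n_perm + 1)`, default 1000 permutations), and
  (b) agreement ≥ 0.5. The effect-size floor exists because partially
  related patterns — e.g. two peaks at different times sharing a baseline —
  agree slightly but, pooled over many genes, significantly above chance
  (chance is 1/3 at 3 levels); requiring half of all positions to coincide
  separates "same shape" from "related shape". Both alpha (default 0.05)
  and the floor are configurable.

Permutations are seeded per (gene id, condition-name pair) by hashing the
identifiers, so p-values are exactly invariant to gene order and to
condition reordering while remaining deterministic in the run seed.

Labels combine the pairwise verdicts: SEP (all similar), DEP (all
different), ODEP (exactly one condition different from every other, rest
mutually similar), mixed otherwise. The composite cluster p is the worst
evidence for the assigned label — the largest p among similar pairs
combined with the smallest (1 − p) among different pairs — floored at
1/(n_perm+1), then BH-corrected across clusters. A cluster is reported as
significant when its label is not mixed, q ≤ alpha, and it has at least
`min_cluster_size` (default 5) genes; undersized clusters are labelled
mixed and excluded from testing.

Degenerate case: when both conditions are flat in every gene the
permutation null is a point mass and the test has no power; equal constant
sequences are treated as similar by convention (mirroring the NMI = 1
convention), since a flat cluster shares its — absent — time pattern.

## Synthetic data generator

The generator emulates the structure of multi-condition time-course
experiments: C conditions × T time points × R replicates, clusters of genes
following smooth condition-level templates (linear ramps, Gaussian peaks of
width 0.1 on [0,1]-scaled time, tanh sigmoids, constants), replicate-level
Gaussian noise with sd = `noise_sd × amplitude`, a baseline of 1.2 ×
amplitude, and a per-gene shift to non-negativity. SEP clusters share one
template across conditions; DEP clusters spread conditions evenly in
template phase; ODEP clusters give the designated condition the
half-phase-offset template. Template separation (pairwise cosine ≤ 0.3
between conditions required to differ) is enforced and fails loudly for
families that cannot support it (three separated linear or sigmoid
variants do not exist; constants cannot differ at all). A Poisson `counts`
mode produces integer data for RNA-seq-like inputs.

The canonical fixture (3 × 6 × 3, two clusters per pattern type, 40 genes
each) keeps peak centers inside [0.1, 0.9]: a peak truncated at the time
boundary degenerates into a monotone ramp whose rank pattern collides with
a neighbouring condition's. Planted "different" effects are time-shifted
templates; value-inverted templates are intentionally not used, because
inversion produces chance-level agreement without anti-agreement — callable
as "not similar" but a weaker planted signal.

What the generator does **not** emulate: gene–gene correlation beyond
shared templates, heteroscedastic (count-depth–dependent) noise, batch
effects, missing time points, or probe-level microarray artefacts. Passing
the planted-recovery tests therefore demonstrates correctness of the
machinery under clean separation assumptions, not performance on real GEO
series.

## Problem sizes used in validation

The acceptance checks run on deliberately compact instances chosen as the
smallest sizes at which each property is meaningful: 240-gene six-cluster
fixtures over 20 seeds for recovery; 100–125-gene fixtures with 4/5/8
planted clusters for the K-test; 500 twenty-gene null clusters at 199
permutations for calibration; 100 instances of n ≤ 8 for the exhaustive
cross-check. The pipeline itself has no such limits; cost grows linearly
in genes and K for clustering and in `n_perm × genes` for classification.

## Known limitations

* The similar/different decision is pattern-shape–based on replicate
  averages; replicate-level variance is not propagated into the test.
* Value-inverted (mirror-image) condition patterns are detected as "not
  similar" only through the agreement floor; no anti-similarity category
  exists.
* With T = 6 and 3 levels the discretization is coarse; subtle timing
  differences inside a level are invisible.
* The elbow recommendation inherits the elbow method's ambiguity on
  smoothly decaying WCSS curves; the `no_clear_elbow` flag should be taken
  seriously.
* Enrichment uses a user-defined universe and BH correction; results are
  only as current as the supplied offline tables.
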