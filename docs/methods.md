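# Methods

This note records the models, conventions and numerical choices behind
`metaclust`, in the order data flows through the package.

## Expression data model

A dataset is an instances-by-features real matrix with optional true class
labels and a nominal chip-type tag. Missing cells are `NaN` in the value
matrix and mirrored in a boolean mask; text readers treat an empty field or
`NA` as unobserved (configurable). Gene-per-row files are handled by an
orientation flag and transposed on load, so everything downstream sees
samples in rows.

Imputation replaces each missing cell with the mean of the observed values of
its feature (gene) — the standard microarray convention; a feature with no
observed values is an error, never silently dropped. Four per-feature
normalizations are registered: `none`, z-score (population sd; constant
features map to all-zeros), min-max to [0, 1] (constant features map to 0.5),
and average-rank scaled to [0, 1]. The quartet spans no/location-scale/range/
order normalization and the registry is extensible, since reasonable
alternatives exist and nothing in the pipeline depends on this particular
set. Z-score and min-max are idempotent on non-constant data.

## Reusable components

The component vocabularies name classical procedures; the package fixes one
published reference behaviour per token, each behind a registry entry so a
variant can be swapped in without touching the engine.

**Distances.** EUCLIDEAN and CITY are the L2/L1 metrics. CORREL is
1 − Pearson correlation and COSINE is 1 − cosine similarity, both in [0, 2].
A correlation against a constant vector (or cosine against a zero vector) is
undefined; it maps to distance 1 — the maximal-dissimilarity midpoint — and
is logged, rather than raising, so a 2016-configuration grid never aborts
mid-run on a degenerate gene profile.

**Initializations** (k centers from the data, under the spec's distance):

- `RANDOM`: k distinct instances, uniform without replacement.
- `KMEANS++`: D² sampling — each next center drawn with probability
  proportional to the squared distance to the nearest chosen center.
- `DIANA`: divisive hierarchy via the classic splinter-group rule (seed the
  splinter with the object of largest average dissimilarity; migrate objects
  while they are closer on average to the splinter than to the remainder),
  always splitting the cluster of largest diameter, until k clusters; their
  mean vectors are the centers. Deterministic.
- `PCA`: project onto the first principal axis, cut the projected range into
  k equal-width bins, take the mean of each non-empty bin; empty bins are
  filled by farthest-point selection. Deterministic.
- `XMEANS` / `GMEANS`: grow from a local 2-means solution, repeatedly
  splitting the cluster whose local 2-way split most improves a spherical
  BIC (XMEANS) or whose projection onto the split direction fails an
  Anderson–Darling normality test at the 5% level (GMEANS). Because the
  engine needs exactly k centers, farthest-point splits are forced if the
  criterion stops early.
- `SPSS`: a QUICK-CLUSTER-style stream — seed with the first k instances,
  then let an instance replace the nearer member of the closest center pair
  whenever it is farther from its nearest center than that pair is from each
  other. Whether the original tool's behaviour is matched in every corner is
  unknowable from its documentation; this is the documented selection rule.

**Updates.** MEAN and MEDIAN are coordinate-wise per cluster; empty clusters
keep their previous center. ONLINE is one MacQueen pass in seeded random
order with rate 1/(t+1), where the prior center counts as one
pseudo-observation — so a single pass leaves each center at the running mean
of (previous center, its instances). The schedule is a registry entry.

**Internal validity measures.** COMPACT is the mean instance-to-representative
distance (lower better). SILHOU is the global mean silhouette under the
chosen distance, with s(i) = 0 for singletons (higher better). AIC and BIC
use the x-means spherical identical-variance Gaussian log-likelihood with
p = k·d + 1 free parameters and penalties 2p and p·ln n; the squared chosen
distance stands in for squared Euclidean deviations so the measures compose
with all four distances (lower better). XB is the Xie–Beni index
Σ d(xᵢ, repᵢ)² / (n · min separation²) (lower better). CONN is Handl–Knowles
connectivity with L = 10 nearest neighbours (clipped to n−1), weighting the
j-th violated neighbour by 1/j (lower better). BIC ≥ AIC on the same fit
whenever ln n > 2, i.e. n ≥ 8.

## Clustering engine

`run_algorithm` applies the spec's normalization, initializes, then iterates
assign/update until assignments repeat, the largest center shift drops below
`tol`, or `max_iter` is reached. Conventions, all deterministic: exact
assignment ties go to the lowest cluster index; an empty cluster is reseeded
at the instance farthest from its current representative. Defaults
`max_iter=100`, `tol=1e-6`, `n_restarts=1` keep full-grid runs tractable;
with restarts, derived seeds are spawned and the restart preferred by the
spec's evaluate component (under its orientation) is returned. The evaluate
component plays no role inside the iteration — it selects among restarts and
is exported as a meta-attribute, nothing more. For MEAN + EUCLIDEAN the
within-cluster sum of squares is non-increasing across iterations (Lloyd
monotonicity), which the test suite asserts from recorded iteration history.

The number of clusters defaults to the number of distinct true labels (the
usual convention on labelled benchmark collections), with an explicit
override. The experiment grid records one row per (dataset, algorithm) keyed
by (dataset id, algorithm name, run seed); per-run failures are caught,
flagged in a `status` column and excluded from the valid count, never fatal,
and a partial table can be passed back to resume.

## External validation

AMI = (MI − E[MI]) / (normalizer − E[MI]), natural logarithms, with E[MI]
the exact expectation under the fixed-marginal permutation (hypergeometric)
model, computed with log-space factorials. The normalizer is the arithmetic
mean of the two entropies by default (max, min and geometric variants are
registered, since conventions differ across the literature). Degenerate
conventions, fixed and tested: partitions identical up to relabeling give
exactly 1 (including two all-singleton partitions, where the adjustment
denominator vanishes analytically); if either partition is a single cluster
the index is 0, since MI and E[MI] are both identically zero there.

## Meta-attributes

Thirteen dataset descriptors, computed on the raw (unnormalized, unimputed)
matrix, in a declarative registry pinned to size 13 so the total
meta-attribute count stays 24: log₂ instances, log₂ features,
instance/feature ratio, % missing cells, mean per-feature skewness, mean
per-feature excess kurtosis, % outlier instances (centroid distance above
mean + 2 sd), Mardia's multivariate skewness (computed through the SVD/Gram
identity, so the d×d covariance is never formed and singular covariances are
handled by construction), mean absolute feature-feature correlation,
% low-variance features (below 10% of the median feature variance), number
of true classes and normalized class-balance entropy (absent without
labels), and the nominal chip type. All are invariant to instance and
feature order. The outlier and low-variance thresholds are fixed documented
defaults; descriptor sets of this kind vary across studies, which is exactly
why the registry is declarative.

A metaexample row is these 13, plus the 5 nominal algorithm descriptors
(four RC tokens and the normalization tag), plus the 6 internal measures,
labelled by AMI and keyed by dataset and algorithm ids.

## Metalearning

Preprocessing dummy-codes every nominal meta-attribute into a full one-hot
block (algorithm descriptors use the complete component vocabularies, so the
indicator layout never depends on which levels a particular repository
contains) and mean-imputes missing numerics with training-column means; the
learned recipe is stored inside the model and replayed verbatim at predict
time, with unseen nominal levels mapping to all-zero indicators (logged).
Every model carries a schema fingerprint checked on each predict.

The five regressor families map to standard estimators: LR = ordinary least
squares; LMSR = least median of squares via PROGRESS-style random elemental
subsets (200 seeded subsets; the all-data LS fit is always a candidate) —
written in-package because no mainstream library ships one; RBFN =
RBF-kernel ridge regression; NN = a single-hidden-layer (32-unit)
perceptron; SVM = ε-SVR with RBF kernel. All sit behind a feature scaler.
Hyperparameter grids are small fixed defaults explored only by the
prescribed 10-fold CV on the training side. Evaluation uses a seeded 70/30
split performed by shuffling sorted row keys — not positions — so row order
cannot change the split; an optional grouped mode keeps each dataset
entirely on one side, because ungrouped splits leak dataset identity between
train and test. Selection minimizes holdout RMSE, breaking ties by MAE and
then by a documented kind order; the report carries MAE, RMSE and the sample
sd of absolute errors. A regressor that fails to fit is excluded with a
logged reason. Models persist via joblib inside a version-tagged envelope;
loading a truncated, foreign or version-mismatched file is an error, and a
reloaded model predicts bitwise identically.

Ranking a new dataset comes in two modes, because six of the 24
meta-attributes only exist after clustering: `a_priori` predicts with those
six left missing (imputed by the recipe's training means — cheap screening),
while `post_hoc` runs each candidate and fills in observed internal measures,
reproducing the full schema. Output is sorted non-increasing by predicted
AMI with name tiebreak.

## Synthetic data

`generate_expression` draws k spherical Gaussian classes (σ = 1) whose
centers sit on a scaled simplex in the first k coordinates, so every pair of
centers is exactly `separation`·σ apart (this requires at least k features).
Spherical Gaussians are the model the AIC/BIC components assume, so the
model-based indices are exercised in-distribution; a Student-t(3) flag
provides a heavy-tailed stress variant for MEDIAN/outlier paths. Optional
knobs add uniformly random missing cells (never emptying a whole feature),
outlier instances resampled uniformly from an inflated bounding box, and a
shared latent factor with loading √ρ that induces pairwise feature
correlation ρ. Everything is a deterministic function of the seed.

What the generator does **not** emulate: dye bias, probe effects,
batch/array artefacts, non-spherical or nested class structure, and
realistic gene-gene covariance beyond the single latent factor. Passing
tests therefore demonstrate correctness of the machinery and recoverability
of planted structure — not clustering performance on real microarray data.

`generate_meta_benchmark` spans dataset sizes 40–120, 10–40 features, 2–5
classes, separations 1–8σ and up to 5% missingness. Its oracle-label mode
synthesizes AMI labels directly from a declared function of the
meta-attributes (default: +0.3 for CORREL-distance algorithms, optionally
conditional on a metafeature threshold, plus N(0, 0.02) noise, clipped to
[0, 1]), filling internal-measure slots with uninformative noise — this
tests the metalearning stack with a known ground truth and no clustering
cost. Clustered mode runs the real grid.

## Problem sizes in the acceptance script

The headline evaluation quantities are recomputed at desk scale: 20 random
100×10 datasets for Lloyd-oracle agreement; every set partition of 2–7 items
against three reference partitions plus 200 random pairs (≈3,700 pairs) for
AMI exactness, and 1,000 random partition pairs at n = 60 for chance
adjustment; a 2,000-row oracle benchmark (100 datasets × 20 algorithms) for
linear effect recovery and a 500-row conditional benchmark with 20 held-out
datasets for top-1 ranking; and a fully clustered end-to-end repository of
10 synthetic datasets × 24 algorithm configurations (240 runs) for metamodel
training and holdout errors. These sizes are the package's own scaled-down
study design; the holdout errors on 240 noisy clustered rows are naturally
larger than what a repository of tens of thousands of metaexamples over real
benchmark collections would support.

## Known limitations

- The exact descriptor set and normalization quartet used by earlier
  metalearning studies on microarray collections are not recoverable from
  their publications; the registries here are documented substitutes with
  the same block sizes.
- The x-means-style AIC/BIC with non-Euclidean distances is a pragmatic
  composition, not a generative model.
- LMSR is an approximate LMS optimizer (random subsets); exact LMS is
  combinatorial.
- The grid runner is single-machine; no distributed execution.
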