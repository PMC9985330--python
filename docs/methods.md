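# Methods

This note documents the models implemented in `batchrank`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducibility.

## Meta-experiment assembly

Experiments are nodes of a linkage graph with an edge whenever two
experiments share at least one category of a single user-designated
biological covariate. Linking on one covariate (rather than on any shared
annotation) keeps the rule predictable and testable; multi-covariate linking
is a possible extension. The retained set is the largest connected
component — ties broken by total sample count, then by the lexicographically
smallest id set — and everything else is discarded with a logged reason.
Merging intersects gene sets (union-with-missing would poison the
correction models with imputed values, and intersecting matches the reality
that older platforms limit the matching gene pool; the lost fraction is
logged), sorts genes lexicographically, and concatenates columns in
experiment-id order. Sample ids colliding across experiments are prefixed
with the experiment id.

## Correction models

**limma-style removal.** Per gene, ordinary least squares of expression on
[intercept, bio indicators (optional), sum-to-zero batch contrasts]; the
fitted batch component is subtracted. Sum-to-zero coding makes the batch
effects average out, so per-gene grand means survive correction. A design in
which batch and biology are confounded is rejected as rank-deficient rather
than silently dropping one factor.

**ComBat (empirical-Bayes location/scale).** Genes are standardized by the
grand mean, the optional covariate fit, and the pooled residual variance.
Per-batch per-gene location (γ) and scale (δ²) estimates are shrunk toward
batch-level priors: `ComBat1` uses the parametric pair — normal prior on γ,
inverse-gamma on δ², hyperparameters by method of moments, posteriors by
fixed-point iteration (tolerance 1e-4 on the maximum relative change, cap
100 iterations, warn on non-convergence); `ComBat2` uses non-parametric
likelihood-weighted empirical posteriors (each gene's posterior is the
likelihood-weighted average of all other genes' estimates). `Q_ComBat` is
quantile normalization followed by parametric ComBat. When the δ² estimates
of a batch are (numerically) constant — e.g. quantile-constant input — the
inverse-gamma moments are undefined, so scale shrinkage is skipped for that
batch and only the location is shrunk. A `mean_only` switch (location-only
adjustment) exists for users who read "non-empirical" as mean-only; it is
not the default.

**naiveRandRUV.** Unwanted factors are the first k left singular vectors
(scaled by singular values) of the sample-by-control submatrix; loadings are
a ridge solve `(WᵀW + νI)⁻¹WᵀY` and `Wα` is removed from all genes. Control
genes come from a packaged human housekeeping list (60 symbols from
standard RT-qPCR reference panels and RNA-seq stability screens;
user-replaceable via a one-symbol-per-line file) or, in empirical mode, the
m least-variable genes after removing per-batch gene means
(m = max(100, 5% of genes)). Defaults k = 2 and ν = 1e-2 · (mean control
singular value)² — scaling ν to the data keeps the ridge meaningful across
expression scales. Quantile-combined variants normalize first.

**ComBat-seq (counts).** Per gene, a log-linear NB mean model with batch
indicators (plus bio covariates in the full model) and a log library-size
offset, fitted by vectorized Poisson IRLS (for categorical designs the
Poisson score equations give the NB mean MLE, which is all the mapping
needs). Per-batch dispersions are per-gene Newton MLEs on the NB
log-likelihood in log φ with a method-of-moments start and fallback, floored
at 1e-8 and capped at 1e3. Each count c is mapped through the CDF midpoint
`(F(c−1)+F(c))/2` of its batch NB and inverted on the batch-free NB (batch
coefficients replaced by their sample-share weighted average; pooled
dispersion re-estimated under the batch-free means). The midpoint rule is a
deterministic tie-break — no random jitter — so corrected counts are
reproducible integers. All-zero genes pass through unchanged.

**RUVs (counts).** On log2(count+1): every biological replicate group is
centred at its group mean (a usable design needs at least one bio category
spanning ≥ 2 batches, otherwise the factors would absorb biology); the top-k
singular vectors of the centred sample-by-control matrix are regressed out
of all genes, and the result is exponentiated back and rounded to
non-negative integers. Defaults: k = 1, controls = all genes.

**mnnCorrect.** Samples are cosine-normalized; batches are merged
sequentially in experiment-id order. Mutual nearest-neighbour pairs
(Euclidean, default k = 20 capped at the smallest batch size − 1) between the
growing reference and the next batch define per-pair correction vectors
(reference − target), smoothed over the target batch with a Gaussian kernel
(σ = 0.1 on the normalized scale) and added; the reference is never
modified. Output is rescaled by the stored per-sample norms. Cosine
normalization can be switched off (`cosine=False`) for users who prefer raw
log-scale geometry on bulk data.

For RNA-seq meta-experiments the Gaussian-scale methods (limma, ComBat
variants, RUV, MNN) operate on library-size-normalized log2(CPM+1); the
count-native methods receive raw counts and their outputs are log-CPM
transformed before scoring, so all metrics compare matrices on the same
scale. The `uncorrected` baseline for counts is the log-CPM matrix itself.

## Evaluation metrics

All six scores live in [0, 1]. PCA retains min(20, samples−1, genes)
components of the gene-centred matrix.

* **PVCA (e1 batch, e4 biology).** Leading PCs are kept until they explain
  60% of total variance (minimum 3) — the convention of the established
  PVCA tooling. Per PC, a mixed model with random effects {batch, bio,
  batch×bio} is fitted by REML: the restricted log-likelihood over the four
  variance components is maximized directly with L-BFGS-B on log-variances
  (the response is standardized first for conditioning), started from
  ANOVA-type moment estimates, which also serve as the fallback if the
  optimizer fails. Per-factor proportions are eigenvalue-weighted averages
  across retained PCs.
* **Silhouette (e2).** |mean silhouette| with batches as clusters, Euclidean
  distance in the top-20 PC space (PC space rather than gene space for
  robustness and speed).
* **pcRegression (e3).** Per retained PC, the one-way R² of scores on batch;
  e3 is the eigenvalue-weighted average — R² weighting only, without a
  p-value screen, which keeps the score deterministic and smooth.
* **Entropy of batch mixing (e5).** min(100, S) query samples drawn without
  replacement; each query's k = min(15, S−1) nearest neighbours in the
  PC1–PC2 plane; Shannon entropy of the neighbour batch composition,
  normalized by log(#batches) so perfect mixing scores 1 for any batch
  count. Sample ids are sorted before seeding, making the score invariant to
  input column order; the query draw is the only sampled step in the whole
  pipeline and is driven by a per-method substream of the master seed.
* **HVG union (e6).** Highly variable genes are those with the largest
  variance in excess of a quadratic least-squares mean-variance trend
  (quadratic rather than loess: fully deterministic, no smoothing
  parameters); n_top defaults to max(50, min(1000, 10% of genes)). e6 is the
  fraction of the union of per-experiment HVG sets that remains highly
  variable after correction.

With fewer than ~2k samples per batch, e5's fixed neighbourhood of 15 makes
small meta-experiments look better-mixed than they are (at 8 samples per
batch the neighbourhood spans most of the data); e1–e3 carry the
discrimination at that scale.

## Ranking

e1–e3 are negated, then all six columns are dense-ranked (ties share a rank,
no gaps); sumRank is the ascending dense rank of the per-method rank sum.
This is the only direction convention under which rank 1 denotes the best
method on both ends. Ties persist to sumRank — no secondary tie-break — and
reports list tied methods alphabetically. Metric subsets are configurable
but the default uses all six.

## Synthetic data

The microarray generator draws per-gene baselines from Normal(7, 1.5²)
(typical log2 intensity scale), adds a ±1 log2-unit biological effect to 10%
of genes, perturbs an affected gene fraction (default: all genes) per batch
with location offsets Normal(0, 1²) and noise-scale factors
LogNormal(0, 0.2²), and adds Normal(0, 0.5²) noise — i.e. data generated
exactly under the location/scale model that ComBat assumes. The count
generator draws base means LogNormal(4, 1²) (median ≈ 55 counts), per-gene
dispersions LogNormal(log 0.2, 0.5²), applies 2^(±1) batch mean multipliers
to 10% of genes plus batch dispersion multipliers LogNormal(0, 0.2²), and
samples NB counts. Default design: three batches of 10 samples, two
biological levels balanced within batch. Ground truth (the exact batch-free
matrix and the injected components) is stored, so an oracle correction is
available for calibration tests.

What the generator does **not** emulate: gene–gene correlation, platform-
specific intensity distributions, outlier samples, unbalanced designs and
library-size extremes. Tests passing on this data show that the estimators
recover the generating model and that the metrics and ranking discriminate
under it — not that any method is best on a particular real dataset.

The simulation bundle (experiment TSV pairs plus a `ground_truth/` directory
of TSV/JSON files) is plain text throughout.

## Problem sizes and determinism

The shipped tests and the acceptance script use 200–1000 genes,
2–3 batches and 6–100 samples per batch — enough for the statistical checks
(e.g. 20-seed ranking recovery on 1000 genes × 24 samples, ComBat-seq
recovery on 1000 genes × 100 samples) while keeping a full run in tens of
seconds. All randomness flows from one master seed through derived
substreams; two pipeline runs with the same seed and inputs produce
byte-identical TSV outputs (floats are written at fixed precision — %.12g
for bundles, %.10g for reports).

## Known limitations

* PVCA's REML on 20–30 samples has limited resolution; variance shares of
  weak factors are noisy, which is why the benchmark aggregates ranks rather
  than raw scores.
* The housekeeping control list is human-specific; for other species or
  simulated ids the housekeeping RUV variants are skipped (logged) and
  empirical controls should be used.
* ComBat-seq's quantile mapping preserves integer counts but not library
  sizes exactly; downstream tools should renormalize.
* scBatch-style distance-matrix optimization is not implemented; externally
  corrected matrices can be injected for ranking via the plugin flag.
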