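# Methods

## Problem setting

A whole-slide image (WSI), after tissue detection and tiling, becomes a
*bag* of thousands of patch feature vectors; only the slide-level binary
label (e.g. HER2 status from IHC) is known. The multiple-instance
learning (MIL) decomposition is

```
Ŷ_i = R( S( {T(t_j^i)}_{j=1..n_i} ) )
```

with `T` the (external, pluggable) patch feature extractor, `S` the
aggregation over instances, and `R` the bag-level classifier. This
package implements a phenotype-guided `S`: a clustering function
`φ({P_i}) → {p_k}_{k=1..L}` discovers L *prototypes* — recurring
feature-space patterns across slides — and aggregation is performed by
cross-attention between prototypes and instances. The motivation is
intratumoral heterogeneity: positive and negative cell populations
coexist within one section, so a bag summary should be expressed
relative to a vocabulary of recurring morphologies rather than a single
pooled vector.

## Prototype discovery

Two-stage affinity propagation (AP), fitted on training bags only:

1. **Stage 1 (per bag):** AP on a bag's instances yields `c_i`
   exemplars, each an exact row of the bag (real data points, not
   averages).
2. **Stage 2 (across bags):** AP on the union `C = ∪_i {exemplars_i}`
   yields the final prototypes `{p_k}`, with `L < Σ c_i` whenever the
   union holds more than one point.

Similarity is the negative normalized Euclidean distance raised to a
power: rows are L2-normalized, then `S[a,b] = −‖x̂_a − x̂_b‖₂^β`. The
exact normalization and exponent are open choices in this architecture;
here "normalized" is read as row L2-normalization (making the metric a
monotone function of cosine distance) and β defaults to 2. Both are
exposed in `SimilarityConfig` with no claim that other implementations
chose identically.

AP itself is the standard responsibility/availability message passing
with damping λ = 0.5 (against oscillation), preference = median
off-diagonal similarity (the conventional default), `max_iter` 200,
`convergence_iter` 15, followed by the conventional final medoid
refinement (each exemplar moved to the point maximizing intra-cluster
similarity). Tie-breaks are deterministic (lowest index). Degenerate
all-identical input produces no exemplar from the messages; the
implementation falls back to a single exemplar at index 0 and flags
non-convergence. If stage 2 degenerately keeps every point, it is rerun
with a more negative preference and, failing that, reduced to the single
best exemplar by net similarity, preserving the `L < Σc_i` contract.
Bags above `max_bag_instances` (default 10 000) are seeded-subsampled
before stage 1, since AP is O(n²) in memory and real bags reach 10⁵
patches.

## Cross-attention aggregation

With instances `P_i (n×d1)` and prototypes `{p_k} (L×d1)`:

```
P̂_i = f_p(P_i),  p̂_k = f_p(p_k)          # shared linear d1 → d3
Q = w_q(p̂),  K_i = w_k(P̂_i)              # linear d3 → d3
M_i[k,j] = ⟨Q_k, K_j⟩ / (‖Q_k‖₂ ‖K_j‖₂)   # cosine, entries in [−1,1]
```

The L×n matrix `M_i` *is* the bag representation. The per-pair cosine
normalization is an interpretation (a global norm would not bound the
entries); it makes each entry a scale-free alignment between one
prototype and one instance, and the classifier heads own the reduction
over the instance axis. Zero-norm vectors yield cosine 0 by convention
(a small ε inside the square root), never NaN.

Prototype modes: `cluster` (frozen AP prototypes), `random_fixed`
(frozen uniform random vectors on `[−1/√d1, 1/√d1]`), `random_learnable`
(same init, optimized with the model), and `none` (self-attention: the
projected instances serve as their own queries). In `none` mode the
measurement is n×n and therefore variable-width along both axes; to
keep the classifier input fixed, the query axis is mean-pooled first,
giving a 1×n effective measurement. This is a design choice where the
architecture is silent; it is the most conservative fixed-width
reduction.

## Classifier heads

- **mean**: instance-axis mean `M̄ ∈ R^L` → MLP (linear, ReLU, linear) →
  2-class softmax.
- **attention**: per-column scores (tanh scorer), softmax over columns,
  weighted column sum → the same MLP.
- **transformer**: columns as an unordered token set (width L), a
  learnable class token, one encoder layer (multi-head self-attention +
  feed-forward, residuals, layer normalization), no positional encoding;
  class-token output → linear → softmax. L must be divisible by
  `n_heads`; with AP-derived L (data-dependent), `n_heads=1` is the safe
  setting.

All heads are permutation-invariant in the instance axis up to
floating-point summation order (asserted at atol 1e-12; exact bit
equality is not a meaningful target because reordering changes the
summation sequence).

## Dual instance sampling

Per training epoch and bag: a uniform random subset of R instances,
then the S = min(S, ·) instances with the highest selector scores (a
linear layer on the raw d1 features, applied before the shared
projection). The shipped defaults mirror the sampling grid explored at
WSI scale (R ∈ {10000, 5000, 2000, 1000, 500, 200}, S = 500); on
desk-scale synthetic bags (32–128 instances) these defaults make the
sampling an identity, which is exactly the R ≥ n contract. Sampling is
disabled at inference. Ties in mining break to the lower index.
Limitation: hard top-S selection is not differentiable, so the selector
layer receives no gradient from the bag loss; it acts as a fixed random
projection unless trained by other means. This mirrors the selector's
definition; making it trainable (e.g. multiplying scores into the
embeddings) would change the architecture and is out of scope.

## Training and evaluation

Mean binary cross-entropy over bag probabilities (clamped at ε = 1e-7),
minimized with Adam (lr 2e-4, weight decay 1e-5), batch size 8, up to 30
epochs with early stopping on validation loss (patience 10) and
best-state restoration. These hyperparameters follow common MIL practice
and are fully exposed; no fidelity claim is made to any external
training schedule. Repeats offset the base seed by the repeat index.
Optional inverse-frequency class weighting is available (off by
default) for imbalanced cohorts.

Because no tensor framework is assumed, the model runs on a small
reverse-mode autodiff core (`protomil.autograd`) over float64 NumPy
arrays; analytic gradients are validated against central finite
differences for every parameter group and head/mode combination.

Metrics: posF1, support-weighted precision/recall/F1, balanced accuracy,
AUROC (tie-aware rank statistic) and AUPRC (average precision). They are
implemented explicitly in `protomil.metrics` and validated against
scikit-learn to 1e-9 in the test suite.

## Interpretability

For the mean head, each measurement column is passed through the MLP and
softmax individually, giving a positive-class probability per patch
(when the MLP acts affinely, the mean of per-instance logits equals the
bag logit, so the read-out is exact, not a heuristic). Scores are
min-max normalized to [0,1] (a constant vector maps to 0.5 — the
degenerate case needs a convention), painted onto a raster at
1/downsample scale; cells covered by several patches average their
scores and untouched cells are NaN (absent), never 0. Per-instance
read-out for the attention/transformer heads is undefined here and
raises rather than guessing. A per-prototype score table (instance-axis
mean of each measurement row, per bag) is exported for
phenotype-vs-prediction analysis.

## Synthetic cohort generator

Bags are drawn from a K-component isotropic Gaussian mixture in feature
space: centers on a random sphere, rejection-checked so all pairwise
distances ≥ separation·scale; one component is the signal phenotype; a
bag is positive iff its realized signal fraction ≥ τ. Defaults (chosen
once as the study conditions): K=4, d1=64, separation 8, scale 1, 200
bags of 32–128 instances, 40% positive, signal fraction of positive
bags uniform in [0.15, 0.6], τ=0.1, negatives signal-free (an optional
hard-negative mode allows sub-threshold contamination). Splits are
label-stratified 60/20/20. Coordinates are laid on a 256-pixel grid.

What the generator emulates: variable bag sizes, weak labels driven by
a minority population, recoverable phenotype structure. What it does
not: the geometry of real contrastively learned patch embeddings,
spatial correlation of tissue, staining/scanner variation, or any
morphological complexity. Consequences observed and accepted:

- **Recovery radius vs dimension.** A Gaussian sample in d dimensions
  concentrates at ≈ √d·scale from its center, so "a prototype within
  3·scale of each planted center" is only geometrically attainable for
  exemplars (actual data rows) in low dimension; recovery checks run at
  d1 = 8 (where the closest of hundreds of samples is well inside
  3·scale), classification checks at the desk-scale d1 = 64.
- **Mode saturation.** The mixture task is separable enough that every
  prototype mode — including self-attention with no prototypes —
  reaches held-out AUROC ≈ 1.0 on the standard cohort. Passing
  classification tests therefore shows the machinery learns; it cannot
  show the *advantage* of clustering-derived prototypes over random or
  absent ones, which on real slides stems from morphological complexity
  this generator deliberately omits. The ablation-ordering check
  documents this: its weak inequalities hold (with equality), the
  strict cluster-over-self-attention gap does not materialize under
  these conditions, and the corresponding test records that honestly
  rather than relaxing the condition.

## Numerical choices

- float64 throughout; cosine ε = 1e-24 inside the square root.
- Similarity matrices exactly symmetrized, zero diagonal before
  preference insertion.
- Loss clamp ε = 1e-7; softmax max-shifted (shift detached).
- Deterministic seeds: cohort/bag seeds derive from the spec seed;
  per-epoch sampling seeds derive from the training seed; repeat r uses
  seed + r.
- Problem sizes in tests and the acceptance script (200-bag cohorts,
  d1 = 64 for learning, d1 = 8 for recovery, 20 clustering-agreement
  instances) are desk-scale choices that keep the full pipeline
  reproducible on a laptop CPU while preserving every contract being
  checked.

## Known limitations

- AP is O(n²) memory; very large bags rely on the pre-subsampling cap.
- The selector layer is untrained under pure top-k mining (above).
- Per-instance interpretability exists only for the mean head.
- The transformer head requires L divisible by `n_heads`.
- Synthetic results do not transfer claims to real cohorts; the
  generator is a testbed for contracts, not a simulator of histology.
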