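# protomil

Phenotype-prototype-guided multiple instance learning (MIL) for weakly
supervised whole-slide biomarker prediction.

## What problem this solves

Predicting a molecular label (e.g. HER2 status in breast cancer) from an
H&E whole-slide image is a weakly supervised problem: a slide yields a
*bag* of thousands of patch feature vectors `P_i ∈ R^{n_i × d1}`, but
only the bag-level label `Y_i ∈ {0,1}` is known. Tumors are
heterogeneous — positive and negative cell populations coexist in one
section — so a good bag summary should express each patch relative to a
vocabulary of recurring tissue *phenotypes* rather than pool everything
into one vector.

`protomil` implements the full pipeline for researchers working with
pre-extracted patch features:

1. **Prototype discovery** `φ({P_i}) → {p_k}_{k=1..L}`: two-stage
   affinity propagation (from scratch, with the similarity
   `S[a,b] = −‖x̂_a − x̂_b‖₂^β` on L2-normalized rows, damping 0.5) —
   per-bag exemplars first, then cross-bag prototypes, fitted on
   training bags only, with `L < Σ c_i`.
2. **Cross-attention aggregation**: a shared projection `f_p : d1 → d3`,
   Query = projected prototypes, Key = projected instances, and the
   **measurement matrix**
   `M_i[k,j] = ⟨Q_k, K_j⟩ / (‖Q_k‖₂‖K_j‖₂) ∈ [−1,1]^{L×n_i}`
   as the bag representation.
3. **Classifier heads** over the instance axis of `M_i`: mean+MLP,
   attention-weighted sum, or a transformer encoder with a class token —
   plus four prototype modes (`cluster`, `random_fixed`,
   `random_learnable`, `none`/self-attention) and dual instance sampling
   (random R, then top-S score-based mining) as training-time
   augmentation, trained with cross-entropy.
4. **Interpretability**: exact per-patch probabilities under the mean
   head, min-max normalized and painted as spatial heatmaps, plus
   per-prototype score tables.

A synthetic cohort generator with planted Gaussian phenotypes (one
signal phenotype whose within-bag fraction drives the label) makes every
stage testable without slide data or a pretrained extractor. The model
runs on a small built-in reverse-mode autodiff core over NumPy, so the
package has no deep-learning framework dependency.

## Worked example

```python
import protomil as pm

# a synthetic cohort: 4 phenotypes in d1=64, 200 bags, 40% positive,
# positives carry 15-60% signal instances against threshold tau=0.1
bank = pm.generate_phenotype_bank(K=4, d1=64, separation=8.0, seed=1)
cohort = pm.generate_cohort(pm.CohortSpec(seed=1), bank)

# prototypes from the training split only
protos = pm.build_prototypes(cohort.split_bags("train"), seed=1)
print(protos.L, "prototypes from", protos.stage1_union_size, "stage-1 exemplars")
# -> 19 prototypes from 776 stage-1 exemplars

# train the cluster-prototype model with the mean head and evaluate
state, history = pm.train(
    cohort, protos,
    pm.ModelConfig(d1=64, prototype_mode="cluster", head="mean", seed=1),
    pm.TrainConfig(seed=1, epochs=30),
)
report = pm.evaluate(state, cohort, "test")
print({k: round(v, 3) for k, v in report.metrics.items()})
# -> {'posF1': 0.968, 'wPRC': 0.976, 'wREC': 0.975, 'wF1': 0.975,
#     'bACC': 0.969, 'auroc': 1.0, 'auprc': 1.0}
```

The prototypes are exact instance rows recovered near the planted
phenotype centers; the held-out AUROC of 1.0 says the bag-level label
(signal fraction ≥ τ) is fully recovered from weak labels alone. Per-bag
heatmaps come from `pm.bag_heatmap(bag, state)`; the normalized patch
scores highlight the signal-phenotype instances inside positive bags.

The same pipeline is available as a CLI:

```bash
protomil simulate --n-bags 200 --d1 64 --seed 1 --out data/
protomil cluster  --manifest data/manifest.csv --out protos.h5
protomil train    --manifest data/manifest.csv --prototypes protos.h5 --out-dir run/
protomil eval     --checkpoint run/checkpoint.h5 --manifest data/manifest.csv \
                  --split test --out eval.json
protomil heatmap  --checkpoint run/checkpoint.h5 --bag data/bag0000.h5 \
                  --downsample 32 --top-k 3 --out-prefix hm/bag0000
```

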