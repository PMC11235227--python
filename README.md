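# tissuemil

Quality-weighted, tissue-based multi-instance learning for renal
whole-slide histology.

## The problem

Pre-implantation kidney biopsies are graded for transplant decisions, but
expert delineations are scarce and slides are small, artefact-ridden and
weakly labelled: usually only a slide-level outcome (delayed graft
function, acute tubular injury grade, Remuzzi components) is known, not
which tissue caused it. Multi-instance learning (MIL) fits this setting —
each slide is a *bag* of segmented tissue compartments (*instances*:
tubules, glomeruli, vessels, nuclei) with one label — but classical
max-pooling MIL is brittle when many instances are poorly segmented or
artefactual.

`tissuemil` implements a workflow for this regime, aimed at computational
pathology researchers:

1. **Ensemble fusion with uncertainty penalty.** Per-pixel maps from a
   segmentation ensemble are fused as `p̃ = max(p̄ − A·σp, 0)`: pixels the
   models disagree on are suppressed, which removes false-positive
   segments produced by a subset of models.
2. **Instance extraction and quality weights.** Tissue instances come from
   a max-flow/min-cut binarisation of `p̃`; each instance `k` receives a
   quality weight from the ensemble disagreement over its mask,
   `g_k = (max_j s_j² − s_k²)/(max_j s_j² − min_j s_j²) ∈ [0, 1]`,
   with `s_k` the mean of `σp` over the mask.
3. **Per-instance features.** Handcrafted morphology / colour / texture /
   nuclei-distribution features (e.g. lumen-to-total *area* ratio,
   urinary-space area, nucleus darkness pooled at every tenth percentile)
   plus pluggable deep embeddings, with train-split-fitted imputation and
   normalisation.
4. **Gated soft-attention MIL.** Instances are embedded, scored by
   `s_k = wᵀ(tanh(V h_k) ⊙ sigmoid(U h_k))`, and pooled as
   `z = Σ_k softmax(s)_k h_k`. With quality weighting the scores are scaled
   by `g_k` before the softmax — at train *and* test time — so contested
   instances lose influence.
5. **Tissue-count-weighted evaluation.** ROC/PR curves weight each slide by
   its tissue count; AUCs aggregate over 5 folds × 5 seeds (donor-grouped
   3:1:1 splits) with unbiased standard errors and inverse-variance pooling
   across tasks.
6. **Visualisation.** Attention rendered strictly inside tissue outlines
   (not tile grids), plus within-instance occlusion saliency from an
   attention-distilled student network.

Real biopsy slides are access-restricted, so the package ships a synthetic
generator (biopsy-like slides with analytic ground truth, simulated
ensemble disagreement, MIL bag sets with controllable contamination) that
exercises every stage; see `docs/methods.md` for what the synthetic
material does and does not emulate.

## Worked example

Train a quality-weighted attention model on synthetic bags with 30%
corrupted instances (features that mimic the signal, high ensemble
disagreement), then score the held-out fold:

```python
import numpy as np
import tissuemil as tm
from tissuemil.mil import ModelConfig, donor_folds
from tissuemil.fusion import quality_weights_from_s2

bags = tm.make_bags(tm.BagSetConfig(n_bags=200, effect_size=3.0,
                                    contamination=0.3, seed=21))
for b in bags:
    b.g = quality_weights_from_s2(b.sigma2)   # Eq.-style min-max of s^2

tr, va, te = donor_folds(bags.bags, 5, seed=0)[0]
model = tm.AttentionMIL(bags, ModelConfig(n_features=10, max_epochs=120,
                                          use_quality_weights=True,
                                          include_g_feature=True))
res = model.fit(tr, va, seed=0)
print(res.summary())

y = np.array([bags[i].label for i in te])
s = np.array([res.predict(bags[i])[0][1] for i in te])
w = np.array([bags[i].n_tissues for i in te], float)
print(tm.weighted_roc(y, s, w).auc, tm.weighted_pr(y, s, w).auc)
```

Output:

```
Attention-MIL results
======================================================
mode:               attention (gated)
classes:            2
features:           10 + g
embedding width:    32  attention width: 16
quality weighting:  True
epochs run:         45 (best epoch 4)
best val macro AUC: 0.9192
train/val bags:     120/40
seed:               0
======================================================
0.850...  0.887...
```

The summary reports the protocol (gated attention, quality weighting on,
early stop at 40 stagnant epochs restoring the best-validation checkpoint);
the two numbers are the tissue-count-weighted test ROC-AUC and PR-AUC of
this single model. Averaged over 10 seeds, the quality-weighted model
scores ≈ 0.72–0.94 AUC depending on the generator seed while the same model
without `g` drops by ≈ 0.1–0.2 and the max-pooling baseline further still —
the corrupted instances sway unweighted pooling, and the quality weight
recovers it.

The same workflow runs from the command line:

```bash
tissuemil synth bags --seed 3 --out-dir data/
tissuemil mil cv --instances data/instances.csv --bags data/bags.csv \
    --use-g --folds 5 --seeds 5 --out predictions.csv
tissuemil report --predictions predictions.csv
tissuemil run --out-dir experiment/ --seed 1   # full synthetic pipeline
```

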