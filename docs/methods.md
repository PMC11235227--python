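# Methods

`tissuemil` implements a weakly supervised analysis workflow for whole-slide
renal biopsy images: segmented tissue compartments (instances) are pooled by
a learned soft-attention mechanism into a slide-level (bag) prediction, with
each instance optionally down-weighted by a segmentation-quality score
derived from ensemble disagreement. This note documents the model, the
synthetic study material, the numerical choices, and what passing tests do
and do not show.

## Ensemble fusion and the quality weight

A segmentation ensemble (any source; this package does not train one)
produces per-model, per-class probability maps. Fusion computes the
across-model mean `p̄` and standard deviation `σp` per pixel and corrects
overconfident predictions with

    p̃ = max(p̄ − A·σp, 0),

where `A ≥ 0` is a penalty constant. Pixels on which the models disagree —
typically false-positive segments produced by a subset of models — are
suppressed. `σp` uses the population convention (divide by the number of
models): the ensemble is the full model set, not a sample; `ddof` is
exposed as an argument for the sample convention. `A` is a configuration
value; `fusion.sweep_penalty` selects it by maximising mean instance-level
Jaccard against reference masks, standing in for an empirical choice on
training data.

Instances are extracted from `p̃` by a two-label min-cut: unary costs
`−log p̃` (foreground) vs `−log(1−p̃)` (background) with probabilities
clamped to `[1e−6, 1−1e−6]`, and a Potts pairwise term of weight
`smoothness` on the 4-neighbour grid. Costs are scaled to integers
(scale 4096, doubled with a sub-quantum tie repair) for the max-flow
solver, which makes the zero-smoothness cut *exactly* equivalent to
thresholding at 0.5 — a property the tests exploit as an oracle.
Foreground components are 8-connected; components under `min_area_px`
(default 32 px at 0.44 µm/px) are dropped.

For a slide with instances `k = 1..K`, `s_k` is the mean of `σp` (the
instance's own class channel) over mask `k`, and the quality weight is the
slide-wise min-max normalisation of `s_k²`:

    g_k = (max_j s_j² − s_k²) / (max_j s_j² − min_j s_j²) ∈ [0, 1].

The most consistently segmented instance of a slide gets `g = 1`, the most
contested gets `g = 0`. When all `s_j²` coincide (including K = 1) every
`g = 1`: equal evidence quality should not down-weight anyone.

Crops are cut at the mask bounding box expanded by `round(pad_um / mpp)`
pixels per side (default 1.32 µm, i.e. 3 px at 0.44 µm/px); pixels outside
the mask are replaced by a Gaussian-blurred copy of the image (σ = 8 px by
default), computed before masking so tissue colour does not bleed back as
sharp structure. Masks touching the image border are kept and flagged
truncated. Note that re-cropping an already produced crop is stable but not
bit-identical outside the tissue: a Gaussian blur is not a fixed point of
itself, so the exterior drifts within blur scale while geometry and all
tissue pixels are unchanged.

## Handcrafted features

Each crop yields a fixed-length record covering the families used in
compartment-based renal morphometry: physical morphology (area µm²,
perimeter, eccentricity, solidity, enclosed-cavity "lumen" area found as
background holes inside the mask, lumen-to-total *area* ratio — a ratio of
areas, not diameters, since most vessel sections are not round — and a
urinary-space analogue: convex-hull minus mask area), colour (per-channel
mean/SD inside the compartment plus boundary-band vs interior contrasts
with a 3 px erosion boundary), texture (Sobel gradient-magnitude mean/SD),
nuclei (count, density, nucleus darkness and nucleus-centroid-to-boundary
distance, each pooled at every tenth percentile, 0th–100th inclusive, 11
values — less artefact-sensitive than max pooling), and slide-level values
(total biopsy area, tissue count) appended to every instance. The `PAS`
profile carries 44 features; `SR` drops the 24 nuclei features (nuclei are
not visible under Sirius Red) for 20. Exact counts are pinned by the schema
object, not scattered in code.

Nuclei features are *missing* (NaN), never zero, when no nuclei are
available. Imputation (column means) and zero-mean/unit-variance
normalisation (population SD) are fitted on the training split only and
applied frozen to validation/test — a leakage guard; a dataset-global mode
is available by fitting on the pooled matrix. Constant features pass
through as zeros after centring.

Deep embeddings are pluggable: an extractor maps a crop (fed at native
size, never resized, so objects of equal physical size elicit equal filter
responses) to a spatial feature map that is average-pooled over space.
Crops smaller than the extractor's minimum are padded reflectively and
flagged.

## The attention-MIL model

Instance features are embedded by one hidden tanh layer into `h_k`. The
gated attention head scores instances

    s_k = wᵀ(tanh(V h_k) ⊙ sigmoid(U h_k)),

(the sigmoid gate sharpens tanh's response for small inputs; an un-gated
variant drops it), and the bag representation is `z = Σ_k a_k h_k` with
`a = softmax(s)`, classified by a softmax head. With quality weighting the
raw scores are scaled by `g_k` *before* the softmax, at both training and
test time; `g` can additionally be appended as a feature column. With all
`g = 1` the weighted form is bit-identical to the unweighted one. The
printed form of the weighted softmax in which the denominator re-uses the
numerator's own `g_k` (and therefore does not normalise) is kept behind
`paper_literal_weighting` for comparison; the default shares the
denominator over `g_j`.

Softmax normalisation and pooling reduce in a canonical (lexicographic)
instance order, making bag predictions invariant to instance permutation
bit-for-bit. The classical MIL baseline applies the head per instance and
takes the bag's positive score as the max (binary tasks only).

Training: one bag per optimiser step (Adam, learning rate 2e−3, L2 weight
decay 1e−3 on weight matrices), bags sampled with probability inversely
proportional to their class frequency, cross-entropy loss. The validation
macro AUC is monitored each epoch; training stops once it has not improved
by more than 1e−4 for 40 consecutive epochs ("stagnation"), restoring the
best-validation checkpoint; a hard cap of 150 epochs (120 in the studies
below) bounds runtime. Defaults (embedding width 32, attention width 16)
were fixed once on the clean synthetic task. Everything — fold assignment,
weight initialisation, bag sampling — is driven by one seed and logged.

Cross-validation is donor-grouped: folds partition donors, never bags, so
no donor appears in two splits. Fold `f` tests on donor group `f`,
validates on group `f+1` (cyclic) and trains on the rest — 3:1:1 at five
folds — and each fold is trained from `n_seeds` initialisations (5×5 = 25
models). Hyperparameters are chosen by config-driven random search
maximising validation AUC on the fully labelled instance-count task, then
frozen for other tasks.

## Evaluation

Slides contribute to ROC/PR accumulators in proportion to their tissue
count, down-weighting inadequate biopsies. Tied scores step simultaneously,
so the weighted trapezoidal ROC-AUC equals the weighted pairwise
Mann-Whitney statistic with half-credit for ties (tested to 1e−12 against
exhaustive enumeration). PR curves use step interpolation (precision held
right-constant); with constant scores the PR-AUC is the weighted
prevalence. Per task, the fold×seed AUCs are averaged with an unbiased
standard error (sample SD over models / √n). Across tasks, ROC-AUCs pool
with inverse-variance weights (pooled SE `1/√Σ se⁻²`); PR-AUCs pool with
the arithmetic mean, as their variances are less trustworthy for hard
tasks. The optimal operating point of a ROC curve maximises weighted
accuracy at the pool's prevalence (the iso-accuracy tangent), ties broken
toward higher TPR. Bootstrap bands resample bags with replacement
(degenerate one-class resamples are redrawn, capped at 50 retries) and
report the median curve and min/max range.

## Visualisation

Attention overlays colour instance *outlines* (mask minus erosion, so no
painted pixel leaves the instance) on a diverging blue-to-red scale,
monotone in attention; uniform attention renders mid-scale. The tile-grid
heatmap baseline paints `ceil(H/t) × ceil(W/t)` cells with no
inter-tile interpolation. For within-instance saliency, a small student
network (crops resized to 16×16, one hidden tanh layer — depth is not the
point, the loss contract is) is distilled from a trained bag model with the
attention-scaled L2 loss `Σ_k a_k (f(x_k) − y_k)²`; occlusion saliency
slides a window (default 16 px, stride 8, fill = mean crop colour) and
records the mean score drop per covered pixel, confined to the instance
mask.

## Synthetic study material

Real pre-implantation biopsy slides are access-restricted, so the package
generates its own acceptance surface:

* **Slides** — tubule-like annular ellipses with a lumen, glomerulus-like
  capsule rings with an empty urinary-space gap around a tuft of packed
  blobs, vessel-like thick rings with configurable lumen area fraction, and
  small dark nuclei inside compartments, on a pale PAS-like background.
  Every shape records its generative parameters, so areas, ratios and
  eccentricities have analytic values; discretised areas agree within 2%
  for radii ≥ 20 px, which makes the generator the oracle for the feature
  extractor.
* **Probability stacks** — ground-truth indicators smoothed with a Gaussian
  (σ = 1 px, so maps are soft like network outputs) plus per-model,
  per-instance noise whose amplitude follows a requested disagreement
  level; optional false-positive blobs present in only a subset of models
  reproduce the failure mode the fusion suppresses.
* **Bags** — background instances are standard normal; signal instances are
  shifted by the effect size (default 3) along a fixed unit direction;
  corrupted instances *mimic the signal signature* while carrying a
  higher-mean disagreement proxy `sigma2` (gamma-distributed, mean 0.5 vs
  0.05). The mimicry conflicts with the bag label exactly where corruption
  can sway it: negative bags in the binary task, the apparent count in the
  ordinal task (the analogue of duplicated tissue sections inflating
  glomerulus counts). The ordinal mode draws the class uniformly, then a
  signal count inside the class band (<7, 7–9, ≥10), pads with 3–8
  background instances, and appends a slide-level bag-size column to every
  instance — attention-averaged representations cannot encode counts, which
  is precisely why slide-level values are appended per tissue in the real
  workflow. Default study sizes: 200 bags, 5–15 instances, 10 features,
  40 donors.

What the synthetic material does *not* emulate: stain physics and scanner
artefacts, photorealistic tissue texture, correlated instances within a
donor, class-dependent instance counts in the binary task, or the
morphology of real segmentation failures. Passing tests therefore
demonstrate that the machinery is correct and that quality weighting
rescues performance under the modelled contamination; they do not predict
AUC levels on clinical material.

## Problem sizes and determinism

The shipped studies run at desk scale by choice: 256–512 px slides, 4-model
ensembles, 200-bag datasets, 5–10 seeds per comparison, 120-epoch caps.
Every generator and training routine is a pure function of its
configuration and seed; per-stage seeds in the pipeline derive from the
global seed by stable hashing, so stages are independently reproducible.
Known numerical edge cases and their resolutions: integer-scaled min-cut
capacities carry a sub-quantum tie repair so the zero-smoothness cut equals
0.5-thresholding exactly; softmax subtracts the (order-free) max before
exponentiation; the quality-weight denominator falls back to `g ≡ 1` when
degenerate; uniform attention renders a mid-scale overlay colour rather
than dividing by a zero range.
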