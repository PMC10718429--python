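# Methods

This note records the models, parameter choices and numerical conventions
of `sharpseg`, including the places where the design was genuinely open and
what the synthetic phantoms can and cannot show.

## Data model and I/O

Images are 2-D uint8 grids; masks are aligned binary grids. The on-disk
dialect is the BUSI layout (`root/{normal,benign,malignant}/<stem>.png` +
`<stem>_mask.png`). Masks binarize at > 0 on read (source masks are 0/255).
An image may carry several mask files (`x_mask.png`, `x_mask_1.png`, …);
they are merged by pixel-wise OR — the union of the outlined regions is
taken as the ground truth when a lesion was annotated in pieces.

The train/validation/test split is a single seeded shuffle cut at
`floor(n·0.8)` and `floor(n·0.9)`. It is **not** stratified by class; with
n = 780 this yields exactly 624/78/78. Stratification was left out because
the split is described only as random; the seed makes any draw
reproducible.

Resizing uses bilinear interpolation for images and nearest-neighbour for
masks (no fractional labels), with masks re-binarized afterwards.
Enhancement runs at native resolution, before resizing.

## CLAHE

Per-tile histograms (default 8×8 tiles, 256 grey levels) are clipped at

    β = (M/N)·(1 + (α/100)·(S_max − 1)),

with the excess redistributed uniformly over all bins in a single pass.
Each tile's clipped CDF becomes a min-normalized equalization mapping
(first occupied bin → 0, last → N−1), which keeps the mapping monotone;
every pixel bilinearly blends the mappings of its four surrounding tile
centres, clamping to the edge tiles at the borders. Defaults α = 40%,
S_max = 4 give a mild enhancement; both are exposed because the formula
parameterizes them, and no canonical values exist for this application.

## Augmentation

One affine warp per training sample: rotation ∘ shear ∘ zoom ∘ shift about
the image centre, then an optional horizontal flip. Parameters are drawn
uniformly from rotation [−45°, 45°], zoom [−0.08, 0.08] (applied as scale
1 + z), x-shear [−0.03, 0.03] rad, shifts up to 0.15 of each extent, and
brightness [0.99, 1.07] (image only, clipped to [0, 255]). Out-of-bounds
pixels replicate the nearest edge for images and are zero for masks, so a
warp can never invent lesion pixels; masks re-binarize at 0.5 after
interpolation. Augmentation is applied on the fly to training batches
only — validation and test data are never augmented.

## Networks

All four variants share a backbone: `depth` encoder levels (default 4) of
two 3×3 "same" convolutions + activation (default swish) with dropout 0.1,
then 2×2 max pooling, channel width doubling from `base_filters`; a
bottleneck block; a mirrored decoder with learned 2×2 stride-2 transposed
convolutions, skip concatenation, dropout 0.5, and a 1×1 convolution +
sigmoid head. No batch normalization (available as an explicit non-goal;
the backbone converges without it at these widths). Padding is "same"
throughout so skip tensors align by construction.

Skip-path content per variant:

* **unet** — raw encoder features.
* **sharp** — encoder features convolved depthwise with the fixed kernel
  [[0,−1,0],[−1,5,−1],[0,−1,0]] (identity + negative Laplacian; entries sum
  to 1, so constant maps are fixed points under the edge-replicate border).
  The deepest skip omits the sharpening filter — removing the filter
  between the last encoder and first decoder level. Sharpening adds no
  trainable parameters; `unet` and `sharp` have identical counts.
* **attention** — encoder features gated by an additive attention gate:
  the coarser decoder-side map g is brought to the skip's resolution by a
  learned 2×2 transposed convolution, both inputs pass 1×1 channel-wise
  convolutions (bias-free; the bias terms are fixed at zero), their sum
  passes swish, a 1×1 channel-collapse convolution and a sigmoid, and the
  resulting per-pixel coefficient in (0,1) multiplies the skip features.
  The intermediate channel count is half the skip width.
* **sharp_attention** — both the gate output and the sharpened features are
  concatenated with the upsampled decoder features. Sharpening operates on
  the raw encoder features (a parallel branch, not on the gate output), and
  the deepest sharpening site is again omitted while gates remain at every
  skip. At depth 4 this gives 3 sharpening sites and 4 gates.

### NumPy implementation

The layers, reverse-mode autodiff and Adam live in `sharpseg.nn`. Feature
tensors are NHWC float32. Convolutions use an im2col formulation; their
input gradients accumulate per kernel offset; max-pool backward routes the
gradient to the (first) argmax of each 2×2 window; dropout is inverted
(scaling survivors by 1/(1−rate)). Every op's gradient is verified against
central finite differences in the test suite. Weights initialize with He
fan-in uniform bounds (suited to the ReLU/swish family); biases start at
zero except the output bias (below).

## Training

The loss is mean binary cross-entropy plus soft Dice loss
(1 − 2Σyp/(Σy + Σp + ε), ε = 1e−5), computed from logits in the stable
softplus form. Optimization is Adam with learning rate 0.001, β₁ = 0.9,
**β₂ = 0.9** and ε = 1e−7 — β₂ is deliberately 0.9 rather than the common
0.999, matching the configured study setting; users changing it should
expect different convergence behaviour. Batch default 32, up to 300 epochs
with early stopping (patience 50). After each epoch the un-augmented
validation set is scored by pooled soft Dice; the best-scoring weights are
checkpointed and restored at the end.

Before the first step the output-layer bias is set to the log-odds of the
foreground prevalence of the training masks. With a zero bias the network
starts at p = 0.5 everywhere and spends its first updates re-learning the
class prior; the calibration removes that transient and costs nothing.

**Thresholding.** Probability maps binarize at p ≥ t. The threshold is
derived from the pooled-pixel ROC of the *validation* predictions at the
Youden point (max TPR − FPR); 0.4 is the fallback default when derivation
is skipped. The test set never influences the threshold.

**Metrics.** The evaluation report pools pixel counts over the whole
evaluated set (micro aggregation), matching the pixel-wise framing of the
statistical comparison. The soft (probability) Dice enters the loss and
the reported `loss`/`dice_loss` columns, while `dice_coefficient` and
`jaccard` are computed on the thresholded masks — which is why F1 and Dice
can appear as distinct columns despite being identical on binary inputs.
Zero-denominator ratios return 1 when the corresponding error count is
also 0, else 0.

## Statistical comparison

For each model pair, every test pixel is classified correct/incorrect per
model against the truth; b (A right, B wrong) and c (B right, A wrong) are
pooled across all test images. The statistic (b−c)²/(b+c) is referred to
χ²(1) without continuity correction; an exact two-sided binomial fallback
is available for small b + c; b + c = 0 returns p = 1 by convention.
Pooling across images (rather than one test per image) is the reading
consistent with a single pixel-wise test over the entire test set; the
per-image alternative would need a combination rule the procedure does not
define. P-values are Bonferroni-multiplied by the number of pairs and
flagged at family α = 0.1 — with four models (six pairs) the per-test
cutoff is 0.1/6 ≈ 0.017, consistent with a printed threshold of 0.02.

## Synthetic phantoms

The generator emulates the *structure* of a breast-ultrasound dataset:
grayscale speckle images of varying sizes (96/128/160 px by default, to
exercise the resize path), per-image binary masks, three class labels with
all-zero masks for `normal`, written as PNG pairs in the BUSI layout.

* **Speckle**: multiplicative field built from smoothed circular
  complex-Gaussian looks (squared magnitude). A single look has exponential
  intensity statistics whose pervasive near-zero patches mimic hypoechoic
  lesions; display-level B-mode texture corresponds to several effective
  looks, so the default averages 4 looks (Gamma statistics, point SNR 2)
  and normalizes to unit mean.
* **Lesion**: a seeded ellipse (aspect 0.6–1.0, radius 12–28% of the side)
  whose boundary radius is perturbed by low-order Fourier harmonics
  (orders 3–8) scaled by `boundary_irregularity` — 0 for benign (smooth),
  0.25 for malignant (spiculated-like). Inside, intensity is multiplied by
  `lesion_contrast` = 0.45 (hypoechoic). A vertical posterior shadow of
  strength 0.25 attenuates the columns below the lesion.
* **Mask**: the analytic lesion support itself — never re-segmented from
  the rendered image.

What the phantoms do **not** model: attenuation with depth, refraction and
reverberation artifacts, anatomical context (ducts, fascia, ribs), operator
variability, or the intensity texture of real parenchyma. Passing the
end-to-end tests therefore shows that the pipeline's mechanics — learning,
selection, thresholding, evaluation, comparison — work on ultrasound-like
statistics; it does not certify clinical-grade accuracy on real data.

## Desk-scale study sizes

The test suite and the reproduction script run a deliberately small
configuration chosen for single-CPU execution: 200 phantoms (34/112/54,
mirroring the real class proportions), 64×64 inputs, base width 8, at most
30 epochs. Under these conditions the fused model reaches a pooled
validation soft Dice above 0.8 and clearly separates from a plain UNet
trained identically (McNemar p ≪ 0.001 at seed 1). Full-scale settings
(128×128 inputs, wider filters, 300 epochs) are exposed through the same
configuration objects.

## Known limitations

* Single-channel 2-D inputs only; no 3-D or multi-modal variants.
* The NumPy backend is single-threaded except for BLAS matmuls; it is
  sized for desk-scale experiments, not for training at clinical scale.
* Checkpoints store raw weight arrays plus a JSON spec; there is no
  cross-version migration of checkpoints.
* The ROC-derived threshold can sit far from 0.4 when predicted
  probabilities are strongly bimodal; the evaluation accepts any threshold
  so the derived and default settings can be compared directly.
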