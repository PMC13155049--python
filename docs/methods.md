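# Methods

This note documents the models and procedures implemented in `cramnet`, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Gated recurrent channel attention (CRAM)

The fusion module operates on the concatenated branch embedding
X ∈ R^{2D}. Each attention pass k computes a gate A_k = σ(f_k(·)) and
multiplies it elementwise into the running feature, followed by ReLU; after
the final pass the original X is added back:

    A₁ = σ(f₁(X)),  Y′ = ReLU(X ⊙ A₁)
    A₂ = σ(f₂(Y′)), Z′ = ReLU(Y′ ⊙ A₂)
    F  = X + Z′

Design choices:

* **Gating transform.** f_k is dense(2D → h) → ReLU → dense(h → 2D), with
  parameters unshared between the two passes. The hidden width h defaults
  to 256: a full-width gate at 2D = 2560 costs ~6.55 M parameters *per
  layer*, which is incompatible with keeping the whole fusion head around
  3 M; h = 256 gives 2,627,072 parameters for both passes combined while
  preserving the two-dense-layers-with-ReLU form. Full-width gating is
  available via `hidden_width=feature_length`.
* **Recurrence depth** is 2 by default (two passes are sufficient; the
  second gate sees the contextually modulated Y′). `n_steps=1` reduces to a
  squeeze-and-excitation-style single gate (the `single_step` ablation);
  `attention_mode="none"` bypasses the module entirely.
* **Initialization.** He-normal weights; all biases zero, so initial gates
  are exactly ½ (neutral) and the closed form
  F = X + ReLU(ReLU(½X)·½) = X + ¼·ReLU(X) holds at init.
* **Residual.** Dimensions always match, so the residual is an identity
  addition; the `residual=False` ablation is supported but less stable and
  carries no quantitative claim.
* The feature is treated as a plain vector; a 1×1×2D spatial map is
  mathematically identical.

Two consequences are used as test invariants: every gate entry lies in
(0,1) (up to float64 rounding, which reaches the boundary once the logit
magnitude exceeds ~37), and F_i ≥ X_i wherever X_i ≥ 0 with F_i = X_i
wherever X_i ≤ 0, for *any* parameters.

## Backbones and classifier

The contract for a backbone is: map an image to a fixed-width embedding and
expose the final convolutional activation map (for Grad-CAM). The built-in
`TinyBackbone` is three stride-2 3×3 conv+ReLU blocks (widths 8/16/32) with
global average pooling — small enough to train from scratch in seconds on a
CPU. The classifier is a single dense layer of size 2 with softmax;
2-class softmax cross-entropy is mathematically equivalent to binary
cross-entropy on the malignant probability. Positive class is malignant;
scores exactly at the 0.5 threshold classify malignant (favoring
sensitivity).

Everything runs on a small reverse-mode autodiff engine (`autodiff.py`):
Tensors over float64 numpy arrays, im2col convolution, and per-node
gradient retention so that gradients with respect to intermediate
activations (Grad-CAM) come for free. Gradients are verified against
central finite differences in the test suite.

## Training procedure

Adam (β = 0.9/0.999) on cross-entropy with L2 weight decay (1e-5) applied
to the fusion parameters (attention + head) only. The learning rate follows
a triangular cycle with a 4-epoch period between `lr_high` and `lr_low` —
the simplest schedule that oscillates between the two rates, starting at
`lr_high`. Early stopping monitors validation loss with patience 5
(default) and restores the best-epoch weights. Augmentation (±90°
rotations, horizontal/vertical flips, brightness/contrast/color jitter with
clipping to [0,1]) is applied online to training batches only, with the
ground-truth mask geometrically co-transformed. Channel standardization
uses training-partition statistics for all partitions (leakage-free).

Defaults follow the fine-tuning recipe for full-size pretrained backbones:
lr 1e-4 ↔ 1e-5, batch 16, ≤ 50 epochs, patience 5. For the from-scratch
tiny backbones those rates are an order of magnitude too small to converge
within a 10-epoch budget, so the desk-scale preset (`desk_scale_config`)
uses 3e-3 ↔ 3e-4 with the same schedule shape — a standard Adam range for
small randomly initialized conv nets. A progressive unfreezing schedule
(`freeze_schedule`) is available for pretrained-backbone use (freeze all
but the last block, then unfreeze), and is off by default for from-scratch
training.

All randomness flows through explicitly passed integer seeds / numpy
Generators; identical seeds give bit-identical datasets, training
histories, and estimates.

## Synthetic data generator

The generator emulates the single visual cue the classifier is meant to
learn — dense clusters of dark nuclei in malignant tissue — while keeping
the ground truth exact:

* **Benign** (label 0): pink textured background (base color ≈ (0.88,
  0.76, 0.84) with low-frequency tint and σ = 0.02 pixel noise) plus 5–15
  round low-contrast blobs (radius 2–4 px, darkening ≤ 0.08). Mask is
  all-zero.
* **Malignant** (label 1): the same background and faint blobs, plus 1–3
  clusters of 20–60 overlapping irregular blobs (radius 1.5–3.5 px, vertex
  irregularity 0.4) darkened by 1.6–2.0× the contrast parameter (0.35).
  The cluster footprint after morphological closing (disk radius 2) is the
  ground-truth mask; closing-filled gaps are darkened too, so the mean
  intensity inside the mask sits more than the contrast parameter below
  the outside mean for every seed.

Default patch size is 64×64 (minimum 32). Patients are synthetic groups of
`images_per_patient` images of one class; the split assigns whole patients
to partitions, stratified per class, with floor-plus-largest-remainder
counts (exact when divisible). With unit groups, 10,000 images at
0.8/0.1/0.1 give exactly 8000/1000/1000.

What the generator does **not** emulate: real H&E stain variation and
artifacts, magnification levels, tumor subtypes, ambiguous borderline
morphology, or non-trivial patient effects. Consequently, passing tests
show that the architecture, training loop and explanation stack are
implemented correctly and can recover planted structure — they say nothing
about accuracy on real histopathology, where near-ceiling results should
not be expected.

The two-feature summary (mean intensity, dark-pixel fraction) separates
the classes linearly at default contrast, which is asserted in the suite;
this guarantees the desk-scale training criterion is well posed.

## Grad-CAM

Per branch: channel weights are the spatial averages of ∂(class logit)/∂A_c
at the last conv activation; the map is ReLU(Σ_c w_c A_c), bilinearly
upsampled to the input size, then max-normalized (an identically zero map
is returned as-is, not an error). Gradients are taken on the pre-softmax
logit, the standard convention that avoids softmax saturation. The
combined map weights each branch by its additive share of the class logit:
the dense head decomposes exactly as logit = w·F = w_A·F_A + w_B·F_B + b
over the two halves of F, and the weight is |s_branch| / (|s_A| + |s_B|)
(0.5/0.5 when both vanish). Multiplying the head by a positive constant
leaves the thresholded map unchanged (scale invariance of support).

Caveat: with attention enabled, the gates mix information across branches,
so zeroing one branch's head weights does not make the logit fully
independent of that branch; the exact-independence behavior (all-zero map)
holds in the no-attention configuration, which is how it is tested.

## Superpixel Shapley attribution

Segmentation uses SLIC (compactness 10, connectivity enforced) targeting
~50 regions; achieved K typically lands within [K/2, 2K]. "Absent"
superpixels are replaced by the image's **global** per-channel mean color —
a per-superpixel mean would leak the region's own content. The coalition
value v(S) is the model output on the masked image; the attribution target
is the malignant-class pre-softmax logit (the additive head makes logit
attributions well conditioned); the baseline v(∅) is the fully masked
image.

`exact_shapley` enumerates all 2^K coalitions (refusing K > 12) and applies
the permutation-weighted marginal-contribution formula; efficiency holds to
1e-10 by construction. `kernel_shap` solves the Shapley-kernel weighted
least squares with the efficiency constraint eliminated by substitution, so
base + Σφ = v(full) holds exactly for any sample. When the budget covers
all 2^K − 2 proper coalitions they are enumerated with their analytic
kernel weights, which makes the estimate identical to the exact oracle (the
suite checks ≤ 1e-6 at K = 8); otherwise coalitions are drawn from the
kernel distribution over sizes with antithetic complement pairs. A
rank-deficient design raises with advice to increase `n_samples`.

The desk-scale experiments use `n_samples = 512` at K ≈ 50: with the
efficiency constraint and antithetic pairing this is ample to sign the
planted-region attribution sum, and it keeps 50-image batches around a
minute on one CPU.

## Agreement metrics

Binarization keeps pixels ≥ frac·max (inclusive, so the peak always
survives; default frac = 0.30). IoU and Dice define the both-empty case as
1 (perfect agreement). The pointing game breaks ties at the maximum by
row-major first occurrence and refuses empty annotations — benign images
are excluded from pointing averages and reported separately. Normalized
overlap is the fraction of total saliency mass inside the annotation
(error on an all-zero map, 0 for an empty annotation). Aggregation reports
class-stratified mean ± population SD; the pointing game aggregates as a
proportion.

## Classification metrics

Positive class malignant. Metrics with zero denominators are omitted, not
reported as 0. Percentages are kept at full precision and rounded to two
decimals only at presentation. ROC/AUC uses a threshold sweep over unique
scores with trapezoid integration (equal scores grouped into one step);
the suite verifies AUC against the Mann–Whitney pairwise statistic
exhaustively for n ≤ 8, ties counted ½. McNemar's test reports the
asymptotic χ² = (b−c)²/(b+c) (optionally continuity-corrected) and the
two-sided exact binomial p-value, defaulting to the exact version when
b + c < 25, where the asymptotic approximation is unreliable.

## Desk-scale study conditions

The standard experiment trains the tiny-backbone hybrid on 200/50/50
synthetic 64×64 patches (seeded), ≤ 10 epochs, batch 16. Expected
behavior, all computed by the test suite and `scripts/acceptance.py`:
test accuracy ≥ 95% (typically 100%), AUC ≈ 1.0, Grad-CAM pointing-game
≥ 0.8 over 50 malignant held-out images (typically ≈ 1.0), and a positive
planted-region SHAP sum for ≥ 90% of correctly classified malignant
images (typically 100%). Randomly initialized models are the negative
control for localization: their pointing scores scatter widely around a
level nearer the mask-area chance rate (≈ 0.2) than the trained score,
because a random conv stack still responds preferentially to
high-contrast regions — the comparison is asserted as "closer to chance
than to the trained model" rather than as a point value.

## Known limitations

* The synthetic task saturates: accuracy differences between attention
  variants are usually zero at this scale, so ablation comparisons
  (McNemar) mostly demonstrate the machinery, not an effect.
* Exact Shapley is limited to K ≤ 12 by cost; Kernel SHAP at larger K is
  an estimate whose variance depends on `n_samples`.
* Real pretrained backbones (MobileNetV2 / EfficientNet-B0 class) are out
  of scope; the backbone contract is the extension point.
* The float64 sigmoid reaches 0/1 for |logit| ≳ 37; the open-interval gate
  range is exact-arithmetic only.
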