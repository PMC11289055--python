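# Methods

## Problem and model

The package estimates the radiographic severity of lung pneumonia from a
single frontal chest image. Severity is annotated per lung on a 0–4
scale — geographic extent (GE, the involved-area quartile) or lung
opacity (LO, the opacification character) — and reported globally as the
two-lung sum in [0, 8].

The regressor is a plain (non-hierarchical) vision transformer. An
H×W×C image is cut into P×P patches; each flattened patch x_p is
projected by a learned matrix E to a D-dimensional token, a learned
class token is prepended, and learned position embeddings E_pos are
added:

    z_0 = [CLS; x_p^1 E; …; x_p^N E] + E_pos,   N = HW / P².

L pre-norm encoder layers follow,

    z'_l = MSA(LN(z_{l−1})) + z_{l−1}
    z_l  = MLP(LN(z'_l))    + z'_l,

and a two-layer head (D → 128 → 2) reads the final-layer class token and
emits one score per lung; the global prediction is p = p_l + p_r. The
head is written exactly as the composition FC₂(FC₁(CLS)) with no
interior nonlinearity; `head_activation` optionally inserts ReLU/GELU.
With `clamp_output` each lung output is clipped to [0, 4] at inference,
bounding p to [0, 8]; training always uses the raw outputs so gradients
flow.

Three named geometries:

| name | input | P | L | D | heads | params |
|------|-------|---|---|---|-------|--------|
| tiny | 224×224×3 | 16 | 12 | 192 | 3 | 5,549,378 (≈5.5 M) |
| small | 224×224×3 | 16 | 12 | 384 | 6 | — |
| nano | 64×64×3 | 8 | 4 | 64 | 2 | 225,218 |

Head count (3) and MLP ratio (4) for the tiny geometry follow the
standard tiny-ViT convention. The implementation is pure NumPy —
forward pass and hand-derived backpropagation through LayerNorm,
multi-head softmax attention and GELU — with gradients verified against
central finite differences in the test suite. Initialisation is
N(0, 0.02) for weights and embeddings, zero biases, unit norm gains,
from a seeded generator; a checkpoint hook allows loading externally
pretrained weights, and no download is ever required.

## Score-aware augmentation

Severity regression needs augmentations whose *labels* are exact.

**Combined lung and score replacement** (offline). The output image is
the image-left half of A concatenated with the image-right half of B
(midline at column ⌊W/2⌋, half-open intervals, extra column to the
right half when W is odd); its per-lung scores are copied from the
corresponding parents, so the global score is A.left + B.right with no
approximation. Reciprocal replacements conserve total score. Per-lung
ground truth is required. The pairing protocol draws one uniform
partner j ≠ i per image per score type, so N originals with S score
types yield N(1+S) training images — e.g. 1,878 images with two rubrics
become 5,634, and 4,695 with one rubric become 9,390. A
`pairing="reciprocal"` variant swaps disjoint pairs instead and gives
the same counts.

**Score-correlated CutMix** (online). A rectangle of A is replaced by
the same rectangle of B and the global label becomes
λ·y_A + (1−λ)·y_B, where λ is the exact integer-pixel fraction of the
output kept from A (computed as (HW − box)/HW so the stored λ equals
the counted provenance bitwise). This is the standard CutMix label
rule; the alternative reading, weighting y_A by the donor fraction, is
exposed as `lambda_from_donor=True`. Boxes are sampled with area
fraction uniform in a configurable range, default (0.05, 0.4), placed
uniformly. During training every batch element is mixed once per epoch
with a uniformly drawn in-batch partner. Per-lung labels of a CutMix
output are undefined (the box ignores the midline) and are dropped.

## Synthetic phantoms

The generator emulates the label-relevant structure of a scored chest
film: a mid-grey body with a bright mediastinal band and two dark
elliptical lung fields (jittered geometry; each field ≥ 5% of the
frame, left field strictly in the left half-columns). Disease is
painted as unions of random discs inside each lung field — ground-glass
blobs (+0.22 intensity) and denser consolidation (+0.45) — until a
target coverage is reached. Labels are then *measured from the painted
masks*: the GE score bins the covered-area fraction at 0.25/0.5/0.75
(edges to the lower bin, a fixed package convention since the rubric's
bins share their edge values), and the LO score grades the
consolidation fraction (0 none / 1 ground glass only / 2 mixture below
half / 3 mixture above half / 4 complete). Labels are therefore exact
by construction, with zero label noise.

Per-lung target severities are sampled uniformly on the integer grid
{0,…,4}. Half-point global scores, which real annotation practice
produces, arise here only through augmentation mixing: sampling
half-point per-lung targets directly would be incompatible with the
integer-valued rubric bins that the label-recovery invariant re-applies.
Image-left corresponds to the first output score and image-right to the
second; anatomical left/right is irrelevant to the arithmetic.

What the phantoms do **not** emulate: ribs, cardiac silhouette,
projection geometry, exposure variation, inter-reader label noise.
Passing tests show the pipeline recovers known generative labels; they
do not certify clinical performance on real radiographs.

## Training

Images are resized to the configured input (bilinear, anti-aliased),
grayscale replicated to three channels, and standardised per image to
zero mean and unit variance (variance floor 1e-6; constant images map
to zeros). Per-image rather than dataset statistics keep the transform
stateless and idempotent; the choice is configurable.

The loss is the batch absolute error L = Σ|p_i − p̂_i|. Optimisation
uses the batch *mean* by default so the learning rate is independent of
batch size; the sum form is available and both are logged. Defaults:
batch 32, learning rate 1e-3, 60 epochs, SGD with momentum 0.9, no
weight decay, constant learning rate ("60 iterations" in the benchmark
protocol is read as 60 epochs, consistent with its learning curves).
MSE / smooth-L1 / Huber losses and Adadelta / Adam / AdamW / RMSprop
optimizers are drop-in options mirroring the ablation axes. Supervision
uses the global score (per-lung pairs can be supervised directly when
available, but not together with CutMix, whose mixed target is global
only). A non-finite loss aborts with the epoch index. All randomness —
initialisation, shuffling, CutMix partners and boxes — derives from one
seed; identical configurations reproduce traces and weights exactly.

## Evaluation

MAE and the Pearson coefficient summarise accuracy; Pearson on a
zero-variance input returns a flagged undefined value (`nan` +
`pearson_defined=False`) instead of propagating silently. The
cumulative matching curve reports the fraction of images with absolute
error ≤ t for half-point thresholds up to the global maximum; the error
histogram uses unit bins over [0, 8]. Attention maps project class-token
attention onto the image, by rollout (head-averaged attention mixed with
identity, row-normalised, chained across layers — the default) or from
the last layer alone; maps are bilinearly upsampled and min–max
normalised. Both methods are retained because published saliency
figures do not disambiguate them; on trained phantom models both place
more mass on painted opacities than elsewhere.

## Problem sizes and measured behaviour at desk scale

The bundled experiments run the nano geometry on 64×64 phantoms: 600
training and 150 test images with GE labels, 30 epochs (one seeded run
each for the plain and the augmented condition; the augmented condition
is 1,200 images after offline replacement, plus online CutMix). These
sizes are the package's reference desk-scale conditions; the tiny
geometry is instantiated for architecture checks and available for full
training.

Measured at these conditions (seeds as in the test suite): plain
training reaches test MAE ≈ 0.57 against a predict-the-mean baseline of
≈ 1.76, Pearson ≈ 0.95. Offline replacement alone improves MAE
(≈ 0.54). Online CutMix *degrades* it here (alone ≈ 0.81; both ≈ 0.83):
with lung fields covering only ~26% of the phantom frame, whole-frame
area-ratio label mixing injects label perturbations of the same order
as the achievable error, and at 30 desk-scale epochs from random
initialisation that noise does not average out. On real films the thorax
fills most of the frame and training is an order of magnitude longer
from a pretrained start, which is where the benchmark observed CutMix to
help; the discrepancy is a property of the phantom geometry, not of the
mixing arithmetic, whose accounting is tested exactly.

## Known limitations

- No pretrained weights are shipped; from-scratch CPU training limits
  practical input sizes.
- The phantom generator's simplicity means results here bound plumbing
  correctness, not clinical accuracy.
- Learning-rate schedules, early stopping, mixed precision and
  multi-device training are out of scope.
- Brixia-style six-zone scoring is representable only through the
  generic rubric's global score; zone-level generation is not modelled.
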