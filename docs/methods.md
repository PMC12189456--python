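# Methods

## Problem and model

`gcsaseg` segments tumor tissue in hematoxylin–eosin histopathology images.
Whole-slide images (WSIs) are orders of magnitude too large for direct
network input, so the pipeline works on a fixed 512×512 patch lattice:
slides are tiled, each patch is segmented into a binary {0, 255} mask
(255 = tumor foreground), and predicted patches are stitched back and
cropped to the slide's original size.

The network is a SegFormer-style encoder–decoder with a **global
channel-spatial attention (GCSA)** bottleneck at the encoder–decoder
junction:

- **Encoder** — a four-stage hierarchical Mix Transformer (MiT-B0 recipe:
  widths 32/64/160/256, depths 2/2/2/2, heads 1/2/5/8). Each stage embeds
  with an overlapped strided convolution (kernels 7/3/3/3, strides 4/2/2/2)
  and runs pre-norm Transformer blocks whose self-attention shrinks the
  key/value sequence with a strided convolution (spatial-reduction ratios
  8/4/2/1) and whose feed-forward inserts a 3×3 depthwise convolution
  (Mix-FFN, expansion 4). Stage outputs sit at strides 4/8/16/32.
- **GCSA** — one independent instance per encoder stage, three stages in
  sequence:
  1. *Channel attention*: at every pixel the channel vector v ∈ R^C passes
     through a position-shared MLP C → C/4 → C (ReLU between); a sigmoid of
     the result gates the input elementwise,
     F_C = σ(MLP(v)) ⊙ F_IN.
  2. *Channel shuffle*: channels are reshaped to (4, C/4), the two axes are
     transposed and flattened — a pure permutation (output channel
     k·4 + i ← input channel i·C/4 + k) that mixes information across the
     four groups without altering values.
  3. *Spatial attention*: two 7×7 convolutions C → C/4 → C (batch-norm
     after each, ReLU after the first, symmetric padding 3 so H×W is
     preserved); a sigmoid of the result gates the shuffled map,
     F_S = σ(BN(Conv(ReLU(BN(Conv(F_CS)))))) ⊙ F_CS.

  Both gates lie strictly in (0, 1), so neither stage can amplify an
  activation; the shuffle is a bijection. Reduction ratio and group count
  default to 4 and are configurable together with the stage widths (which
  must stay divisible by both).
- **Decoder** — the all-MLP head: each stage map is linearly projected to a
  common width (256), bilinearly upsampled to stride 4, concatenated
  (4 × 256 channels), fused by a 1×1 convolution with batch-norm and ReLU,
  and classified per pixel; logits are bilinearly upsampled to the input
  resolution and argmaxed into the binary mask.

Where the GCSA placement was ambiguous (per encoder stage vs. once on the
fused feature), we apply one instance per stage: the all-MLP decoder
consumes all four stage maps directly, so "between the encoder and the
decoder" has four junctions. The sigmoid in the spatial gate takes only the
conv/BN chain as its argument, with the shuffled map as an outer elementwise
factor, parallel to the channel gate's structure.

## Numerical substrate

The package runs on its own compact reverse-mode autodiff engine over NumPy
(`gcsaseg.nn`): a `Tensor` graph with closure backpropagation, im2col-based
grouped convolution, bilinear resampling with an exact adjoint, fused
softmax cross-entropy, AdamW, and step learning-rate decay. Gradients of
every primitive are verified against central finite differences in float64.
Forward/backward are deterministic on CPU, which is what makes the bitwise
reproducibility contracts below testable at all.

## Training recipe

AdamW with first-moment coefficient β₁ = 0.9 (the recipe's "momentum";
AdamW has no classical momentum), β₂ = 0.999, decoupled weight decay 0.02,
learning rate 1e-4, pixelwise unweighted cross-entropy on two classes,
batch 8, 50 epochs, step decay (default: ×0.1 every 20 epochs — the step
size and factor are conventions, exposed in `TrainConfig`). One integer
seed drives initialization and the per-epoch shuffle; two runs with the
same seed produce bitwise-identical loss traces and checkpoints. The
returned model is the best-validation-MIoU state. No data augmentation.

Initialization: linear layers are truncated-normal (std 0.02, realized as a
±2σ clipped normal), encoder/decoder convolutions Kaiming fan-out, GCSA
convolutions truncated-normal, biases zero, batch-norm scale 1 / shift 0.
Batch-norm uses per-channel batch statistics in training and running
averages (momentum 0.1) in evaluation. All upsampling is bilinear with
corner alignment disabled.

## Metrics

From pooled pixel confusion counts (TP = predicted and true foreground,
etc.):

- MIoU = (TP/(TP+FP+FN) + TN/(TN+FN+FP)) / 2
- MPA  = (TP/(TP+FP) + TN/(TN+FN)) / 2
- Accuracy = (TP+TN) / total

MPA is deliberately the mean of the two class *precisions* — that is the
form the formula states, even though the usual quantity of that name
averages recalls; `mpa(..., variant="recall")` gives the conventional form.
A class term with a zero denominator scores 1.0 (an absent, never-claimed
class is handled perfectly). Dataset-level aggregation is micro (pooled
counts) by default, matching whole-slide stitching semantics; macro
(per-patch mean) is available via a flag.

## Tiling, labels, splits

Tiling zero-pads the right/bottom edges to the next 512 multiple and crops
after stitching, making tile→stitch an exact identity for any size ≥ 1;
zero (background) padding biases border predictions least. Annotations are
harmonized to binary masks: liver scheme HCC ∪ MVI → 255, ROI ∪ Non-ROI →
0; breast (BACH) scheme in-situ ∪ invasive → 255, normal ∪ benign → 0.
Incompletely annotated regions carry no ignore label and count as
background. Splitting is patch-level 7:2:1 by seeded shuffle with the floor
rule (n=10 → 7/2/1; remainder to test).

## Synthetic data

The generator stands in for HE-stained patches: an eosin-like pink Gaussian
noise background (mean RGB ≈ (231, 180, 197), σ = 12) with a union of
hematoxylin-like purple ellipses (mean ≈ (120, 70, 155)) as foreground, and
the exact ellipse-union mask. It reproduces the *format* and the
figure–ground color statistics of stained tissue, not its morphology: no
nuclei, stroma, staining gradients or scanner artifacts. Consequently the
desk-scale learning result below shows that the full pipeline can fit a
color+shape segmentation task end to end — it says nothing about
performance on real pathology data. A spec whose two texture means are
closer than 30 (Euclidean, 8-bit RGB) is rejected as unlearnable by
construction.

## Desk-scale experiment sizes

CPU-scale runs use a reduced configuration chosen once: widths 8/16/24/32
at depth 1 (heads 1/2/2/4, since 5 does not divide 24; decoder width 64),
200 synthetic 64×64 patches (2 blobs, radii 6–16 px) split 7:2:1, 10 epochs
at the standard optimization recipe. Under these conditions held-out MIoU
lands near 0.92 (threshold 0.85 in the tests), and the whole run takes
under a minute on one CPU. `scripts/acceptance.py` re-runs exactly this
experiment from a fresh seed.

## Known limitations

- No ImageNet pretraining (offline constraint is a non-issue for the
  synthetic task, but real-data performance would depend on it).
- Binary segmentation only; no multi-class head, no boundary metrics.
- No pyramidal WSI decoding (SVS/NDPI), stain normalization, or
  overlap-tiling with blending; tiles are independent, so seams are
  possible at tile borders.
- The NumPy engine is single-device and unoptimized for large batches;
  the full 512×512 MiT-B0 forward runs in seconds, training at that scale
  is out of scope.
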