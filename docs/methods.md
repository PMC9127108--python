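# Methods

## Problem and model

`lungseg` segments the lung fields (the image region occupied by the lungs)
in 2-D chest-radiograph-like images. The model is an encoder–decoder U-Net:
five encoder stages produce feature maps at strides 2–32, and five decoder
stages mirror them, each receiving the same-resolution encoder feature
through a skip connection so fine spatial detail survives the bottleneck.

The distinctive part of the architecture is the decoder sub-block. Each of
the five decoder stages applies, in order:

1. 2× nearest-neighbour upsampling and concatenation with the skip feature
   (the deepest stage upsamples the stride-32 bottleneck; the final stage,
   stride 2 → 1, has no skip),
2. dropout (regularization; default rate 0.2),
3. a padded 3×3 convolution with batch normalization,
4. a configurable number of **residual blocks** (default two), and
5. a LeakyReLU activation.

A residual block computes `y = x + C(B(x))`: a branch of two 3×3
convolutions with batch normalization (and the configured activation between
them) added onto an unmodified identity shortcut. Differentiating gives
∂L/∂x = ∂L/∂y · (I + ∂branch/∂x): the upstream gradient reaches the input
with an explicit identity term, so it cannot be annihilated by a chain of
small branch Jacobians (the "vanishing gradient" failure). With every branch
parameter zero the block is exactly the identity; both properties are tested
(the gradient one against a central finite-difference oracle at step 1e-4,
required to agree to relative error < 1e-3).

LeakyReLU (slope 0.01 — the conventional "slight gradient"; the value is
configurable) is used instead of ReLU so that units with negative
pre-activations keep a nonzero gradient ("neuron death" avoidance). A 1×1
convolution with a sigmoid produces the single-channel probability map at
the input resolution; masks are binarized at threshold 0.5 by default. The
sigmoid input is clipped to ±35, which keeps the output *strictly* inside
(0, 1) in float64 — that makes threshold 0 exactly all-foreground and
threshold 1 exactly all-background, a convenient contract for callers.

### Encoders

* `tiny_test`: five stride-2 conv/BN/LeakyReLU stages with widths
  (8, 16, 32, 64, 128). With its matching decoder widths (32, 24, 16, 12, 8)
  the whole network has ≈ 250k parameters and trains on one CPU in seconds
  per epoch at 64×64 — this is the configuration every end-to-end test uses.
* `efficientnet_b4_random`: the EfficientNet-B4 topology — stem plus seven
  MBConv stages (expansion 1 or 6, 3×3/5×5 depthwise convolutions,
  squeeze-excitation at ratio 0.25, B4 depth scaling 2/4/4/6/6/8/2, feature
  taps at channels 24/32/56/160/448) — with random He initialization.
* `efficientnet_b4_pretrained` raises an explicit error: ImageNet weights
  cannot be fetched in an offline installation, and silently substituting
  random weights would misrepresent the model; the error names the two
  working alternatives.

### Numerical backend

The network runs on a small reverse-mode automatic-differentiation engine
written on NumPy (`lungseg.nn`): broadcast arithmetic, dense and depthwise
2-D convolution (im2col / einsum with hand-derived backward passes), batch
normalization, LeakyReLU/sigmoid/swish, nearest upsampling, concatenation,
reductions and inverted dropout. Arrays are float64 throughout — the models
are small enough that precision is free, and it keeps finite-difference
gradient checks sharp (every operation's gradient is verified against
central differences in the test suite). Checkpoints are NumPy `.npz`
archives with a YAML sidecar describing the architecture.

## Loss and metrics

Training minimizes the soft dice loss
`1 − (2 Σ p·t + ε) / (Σ p + Σ t + ε)` with ε = 1e-6; the smoothing term is
needed so an empty-truth/empty-prediction pair has loss 0 rather than 0/0.
The loss is computed per sample and averaged over the batch, so a sample
with large lungs cannot dominate one with small lungs.

Evaluation reports accuracy, specificity, sensitivity, dice and jaccard
from pixel confusion counts. Conventions for degenerate denominators:
dice = jaccard = 1 when TP = FP = FN = 0 (logged); sensitivity is NaN when
the truth is empty and specificity NaN when the truth fills the frame; NaNs
are excluded per metric during aggregation. Aggregation is per-image
(macro) mean ± sample (n−1) standard deviation — the reporting convention
of ablation tables in this literature; the n−1 choice is a documented
convention since either is defensible, and a single image reports std 0.

## Morphological repair

Two deterministic operators fix the classifier's characteristic errors:
`keep_largest_components` retains the two largest 8-connected foreground
components (left and right lung) and removes fragment false positives;
`fill_holes` converts enclosed false-negative holes — background not
4-connected to the image border — to foreground. Foreground 8-connectivity
with background 4-connectivity is the standard complementary pair that
avoids topological paradoxes; area ties are broken by first raster index for
determinism; `repair` runs components-then-holes so a speckle inside a
removed fragment's hole cannot survive. Both operators are verified against
exhaustive breadth-first-search oracles on all 65,536 4×4 masks, and
`repair` is idempotent. The implementation delegates the connected-component
labeling and flood fill to `scipy.ndimage`.

## Training schedule

Defaults: Adam (the conventional optimizer for this architecture family; the
recipe this package follows names only the learning rate, batch size and
epochs) at initial learning rate 2e-4, batch size 64 (automatically reduced
and logged when the training set is smaller), at most 70 epochs. A
reduce-on-plateau rule halves the learning rate after 10 consecutive epochs
without improvement of the monitored validation loss (min-delta 0; a
`val_dice` monitor is available behind a flag); the produced learning-rate
sequence is always `initial · 0.5^m`. Splits: 1/3 of the data held out for
testing, and 20% of the remaining 2/3 for validation (round-to-nearest at
each stage, so n = 300 gives 160/40/100). Training is fully deterministic
given the config seed (weight init, shuffling and dropout all derive from
it). Non-finite losses abort with a diagnostic rather than continuing.

The six ablation variants of the decoder sub-block are exposed as
Method 1–6: (relu, 0 residual blocks), (leaky_relu, 0), (relu, 1),
(leaky_relu, 1), (leaky_relu, 2) — the full model — and (leaky_relu, 3).
The variants differ only in activation and residual-block count; no
performance ordering among them is asserted by the tests, since that is an
empirical claim about real radiographs, not a structural property.

## Phantom data

Real radiograph datasets (JSRT/MC/NIH) are optional external inputs; all
tests run on generated phantoms with exact ground truth. A phantom is a
bright body ellipse on a dark air background containing two mirrored,
tilted superellipses (exponent 2.5) of lower intensity for the lungs —
air-filled lungs are radiolucent — with per-sample eccentricity drawn from
(1.7, 2.3) and mild smooth texture. Corruptions emulate the hard-case axes
of clinical films:

* **opacity** — additive heavily-blurred haze over one lung (severity 0.35,
  probability 0.5 by default), the appearance of consolidating disease;
* **occlusion** — 1–2 bright axis-aligned bars through a lung (probability
  0.25), a pacemaker-lead/catheter analogue;
* **deformation** — a smooth random elastic warp (amplitude 3 px by
  default, Gaussian-filtered displacement field at σ = size/8) applied to
  image *and* mask, since deformed anatomy moves the true border;
* **noise** — additive Gaussian intensity noise (σ = 0.02).

Defaults were chosen once as a plausible moderately-hard case mix; the
corruption frequencies are free parameters of the generator, not calibrated
against any clinical severity distribution. Opacity and occlusion touch the
image only, so the mask of a corrupted phantom is bit-identical to the clean
phantom's at the same seed — a tested invariant that makes corruption
ablations exact. Every random choice draws from its own named stream spawned
from the sample seed, and per-sample seeds derive from the master seed by a
counter-keyed scheme, so growing a dataset appends samples without
reshuffling earlier ones.

What the phantoms do **not** emulate: rib cages and mediastinal anatomy,
scanner-specific noise spectra, patient positioning variation, genuine
pathology texture, and the full diversity of clinical lung shapes. Passing
tests therefore demonstrate that the architecture, loss, schedule, repair
and plumbing are implemented correctly and can learn a bilateral
segmentation task end to end — not that the model reaches clinical-grade
accuracy; that claim requires the real datasets, pretrained encoder weights
and GPU-scale training, which are out of scope here.

The four training augmentations are implemented in-package: horizontal flip
(geometric — applied to image and mask, an involution), random gamma
(exponent U(0.7, 1.4)), Gaussian blur (σ ∈ U(0.5, 1.5)) and min-max
normalization. The photometric three never touch the mask. Normalization is
min-max to [0, 1] rather than channel standardization so that augmented
images stay within the sample type's [0, 1] contract.

## Problem sizes in tests and the acceptance script

End-to-end runs use the `tiny_test` encoder at 64×64: an 8-phantom overfit
run (150 epochs, lr 1e-3, dropout 0, plateau patience widened to 30 so the
schedule does not freeze an intentional overfit — a capacity/pipeline
sanity check that must reach training dice ≥ 0.95) and a 60-phantom demo
pipeline (Method 5,
40 epochs, batch 8, published lr 2e-4) that exercises
generate → split → train → evaluate → report with both raw and
post-repair metrics. These sizes were chosen as the smallest runs that
still demonstrate learning and produce stable reports on a single CPU.

## Known limitations

* No GPU path and no float32 mode; pure-NumPy training is desk-scale only.
* `efficientnet_b4_random` is structurally faithful but untrained; it is
  exercised for construction and shape contracts, not trained in tests.
* Drop-connect (stochastic depth) of the original EfficientNet training
  recipe is not implemented; it matters only for large-scale training.
* The plateau rule interprets "no improvement over ten epochs" as
  patience-10 monitoring with min-delta 0; other readings (fixed 10-epoch
  windows) would shift halving times by at most a few epochs.
* Whether published metrics in this task family are computed before or
  after morphological repair is ambiguous; the pipeline always reports both.
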