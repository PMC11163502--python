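# Methods

This note records the models, conventions and design choices behind the
package, in the order data flows through it.

## Problem setting

The package segments pulmonary nodules in chest CT. The unit of
computation is a nodule-centred region of interest (ROI) of 11 axial
slices of 64x64 voxels at 1 mm isotropic spacing: large enough to contain
the nodule-size range seen in screening data (3.2-27.4 mm diameters),
small enough that foreground/background imbalance stays mild. The network
is 2.5D: in-plane (2D) and through-plane (1D) operations are mixed so the
slice structure of CT is exploited at a fraction of full-3D cost.

## Preprocessing

The chain is fixed: HU clip -> lung mask -> isotropic resample ->
normalise -> crop. All steps are deterministic.

* **HU clipping** to [-1000, 600] removes bone and bright artefacts while
  keeping the full air-to-soft-tissue range that nodules occupy.
* **Lung masking**: voxels below -320 HU are labelled air; components
  touching the volume border (outside air) are discarded; the two largest
  interior components are kept, closed with a radius-2 ball, and
  hole-filled. Hole filling matters: solid nodules are dense and would
  otherwise be cut out of the image by the mask. The mask restricts the
  volume (background set to -1000 HU); it fails open to all-true, with a
  warning, when no interior air component exists, so flat synthetic slabs
  pass through. The exact recipe is a conventional parenchyma extraction;
  nodule-centred crops are insensitive to its fine detail.
* **Resampling** to 1 mm isotropic voxels uses trilinear interpolation for
  images and nearest-neighbour for masks (SimpleITK), with origin
  bookkeeping so world coordinates stay valid.
* **Normalisation** maps the retained window linearly to [0, 1] and then
  subtracts the volume mean ("de-averaging"). The map is affine and
  invertible; re-normalising a normalised volume is refused.
* **Cropping** places the annotated centre at patch index (5, 32, 32) of
  the 11x64x64 window and zero-pads beyond the volume border rather than
  shifting the window, because the central-pooling operator downstream
  assumes a target-centred input.
* **Ground truth**: real annotations carry only a centre and diameter, so
  a diameter-sphere proxy mask is rendered when no contour mask is given;
  synthetic cases use the generator's exact mask. The sphere proxy is a
  stand-in, not a claim about how reference masks were drawn.

Coordinates: arrays are (z, y, x), 0-based; world coordinates are
(x, y, z) millimetres as in the annotations CSV; every conversion passes
through `world_to_voxel` (round((world - origin) / spacing) plus axis
reversal).

## Central pooling

Uniform stride-2 max pooling treats the centre of a nodule-centred patch
the same as its periphery. Central pooling instead tiles each in-plane
axis of length Q with max-windows of sizes 1, 2 and 3 -- size-1 windows in
the middle, size-3 at the edges -- chosen so the axis still halves:

    n1 + 2 n2 + 3 n3 = Q        (tiling)
    n1 + n2 + n3     = Q / 2    (halving)
    n1 + n3          = n2       (half of the windows have size 2)

The unique non-negative solution is (n1, n2, n3) = (Q/8, Q/4, Q/8), so
Q = 64 gives (8, 16, 8) and Q = 8 gives (1, 2, 1); divisibility by 8 is a
precondition and the solver is verified against exhaustive enumeration.
The printed source for this system is typographically garbled; the system
above is the unique reading consistent with both of its worked solutions
and with the halving behaviour of the pooling it replaces.

Layout: windows are placed centrally symmetrically, 3s outermost, then
2s, size-1 windows in the middle; when a count is odd the extra window
goes to the leading (low-index) side. 2D pooling applies the same
partition separably along rows and columns; 3D pooling applies 2D pooling
per slice and pools the slice axis only when its length is divisible
by 8 -- an 11-slice stack is left unpooled through z, preserving the 2.5D
structure. All four down-transitions of a 64x64 input (64, 32, 16, 8)
satisfy the divisibility rule, so central pooling is active at every
level. The operation is parameter-free.

## Architectures

### Baseline: classic residual V-Net (preset 1)

Five levels, 16 base channels doubling to 256, 5x5x5 convolutions,
residual stacks of (1, 2, 3, 2) convolutions down and (2, 2, 1, 1) up,
strided-convolution down-transitions and transposed-convolution
up-transitions, PReLU activations, batch normalisation after every
convolution. Because the input has 11 slices, down/up transitions act
in-plane only ((1, 2, 2) kernels and strides); z stays 11 end to end.
This configuration has 45.21 M trainable parameters and 93.68 GMAC (table
convention, see below) at a 1x11x64x64 input, matching the baseline's
published fingerprint (45.60 M / 93.91) to within 1%.

### Proposed family (presets 2-6)

The proposed model family shares a five-level encoder-decoder skeleton
with the baseline but is its own architecture:

* 3x3x3 convolutions at levels 1-3; **separable S3D stages** at levels
  4-5: a 1x3x3 intra-slice convolution followed by a 3x1x1 inter-slice
  convolution, each with batch normalisation and PReLU. At the deepest
  levels inter-slice weight structure is most informative, and the
  factorisation there cuts cost with the least damage.
* **Down-transitions** are pooling (uniform 2x2 max, or central pooling
  when enabled) followed by a 1x1x1 channel-doubling convolution;
  **up-transitions** are (1, 2, 2) transposed convolutions.
* **DFFM** fuses each skip: both the encoder map and the upsampled decoder
  map pass a 3x3x3 convolution (+BN+PReLU); the encoder branch is
  additionally max-pooled at stride 1 with a 3x3x3 window (a local
  "most-interesting-region" filter); the branches add and pass a PReLU.
  When DFFM is off, skips are concatenated and the first decoder
  convolution halves the channels, with a 1x1x1 projection on the
  residual shortcut.
* **RACM**: two reverse-attention units in series on the decoder path
  (levels 4 then 3). Each unit computes A = 1 - sigmoid(coarse logits),
  returns f + A * conv3x3x3(f), and emits its own 1x1x1 prediction, which
  (nearest-upsampled) drives the next unit. The first coarse prediction
  comes from the bottleneck. Reverse attention steers capacity toward
  regions the running prediction has not yet claimed -- nodule edges.
* **SE blocks** after each decoder level: global-average squeeze, a
  bottleneck MLP with reduction 16, sigmoid channel gates.
* Final 1x1x1 convolution + sigmoid produces a 1-channel probability map
  at input resolution.

### Width calibration

The published record of this architecture family fixes it only through
four numbers: baseline parameters (45.60 M), S3D-variant parameters
(33.47 M), full-model parameters (38.28 M) and full-model GMACs at the
11x64x64 input (52.64). Channel widths, per-level convolution counts and
the S3D hidden width are not stated anywhere, so this implementation
treats those printed counts as the calibration surface and fixes:

* base width 28 (channels 28, 56, 112, 224, 448);
* encoder convolution counts (1, 2, 3, 3, 3), decoder (1, 2, 2, 1);
* S3D hidden widths: half the output channels at level 4 (112), four
  times the output channels at level 5 (1792). A wide separable hidden
  layer is the same device R(2+1)D networks use to trade parameters
  against the factorised kernel shape;
* RACM units at decoder levels 4 and 3; SE reduction 16.

Achieved fingerprints: preset 2 = 33.69 M (+0.7%), preset 6 = 38.19 M
(-0.2%) and 52.70 GMAC (+0.1%); intermediate presets 3/4/5 land at
36.49 / 38.19 / 38.19 M against published 35.67 / 37.61 / 37.64. The
published table also shows central pooling adding 0.03 M parameters; the
operator as described is parameter-free, so here preset 5 equals
preset 4 and the 0.03 M discrepancy is noted rather than imitated.

**Compute-cost convention.** "GMAC" figures follow the 2-operations-per-
multiply-accumulate (FLOP) convention: reconstructing the baseline V-Net
at the 11x64x64 input gives 46.95e9 raw multiply-adds, exactly half the
published 93.91 -- so the published column counts both the multiply and
the add. `count_macs` returns raw multiply-accumulates;
`gmacs_table_convention` doubles them for comparison with such tables.
Convolution MACs are kernel x Cin x Cout x output voxels; transposed
convolutions count per input voxel; pooling, normalisation and
activations count zero; SE blocks count their FC products.

## Losses and metrics

* DSC = 2TP / (2TP + FP + FN); OE = 1 - TP / (TP + FP + FN). Both are
  defined for empty-vs-empty masks (DSC 1, OE 0). They are linked by
  DSC = 2J / (1 + J) with J = 1 - OE.
* Soft Dice loss 1 - (2<p,g> + eps) / (sum p + sum g + eps) with
  eps = 1e-5 in numerator and denominator.
* Weighted BCE: voxel mean of -[wp g log p + (1 - g) log(1 - p)] with
  probabilities clipped to [1e-7, 1 - 1e-7]. The positive-class weight wp
  defaults to 1: nodule-centred crops already mitigate the imbalance.
* Training loss: a * Dice + (1 - a) * BCE with a = 0.5, the weighting
  found best in the reference weighting study.
* Fold comparison: two-sided pooled-variance two-sample t-test on
  per-fold mean DSC (df = n_a + n_b - 2), reported with group mean +- SD.
  Whether the original comparison was paired cannot be determined; the
  unpaired form matches the mean +- SD presentation.

## Training protocol

Adam at initial learning rate 3e-4, batch size 8, at most 200 epochs.
The learning rate decays stepwise every 30 epochs by 1% -- a stated
"decrease of 0.01 per 30 epochs" cannot be absolute at lr = 3e-4, so it
is read as a relative factor of 0.99, exposed in the config. No data
augmentation, no early stopping; the final and best-loss weights are
retained. Folds: 10-fold cross-validation honouring an official `subset`
column when present, otherwise a seeded series-grouped round-robin split
so no scan contributes to both training and test sets. Everything is
seeded: weight initialisation, batch order, fold assignment.

## Synthetic phantoms

Each phantom is a soft-tissue body ellipse containing two air-density
lung ellipsoids, one nodule of a chosen archetype (solid isolated,
lung-wall adherent, ground-glass, vessel-adherent), Gaussian HU noise
(SD 12), and sparse bone/air speckles that exercise the clipping stage.
HU palette: lung -850, soft tissue +40, solid nodule +20, GGO -550 -- all
inside the retained window, with speckles outside it. Nodules are
smoothed ellipsoids (edge sigma 0.6 mm; 1.5 mm for GGO); the ground-truth
mask is the exact pre-smoothing ellipsoid support, noise-free. The
vessel archetype adds a 1.5 mm soft-tissue tube through the nodule
surface; the wall archetype centres the nodule on the lung boundary.
Diameters stay inside the 3.17-27.44 mm screening range. A master seed
fans out per-case seeds; with `anisotropic=True` slice spacing is drawn
from [0.45, 3.0] mm to exercise resampling, mirroring the spacing range
of screening CT.

What passing on phantoms shows: the preprocessing chain is geometrically
exact (at 1 mm generation spacing the cropped mask reproduces the
generator mask with DSC 1.0), the network trains, and gradients are
correct. What it does not show: performance on real nodules -- phantoms
have none of the texture, anatomy or annotation noise of clinical CT.

## Numerical engine

No GPU framework is used: the network runs on a reverse-mode autodiff
engine written on NumPy. Stride-1 convolutions run in the Fourier domain
(scipy.fft) over exactly the axes where the kernel extent exceeds one --
a 1x3x3 kernel never transforms the slice axis -- with the kernel's
flipped spectrum derived from one FFT via a conjugate-phase identity, and
input spectra cached for the backward pass; volumes with at most 12,000
voxels switch to an im2col matrix product on the BLAS, which is faster at
small spatial extents. The two routes agree to float32 precision and
every operator passes central-difference gradient checks at 2% relative
tolerance. Strided (1, 2, 2) transitions are computed by reshaping
(non-overlapping windows). Max-pooling backward scatters to recorded
argmax positions; ties resolve to the first candidate. Batch
normalisation uses momentum 0.1 running statistics; evaluation mode is
deterministic, so batched and single-sample inference agree bit-for-bit.

## Desk-scale configuration

Full-width training at the published protocol is a multi-day GPU
workload and is out of scope here. The learning-dynamics check instead
overfits the four archetype phantoms with width-reduced models
(base 4 channels, unit S3D hidden widths, SE reduction clamped to the
width): batch 2, Adam at 6e-3 (an overfitting rate for a four-sample
memorisation task, not the full-data protocol rate), 150 steps.  The
step budget deliberately ends in the active-descent regime: run much
longer and both models converge to near-zero training loss, where
comparing them measures float noise rather than optimisation behaviour.
Under this fixed seed both the baseline and the full model reach
training soft Dice above 0.85, and the full model's training loss at the
fixed budget is lower than the baseline's -- a directional sanity check
of the added modules, not a reproduction of any published accuracy.

## Known limitations

* The exact DFFM/RACM wiring is not fully constrained by its published
  textual description; this implementation is one consistent realisation.
* The S3D hidden width at level 5 (4x) is a calibration artefact; the
  true authorial width layout is unknowable from the published counts.
* The sphere-proxy ground truth under-represents spiculated margins.
* The t-test helper assumes unpaired folds.
* Batch normalisation with batch size 2 (desk-scale runs) has noisy
  statistics; the full protocol uses batch 8.
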