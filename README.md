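# nodseg — 2.5D lung-nodule segmentation with a separable-3D V-Net

Accurate delineation of pulmonary nodules on chest CT underpins growth
monitoring and early lung-cancer management. Full-3D segmentation
networks use the volumetric context that 2D networks lose, but at a
computational cost that is hard to justify for a target a few voxels
wide. `nodseg` implements a 2.5D compromise end to end: a V-Net-shaped
encoder–decoder that runs cheap separable convolutions where full 3D
kernels matter least, plus three attention-style modules aimed at the
hardest part of the task — nodule edges.

The model consumes an 11-slice, 64×64, nodule-centred CT patch at 1 mm
isotropic spacing and emits a voxelwise nodule probability map. Its
components:

- **S3D convolution** — the deepest two levels replace each 3D kernel by
  a 1×3×3 intra-slice convolution followed by a 3×1×1 inter-slice
  convolution (each + batch norm), cutting parameters and compute while
  keeping through-plane mixing.
- **Central pooling** — down-sampling tiles each axis of length *Q* with
  max-windows of sizes 1/2/3 (small at the nodule-centred middle, large
  at the edges), with counts from the unique solution of
  n₁+2n₂+3n₃=Q, n₁+n₂+n₃=Q/2, n₁+n₃=n₂ — i.e. (Q/8, Q/4, Q/8).
- **DFFM** (dual-branch feature fusion) — skip connections fuse encoder
  and decoder maps through per-branch 3×3×3 convolutions with an
  encoder-side stride-1 max pooling, combined additively.
- **RACM** (reverse attention) — two chained units weight features by
  1 − σ(coarse prediction), pushing capacity toward not-yet-segmented
  edge regions.
- **SE blocks** — channel gates on the decoder path.
- **BCEDice loss** — L = a·L_dice + (1−a)·L_bce with a = 0.5, and
  DSC/OE (1 − Jaccard) evaluation with a 10-fold cross-validation
  harness (lr 3e-4, batch 8, ≤200 epochs, 1% lr decay per 30 epochs).

Everything runs on a built-in NumPy reverse-mode autodiff engine
(FFT-domain and im2col convolutions) — no GPU framework required — and a
synthetic phantom generator emulates the LUNA16 data layout (MetaImage
volumes + world-coordinate `annotations.csv`) with four nodule
archetypes, so the whole pipeline is testable without any download.

## Worked example

```bash
python examples/02_phantom_to_roi.py
```

```
volume (40, 96, 96) at spacing (1.0, 1.0, 1.0) mm, HU range [-1049, 1195]
annotation: centre (73.44, 45.12, 20.0) mm, diameter 10.0 mm
ROI image (11, 64, 64), intensity mean +0.0279 (de-averaged), mask voxels 326 (~335 expected for the ellipsoid)
mask present at the centre voxel: True
```

A synthetic vessel-adherent nodule (5×4×4 mm semi-axes) is written in
LUNA16 format, read back, clipped to [−1000, 600] HU, lung-masked,
resampled, normalised and cropped; the 326 mask voxels match the
analytic ellipsoid volume to 3%, and the annotation centre lands on the
patch centre voxel — the geometry the centre-weighted pooling relies on.

```bash
python examples/03_architecture_fingerprints.py
```

```
preset  model                params (M)     GMAC
     1  V-Net baseline            45.21    93.68
     2  S3D V-Net                 33.69    40.23
     3  +DFFM                     36.49    48.89
     4  +RACM                     38.19    52.70
     5  +central pooling          38.19    52.70
     6  +SE (full model)          38.19    52.70
```

(GMACs use the 2-ops-per-MAC table convention at a 1×11×64×64 input; see
`docs/methods.md`. Preset 5 ≡ 4 in parameters because central pooling is
parameter-free.)

Other entry points: `examples/01_central_pooling.py` (the pooling
operator on worked inputs), `nodseg synth | preprocess | train |
crossval | predict | eval | compare | report-arch` for shell use.

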