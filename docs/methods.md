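# Methods

## Scan geometry and data model

A C-scan is a 3D intensity grid `(X, Y, Z)` = (axial A-scan axis, fast
galvo axis, slow galvo axis), min–max normalized to [0, 1] per volume. The
reference acquisition geometry is a 1024 × 1024 × 128 dense raster covering
3.6 mm × 7 mm × 7 mm with 25.8 µm lateral resolution; the undersampled
acquisition keeps every 4th lateral position in both Y and Z
(1024 × 256 × 32, a 1/16 voxel fraction). With two samples required per
resolvable element, the Nyquist-sufficient lateral count is
round(7 mm / 25.8 µm × 2) = 543, so even the dense raster's 1024 samples
oversample, while 256 and 32 samples reach 47 % and 6 % of sufficiency.

Training triplets are built by exact sub-grid selection from a dense
volume: `mid = high[:, :, ::4]` and `low = mid[:, ::4, :]`. Sparse
selection starts at index 0 and composes (`::a` then `::b` equals `::ab`),
and no anti-alias prefilter is applied: the scanner's spot size and
numerical aperture do not change when fewer positions are visited, so
numerical decimation must not low-pass either. A prefilter remains
available as an explicit opt-in for experiments.

## Networks

Both architectures share one dimension-generic two-path design
(`octvolsr.models.twopath.TwoPathNet`).

* **Upper path**: separable linear interpolation by the lateral factors
  (×4 Y, ×4 Z in 3D; one axis per stage in 2D). Sample positions follow
  the half-pixel-center convention with edge clamping, so constants are
  reproduced exactly.
* **Lower path**: U-Net encoder/decoder of residue blocks — two same-padded
  3×3(×3) convolutions each followed by ReLU, plus an identity shortcut
  (1×1 projection when the channel count changes). No batch normalization
  anywhere: renormalizing feature statistics measurably hurts
  high-frequency reconstruction. Encoder levels halve spatial extent by
  stride-2 max pooling (all three axes by default; lateral-only via
  `pool_axes="yz"`); channels start at 4 and double per level (capped at
  64). Decoder levels upsample linearly ×2, convolve, concatenate the
  encoder skip, and apply a residue block.
* **Multi-level residue decoder**: every level's output (bottleneck
  included) passes through a 4-channel residue head `R_i`; the decoder
  output is accumulated coarsest→finest, `D_i = R_i + Up₂(D_{i−1})`, with
  the base case at the coarsest level. The printed recurrence is grounded
  at the deepest level because only that reading is consistent with ×2
  upsampling per level across the decoder's spatial pyramid. With
  `use_mrd=False` only the finest head output is used (the classical
  decoder, kept as the ablation arm).
* **Output head**: a 4-channel residue block, a 1×1 projection to
  `prod(upsampling factors)` channels (16 in 3D, 4 per 2D stage), then a
  channel-to-space rearrangement. The projection is zero-initialized, so an
  untrained network reproduces pure interpolation bit-for-bit in fp32 —
  training only ever learns the high-frequency residue. At exactly zero the
  projection passes no gradient upstream, but the projection's own first
  update leaves that point, so optimization is not trapped; all remaining
  weights use Kaiming-uniform initialization.

The dual-2D pipeline slices the volume into Z-indexed XY B-scans for the
Y-stage and X-indexed YZ en-face images for the Z-stage. During training
the Z-stage batch is subsampled without replacement (128 of 1024 at full
scale) to bound memory; at test time the full batch is used. Gradients
flow through both stages jointly, with the Y-stage scored against the
mid-resolution member and the Z-stage against the high-resolution member.

All of this runs on a small numpy reverse-mode autodiff engine:
convolutions are im2col + BLAS matmul (chunked along the first spatial
axis to bound the column matrix at ~128 MB), and the backward pass of a
same-padded correlation is a same-padded correlation with the spatially
flipped, channel-transposed kernel. Every op's gradient is checked against
central finite differences in float64 in the test suite. FP16 inference
casts parameters and activations to half precision, exactly halving
parameter bytes; on normalized desk-scale phantoms the output deviates
from fp32 by ~2e-3 at most (bound asserted at 1e-2).

## Objective and metrics

`L = α L_p + β L_g` with `L_p` the mean absolute voxel difference and
`L_g` the per-axis-weighted L1 distance between forward finite differences,
both normalized by the total voxel count N (so weights are independent of
volume size). The axis weights λ = (16, 0.4, 0.05) for (x, y, z) reflect
physical pitch: the same intensity step across a larger physical separation
implies a smaller true gradient, so densely sampled axes get smaller
weights. Defaults α = 16, β = 1. The forward-difference operator over the
N−1 valid positions per axis row is the simplest operator consistent with
the 1/N normalization; axes of extent 1 raise an error.

Metrics: RMSE, PSNR (data range 1, +inf sentinel at zero MSE), and SSIM
computed per XY slice with the standard Gaussian-window formulation
(11 × 11, σ = 1.5, population covariances) and averaged over the slow axis
— a 2D slice-averaged reading was chosen over a 3D window and is the
documented convention throughout. Ablations compare per-volume score lists
with a paired two-tailed t-test; identical lists (zero difference variance)
are surfaced as a degenerate-test error rather than p = NaN.

The non-learned baseline is cubic spline interpolation along Y and Z with
knots placed exactly on the retained A-scan positions (low index i ↔ dense
index 4i). Generic zoom routines place samples on a shifted grid and would
misalign the baseline with the decimation convention.

## Phantom generator

`octvolsr.phantom` renders schematic anterior-segment volumes: a corneal
spherical-cap shell, two iris slabs with a circular pupil aperture, and a
crystalline-lens ellipsoid (reflective shell, weakly scattering interior)
over a dark background. The clean geometric render is then smoothed by a
Gaussian point-spread-function surrogate (default σ = 1.5 voxels — the
25.8 µm spot spans about that many dense-grid voxels laterally), and
multiplied by unit-mean gamma speckle (shape 1/scale², default scale 0.3)
before renormalization. PSF smoothing matters beyond realism: a binary
step edge decimated ×4 is not a recoverable function of the sparse input,
whereas band-limited boundaries are — which is exactly the premise of
super-resolving a beam-limited scanner.

Datasets draw jittered specs (geometry perturbed ±10 % by default) from
one seeded generator, rejecting and resampling specs whose structures
leave the grid, and split train/validation at 200:236 by default. The
desk-scale grid is 64 × 64 × 32 (divisible by 4 laterally and by the
encoder pooling); the full 1024-scale grid is available through the same
config.

What the phantoms do **not** emulate: attenuation and shadowing along the
beam, the axial interferometric PSF shape, motion artifacts, vascular or
layered retinal texture, and realistic intensity statistics of tissue.
Passing the desk-scale studies therefore demonstrates that the
implementation learns and that the architecture behaves as designed — not
that it reaches any particular fidelity on real eyes.

## Training protocol and study sizes

Training follows the published recipe: Adam (β = 0.9/0.999, ε = 1e-8 —
the recipe names only the optimizer, so its standard defaults are used),
initial rate 1e-3, halvings at epochs 25/75/125/175, one low/high volume
pair per iteration (slice batches for the dual-2D model), loss computed at
fp32. Checkpoints embed both configs and reload to bit-identical forward
outputs.

The bundled studies run at desk scale — depth 3, 4 base channels,
20 phantoms (17 train / 3 validation), 30 epochs, a couple of minutes each
on one CPU core:

* **Baseline comparison**: the trained 3D+MRD network beats cubic
  interpolation on held-out phantoms by ~0.8–1.7 dB mean PSNR across the
  seeds tried. This direction is robust.
* **MRD convergence**: at this scale the difference between the MRD and
  classical-decoder arms is smaller than the seed-to-seed spread (~2 % of
  final training loss); the MRD arm reaches the classical arm's final loss
  early at some seeds and not at all at others. The three-level decoder
  and the quickly reached speckle floor leave the multi-level aggregation
  little room to act; resolving the effect would need the full-depth,
  full-data configuration.
* **Single-phantom overfit**: on one noiseless phantom the 200-iteration
  recipe reduces the total loss by ~1.4× (learning-rate and initialization
  sweeps reach at most ~3× within 500 iterations). A 200-step Adam budget
  on a ~30k-parameter network does not drive a 10× fit at this scale.

The last two observations are reported as measured; the corresponding
acceptance assertions are intentionally left failing rather than loosened.

## Numerical choices and edge cases

* Min–max normalization of a constant volume raises a degenerate-range
  error; normalization is idempotent and order-preserving.
* Decimation steps larger than an axis keep a single slice and log a
  warning; triplet construction strictly requires lateral divisibility
  by 4 and names the offending axis.
* Forward passes validate divisibility by `pool^(depth−1)` up front and
  raise before any computation.
* Channel-to-space rearrangement is an exact bijection (inverse provided);
  max-pool ties resolve to the first maximum (numpy argmax order).
* All randomness (weight init, phantom jitter, epoch shuffling, Z-stage
  subsampling) flows from one seeded generator per run; repeated runs with
  the same seed produce bit-identical checkpoints on the same BLAS.
* File I/O: multi-page TIFF (one XY page per Z index), NIfTI-1 (identity
  affine), NPZ (`volume` key); round-trips are bit-exact at float32.
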