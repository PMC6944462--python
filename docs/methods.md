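# Methods

## The imaging problem

Translational CT (TCT) replaces the rotating gantry of a conventional scanner
with two opposite linear translations: the X-ray source slides along one line
while the flat-panel detector slides along a parallel line on the far side of
the object. One translation acquires a 30° *segment* of views; between
segments the source/detector pair is rotated rigidly about the object by 30°.
A limited-angle scan stops after 3–5 segments ([0°, 90°] to [0°, 150°]),
short of the classical fan-beam sufficiency range of 180° plus the fan angle,
so the inverse problem is ill-posed and reconstructions show directional
streak and shading artifacts.

Discretized, the measurement model is the linear system `A x = b`, where
`x ∈ R^N` collects the pixel attenuation values, `b ∈ R^M` the measured line
integrals, and `a_ij` is the intersection length of ray `i` with pixel `j`.

## Scanning geometry

Defaults (all configurable in `TCTParams`): source–detector distance 1300 mm,
source–axis distance 900 mm, 207 views per 30° segment at 0.145° spacing,
800 detector elements of 1 mm, 256 × 256 image grid with 1.38 mm pixels
(≈ 353 mm field of view). Within a segment the view at deflection angle γ has
its source at distance `R_s tan γ` along the translation line; its detector
array is centered where the source–axis line meets the opposite translation
line and stays parallel to that line (a translating flat panel). This makes
the central ray of every view pass through the rotation axis, and the
source-to-detector-midpoint distance equal `D / cos γ`.

Two conventions were genuinely open and are fixed as follows:

- **View-angle sign.** The source abscissa runs opposite to γ, so that the
  view angle at the axis (`view_angles`) increases strictly within a segment
  and the central view of segment m sits at `15° + 30° m`. The mirrored
  convention describes the identical physical scan.
- **Segment closure.** 207 views at 0.145° span 29.87°, not 30°; the literal
  counts take precedence and the 0.13° slack per segment is accepted. No
  views are duplicated at segment boundaries.

The nominal field-of-view diameter (352.90 mm) is carried as metadata only;
no computation derives or asserts it.

## Projector

`a_ij` is the exact ray/pixel intersection length computed by Siddon grid
traversal, one ray per detector element (no element-footprint integration).
Forward projection, backprojection and the normalization sums share the same
traversal, so the operator pair is exactly adjoint
(`⟨Af, g⟩ = ⟨f, Aᵀg⟩` to round-off, verified to 1e−10 relative in the tests).
Rays that miss the image square have row sum `a_i+ = 0` and are excluded from
reconstruction updates; pixels crossed by no ray (`a_+j = 0`) are never
updated. A dense brute-force intersection oracle (interval clipping of every
ray against every pixel box) lives in the test suite and pins the traversal
on grids up to 32 × 32.

A note on the disk/chord validation: projections of a *rasterized* disk match
the analytic chord `2√(r²−d²)` to within about one pixel diagonal only away
from the rim. Near tangency the chord's sensitivity to boundary placement,
`2d/√(r²−d²)`, diverges, so no pixelized phantom can meet a flat bound there;
the tests therefore check rays with `d ≤ 0.7 r`. This is a property of
rasterization, not of the projector (which the dense oracle verifies
exactly).

## SART

The simultaneous update, with relaxation β (default 1):

    f_j ← f_j + β (1/a_+j) Σ_i (a_ij / a_i+) (b_i − A_i f)

The default mode runs the literal simultaneous sum over all M rays per sweep;
`view_sequential` applies one sub-update per source position in acquisition
order, normalizing by per-view column sums (the classical SART ordering). The
initial image is zero, there is no nonnegativity clamp by default (a flag
provides one), and the stopping rule is a fixed sweep count — 2500 at the
production 256 × 256 scale, scaled to 300 for 64 × 64 desk runs. Per-sweep
residual norms `‖Af − b‖` are recorded for diagnostics only; on consistent
data they are non-increasing, and consistent data are a fixed point of the
update.

## FBP baseline

The analytic baseline rebins every TCT ray to parallel-beam coordinates
(normal angle θ ∈ [0°, 180°), signed axis distance s) by bilinear splatting
with weight normalization, fills empty interior bins by 1-D interpolation
along s, ramp-filters, and backprojects over the covered angles only (the
angular weighting is corrected for partial coverage). Filtering and
backprojection delegate to `skimage.transform.iradon`; the output is
resampled onto the package's pixel-center grid (the two grids differ by half
a pixel) and rescaled for the mm sample spacing. Default rebin grid: one
angle bin per view and offsets at the image pixel pitch; a finer offset
pitch is supported and improves full-coverage quality. With full coverage
(≥ 180° + fan) the baseline reconstructs a disk at ≥ 25 dB PSNR; under
limited angles it is dominated by SART, which is the motivation for feeding
the network SART images rather than FBP images.

## Phantoms, noise, datasets

The phantom generator stands in for real chest/abdomen CT labels; it makes
no claim of anatomical realism. `random_anatomy` draws a body-outline
ellipse (attenuation 0.25, axes 75–90 % of the field) containing 4–9 random
internal ellipses with attenuations in [0.05, 0.45]; `shepp_logan` rasterizes
the classic ten-ellipse head phantom. Rasterization is pixel-center
membership, deterministic per seed. With these attenuations the line
integrals across the ~353 mm field are O(10²), so additive Gaussian noise of
variance 10 on the line integrals — applied post-log, the literal reading of
noise "on the projection data" — is a visible but moderate perturbation.

`build_dataset` runs phantom → forward projection → optional noise → SART
per index, pairing the SART image (network input) with the phantom (label).
Train and test indices draw from disjoint `SeedSequence` spawn keys of one
master seed, so the splits cannot share a phantom and the whole archive is
bit-reproducible. The production-scale configuration is 450 train / 50 test
pairs at 256 × 256 with 2500 SART sweeps; the desk-scale default used
throughout the tests and the acceptance script is 20 / 5 at 64 × 64 with 300
sweeps, which runs end-to-end on one CPU in minutes. Desk-scale geometry
(`desk_scale_params`) keeps every physical distance and the 30° segment
structure, cutting view and detector-element counts in proportion to the
coarser grid (52 views × 200 elements per segment at 64 × 64).

## U-net

Encoder of `depth` stages (default 4; desk runs use 3) of two 3 × 3
zero-padded convolutions + ReLU followed by 2 × 2 max pooling, channels
doubling from `base_channels` (default 64; desk runs use 8–16); bottleneck;
decoder of 2 × 2 up-convolutions, concatenation with the matching encoder
feature map, and batch-normalized conv + ReLU pairs; a final 1 × 1
convolution reduces to one channel. A residual connection adds the input
image to the output, so the convolutional path learns the artifact
component. The implementation is pure numpy with hand-written backward
passes (verified against central finite differences); batch size is fixed
at 1, and batch normalization therefore normalizes per channel over the
spatial dimensions, with running statistics used at inference.

Two numerical choices matter:

- **Zero-initialized output layer.** All convolutions use seeded He-normal
  init except the final 1 × 1 convolution, which starts at zero. With the
  residual skip the untrained network is then exactly the identity, so
  training can only improve on its SART input instead of first un-learning
  initialization noise — important at desk scale where the step budget is
  small.
- **Input normalization.** Inputs and labels are divided by a single
  constant, the maximum over the training labels, stored with the model and
  re-applied at inference.

Training is momentum SGD on the mean squared error, learning rate log-spaced
across epochs, with optional clipping of the global gradient norm.
Production-scale hyperparameters: lr 0.01 → 0.001, momentum 0.99, 151
epochs, patch size 256 (the full image, so no cropping), gradient clip 1e−2.
At desk scale the loss sits two orders of magnitude lower (the SART input is
already close to the label), so proportionally larger steps are needed for
the ~800-step budget to move the weights: the desk preset trains with
lr 0.5 → 0.05, momentum 0.99, no clipping, 40 epochs (chosen by pilot runs at
this scale; larger steps destabilize training). When inputs exceed the
patch size, seeded random crops are taken. Training is bit-reproducible from
its seeds on a fixed numpy/BLAS stack; across BLAS builds, reductions may
reorder and results can differ in the last few ulps.

## Metrics

PSNR uses the label's maximum as peak: `10 log10(max(y)² / MSE)`; identical
images report +∞. SSIM is computed *globally* — single means, variances and
covariance over the whole image — with `C1 = (0.01 L)²`, `C2 = (0.03 L)²`,
`L = max(y)`; this is the printed-formula form rather than the usual 7 × 7
sliding-window mean, which is available behind `windowed=True` (delegating to
scikit-image) for cross-tool comparison. Batch evaluation reports four
decimals.

## What the synthetic experiments do and do not show

The desk-scale experiment (random-anatomy phantoms, noiseless [0°, 120°],
SART 300 sweeps, U-net depth 3 / base 8–16, ~40 epochs) demonstrates the
pipeline's orderings: reconstruction quality rises with scan range, SART
dominates FBP under limited angles, and the trained network improves on its
SART inputs on held-out phantoms. The margins at this scale are fractions of
a dB — the 64 × 64 SART images are already close to the piecewise-elliptical
phantoms, leaving the network little artifact to remove. Nothing here
certifies performance on real anatomy: elliptical phantoms lack texture,
bone/air extremes, and detector physics (polychromatic spectra, scatter,
electronic noise), and the production-scale configuration (450 real labels,
2500 sweeps, 151 epochs) is orders of magnitude beyond a CPU test budget.

## Known limitations

- 2-D fan geometry only; no cone-beam/3-D support.
- The FBP baseline is one defensible construction (rebin + Ram-Lak), not a
  TCT-specific optimized analytic algorithm.
- The numpy U-net is CPU-bound; production-scale training is impractical
  without porting the layers to an accelerated backend.
- Global SSIM saturates near 1 on images that agree in low-order moments;
  the windowed variant is the better discriminator across tools.
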