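# Methods

## The imaging model

Magnetic particle imaging (MPI) measures the voltage induced in a receive
coil by the nonlinear magnetization of superparamagnetic nanoparticle (MNP)
tracers while a field-free point (FFP) is swept across the field of view.
For an ensemble of particles with magnetic moment `m0` at temperature `T0`,
the equilibrium magnetization follows the Langevin law `L(xi) = coth(xi) -
1/xi`.  X-space reconstruction grids the received signal by the
instantaneous FFP position; the resulting "native" image equals the true
concentration map convolved with a point-spread function (PSF) proportional
to the field derivative of the Langevin function,

    L'(xi) = 1/xi^2 - csch(xi)^2,    xi = k * G * x,
    k = mu0 * m0 / (kB * T0 * h_sat),

where `G` is the selection-field gradient and `h_sat` the saturation field
scale normalizing the drive-field argument.  The simulator evaluates both
functions with a Taylor-series branch below `|xi| < 1e-2` (`xi/3 - xi^3/45`
and `1/3 - xi^2/15 + 2 xi^4/189`) because the closed forms cancel
catastrophically near zero; the branch point keeps the relative error of
both branches below ~1e-10.

The 2-D model is deliberately scalar: a single receive channel in the x-z
plane with constant coil sensitivity, no particle relaxation, no Lissajous
trajectory.  Under those assumptions the native image is exactly
`PSF (*) phantom` plus additive noise, which is what the image-domain
pipeline implements.  1-D signal synthesis along a sinusoidal FFP
trajectory (`simulate_signal`) is provided to make the derivative
relationship between the induced voltage and the total magnetization
testable; it is not part of the image pipeline.

### Default physical parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| `mu0` | vacuum permeability | 4π × 1e-7 | N A⁻² |
| `D` | particle diameter (metadata; the moment is given directly) | 20 | nm |
| `T0` | temperature | 293 | K |
| `kB` | Boltzmann constant | 1.28e-23 | J K⁻¹ |
| `m0` | particle magnetic moment | 6.75e-18 | A m² |
| `G` | selection-field gradient | 6 | T m⁻¹ μ0⁻¹ |
| SNR | additive-noise range, sampled uniformly | 5–15 | dB |
| `h_sat` | saturation field scale | 1.6e-5 | A m⁻¹ |

`kB` is kept at the source table's printed 1.28e-23 rather than the
physical 1.38e-23 so that default simulations reproduce the published
configuration; both are accepted through the config.  Since `kB`, `m0` and
`h_sat` only enter through the single product `k`, the printed-vs-physical
discrepancy is absorbed by `h_sat` with no observable consequence.

`h_sat` has no published value.  It is the one free scale that sets the
PSF width: the default makes the Langevin argument traverse the nonlinear
region across the 40 mm field of view, giving a PSF FWHM of ≈4.9 mm
(≈6 px at 50 px), with resolution scaling exactly as `1/G`.  A wider-PSF
variant (larger `h_sat`) was evaluated and rejected: it degrades the
learning task faster than the classical inverses and is not required by any
quantitative target.

The field of view defaults to 4 cm (the only physical scale the source
reports for its scanner), hence 0.8 mm pixels at the canonical 50 × 50
image size.  Convolution uses symmetric (mirror) boundary padding,
configurable; the Wiener tests use circular (`wrap`) blurring where an
exactly invertible forward operator is needed.

## Synthetic phantoms and the dataset

The published study hand-drew 400 binary tumor images; those shapes cannot
be redrawn programmatically, so the generator replaces them with seeded
star-shaped polygons `r(θ) = R (1 + Σ_k a_k cos(kθ + φ_k))`, k ∈ {2,3,4},
rasterized and checked for pixel area within a configurable range (default
30–200 px²), count (1–3 blobs), border clearance and mutual separation.
What this emulates about the real corpus: diversity of lesion size, shape
and count, distinct grayscale concentration levels (including the 1:r
two-target ratio designs), within-lesion gradients (Gaussian smoothing of
the level map), and eightfold dihedral augmentation.  What it does not
emulate: the geometry of hand-drawn or 3D-printed phantoms, scanner noise
statistics beyond a spatially correlated Gaussian field, and any
concentration–signal nonlinearity.  Passing tests therefore demonstrate the
method's behavior under the stated forward model, not performance on real
scanner data.

Each base phantom expands into a *family*: {binary, multi-level grayscale,
gradient grayscale} × 8 dihedral variants (≤24 images).  Families are
assigned whole to a split (test first, then train; the last family of a
split may be truncated), so no phantom and its augmented variants ever
straddle the train/test boundary.  Each entry is blurred with the PSF
(25 px kernel at the image pixel pitch) and corrupted by a zero-mean, unit
variance noise field (Gaussian, correlation length 2 px, emulating the
spatially varying background noise of a real scanner) scaled so the
realized SNR equals a uniform draw from [5, 15] dB exactly.  Everything is
driven by one `numpy` generator per build, making datasets byte-identical
across reruns of the same seed.

## The network

Input is the raw native image (≈[0, 1] after blur, with noise excursions;
no per-image normalization, so absolute concentration ratios remain
learnable).  A 3×3 stem embeds it into `base_channels` (default 16)
channels.

* **Dual-branch CNN** — three stages; per stage, branch 1 is conv→ReLU→2×2
  average pool (artifact suppression at reduced resolution), bilinearly
  upsampled back and added to branch 2's conv→ReLU output.  Produces `Uc`.
* **Transformer** — operating on `Uc` (cascade) or on the stem output when
  the CNN branch is ablated.  The feature map is average-pooled twice
  (tokens = 13² at 50 px input), projected by a depth-wise separable
  convolution into Q, K, V token matrices, run through multi-head scaled
  dot-product attention (scale `1/sqrt(d_head)`, softmax over keys, heads
  concatenated, averaged residual `(O + I)/2`; a plain-sum variant is a
  config switch), refined token-wise by LayerNorm → 2-layer ReLU MLP with a
  residual, reshaped and upsampled back.  Produces `Ut`.  No positional
  encoding: the token pipeline is permutation-equivariant, and the attention
  implementation is output-equivalent to a dense per-head loop (asserted in
  tests).
* **Channel-attention fusion** — concat(`Uc`, `Ut`) → 3×3 conv → ReLU,
  gated per channel by GAP → bottleneck (reduction 4) → ReLU → linear →
  sigmoid, then a 3×3 conv + 1×1 head.

All three heads (`x_a` CNN, `x_b` Transformer, `x_f` fusion) are 1×1
projections *added to the input image*: the network predicts a correction,
not the image.  Head weights start at 1/100 of He scale so training begins
near the identity.  This global residual is this package's design (the
source describes per-module predictions but not how they are formed);
without it the single-pair capacity probe plateaus far below its target in
every configuration tested.  Deployed predictions are clipped to [0, 1],
the valid relative-concentration range.

The loss is `λa·MSE(x_a, y) + λb·MSE(x_b, y) + λf·MSE(x_f, y)` with
defaults λa = λb = 0.5, λf = 1.0 (unpublished in the source; chosen to
keep the fusion head dominant while still supervising both branches).

Ablation variants: CNN-only and Transformer-only deploy their branch
through the fusion head (no second branch, no channel attention);
"fusion without attention" keeps both branches and the fusion conv but
removes the gate; branch heads absent from a variant drop out of the loss.

### Numerical and training choices

* Training runs in float32 on a hand-written numpy reverse-mode autodiff
  engine (no deep-learning framework is a dependency); oracle-grade tests
  cast the network to float64.  All operator gradients are verified against
  central finite differences.
* Optimizer: Adam, lr 2e-3, batch 16, cosine-decayed to lr/20 over the run
  (constant-lr training at the larger step sizes the capacity probe needs
  proved divergence-prone — dead-ReLU collapse).  Validation is a seeded
  10 % carve-out of the training split; the checkpoint with the lowest
  validation loss is kept.
* The single-pair capacity probe uses 500 Adam steps at lr 8e-3,
  β₂ = 0.99 (a shorter second-moment horizon suits a stationary
  single-sample objective), with a 30-step linear warmup followed by
  cosine decay; the warmup keeps the near-identity start from being
  destroyed by the first large steps.
* Degenerate inputs: an all-zero phantom is a legal input everywhere except
  SNR scaling, which requires nonzero signal power; `target_snr_db = inf`
  is the documented no-noise sentinel; Richardson–Lucy clips negative
  observation pixels with a warning.

## Baselines

Wiener inversion is the per-frequency closed form `H* Y / (|H|² + nsr)`
with the true simulation PSF and `nsr = 10^(−SNR/10)` at the dataset's mid
SNR — the most favorable classical configuration.  Richardson–Lucy (30
iterations default) is implemented directly so its convolutions share the
forward model's symmetric boundary (library versions zero-pad, which breaks
the uniform-image fixed point).  Blind deconvolution alternates RL updates
of image and kernel from a flat kernel.  Their hyperparameters are
unpublished in the source; rank order, not magnitude, is the reproduction
target.

## Metrics

PSNR is `10·log10(255²/MSE)` with per-pixel MSE on images rescaled from
[0, 1] to [0, 255]; identical images report an `inf` sentinel excluded from
aggregate means with a warning.  SSIM defaults to the global-statistics
form (whole-image means, population variances, covariance; stabilizers
`(0.01·255)²`, `(0.03·255)²`), which is the form the source's formula
states; the windowed scikit-image variant is available.  Aggregates are
mean ± population std.

## Problem sizes

The reduced end-to-end study shipped in the test suite and acceptance
script trains on 400 pairs for 24 epochs with a 40-pair held-out
test set (seed 7), instead of the source's 7000/1000 × full training —
a size this package adopts so the whole suite runs on a single CPU.  All
study checks are relative (margins over native images and classical
baselines, ablation ordering), so the reduction changes statistical power,
not the direction of any comparison.  Absolute metric levels from the
source's tables are not reproduction targets here: they depend on the
hand-drawn corpus and unreported training budgets.

## Known limitations

* No particle relaxation, 3-D imaging, Lissajous trajectories or
  system-matrix reconstruction.
* The transformer tokenizes at quarter resolution; extremely fine
  structure is carried by the CNN branch and the global residual.
* At reduced training scale the channel-attention gate's benefit is within
  training noise of the ungated fusion; the full-vs-ungated comparison is
  the least stable of the ablation inequalities.
* Real-scanner generalization is untested inside this repository; the
  transfer-learning path (freeze all but fusion/heads, fine-tune) is
  exercised on synthetic domain shifts only.
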