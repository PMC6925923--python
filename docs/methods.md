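# Methods

## Problem and model

Low-dose CT (LDCT) acquisitions trade radiation exposure for image quality:
lowering the tube current reduces the photon count at the detector, and the
reconstructed slices become noisy.  Supervised denoisers need pixel-aligned
low-dose/normal-dose pairs, which clinical practice rarely provides.  This
package implements an *unpaired* approach: a cycle-consistent adversarial
network whose forward generator is additionally anchored by a classically
denoised **prior image** computed from the low-dose input itself.

Two generators are trained jointly: `G_N` maps low-dose slices toward the
normal-dose domain and `F_L` maps back.  Two fully convolutional patch
critics `D_N`, `D_L` score realness.  With least-squares adversarial terms,
the generator objective is

    L_G = E[(D_N(G_N(x)) - 1)^2] + E[(D_L(F_L(y)) - 1)^2]
        + lambda * ( E||F_L(G_N(x)) - x||_1 + E||G_N(F_L(y)) - y||_1 )
        + alpha  * E||G_N(x) - I_prior(x)||_1

and each discriminator minimizes `E[(D(real)-1)^2] + E[D(fake)^2]`.  The
prior image `I_prior(x)` is a BM3D-denoised copy of the low-dose slice `x`;
because it derives from the source side only, the unpaired property of the
training set is untouched.  The prior term applies to the forward generator
only, and no identity loss is used.

All L1/least-squares reductions are pixel *means*, so `lambda = 10` and
`alpha = 10` (the defaults) are scale-free across patch sizes.  The
discriminator loss carries no 1/2 factor.

## Architectures

Generator (base width `w`, default 64): reflection-padded 7x7 conv to `w`
channels, two stride-2 3x3 convs to `2w` and `4w` (encoder); `n_res_blocks`
(default 6) residual blocks at `4w` (convertor); two fractional-stride
(transposed 3x3, stride 2) convs to `w` and `w/2`, then a reflection-padded
7x7 linear projection to the output channels (decoder).  The decoder widths
are deliberately asymmetric (`u64`/`u32` against a width-64 encoder).
Instance normalization and ReLU follow every layer except the final
projection, which is linear; intensities are mapped from the configured CT
range (default [0, 2000]) to [-1, 1] before the network and back after.

Discriminator: four 4x4 stride-2 conv blocks at `w, 2w, 4w, 8w` channels,
each with instance norm (including the first block) and LeakyReLU slope
0.2, then a 4x4 stride-1 conv with one filter.  The output is a 2-D map of
per-patch scores; with all four blocks at stride 2 the receptive field is
larger than the classic 70x70 patch critic.

The layer stack (convolutions, transposed convolutions, reflection padding,
instance norm, activations, residual blocks), the manual backpropagation
through it and the Adam optimizer are implemented in NumPy (`cyclect.nn`),
in float64 and single-threaded, which makes every run bit-reproducible for
a fixed seed and lets the gradient path be verified against central finite
differences (see the loss tests).

## Training protocol

Adam (beta1 = 0.5, beta2 = 0.999), batch size 1.  The learning rate is
constant at `lr0 = 2e-4` until `decay_start_epoch` and then decays linearly
to zero at `total_epochs` (defaults 10k/20k).  One step updates the two
generators jointly, then the two discriminators on detached fakes; every
network is touched exactly once per step.  An epoch is one pass over the
source collection with a fresh shuffle; the target slice for each step is
drawn independently, so index-matched pairs occur only at chance rate.
`max_steps` caps the total step count as an alternative budget unit.  No
image-history buffer is used for the discriminators.

Because the endpoint of adversarial training is noisy at small scale, the
trainer can record intermediate checkpoints and select the one with the
best *unpaired-legal* validation score: the mean absolute deviation of the
generator output from the prior images on a fixed subset of source slices
(the quantity the prior term explicitly controls), or the forward cycle
reconstruction error when training runs without a prior.  The normal-dose
reference is never consulted.

## Prior images

BM3D is the default prior denoiser and is implemented in full
(`cyclect.bm3d`): stage 1 groups similar 8x8 blocks (L2 distance, 39x39
search window, up to 16 blocks), applies a separable 3-D transform (2-D DCT
per block, 1-D Haar across the stack), hard-thresholds at `2.7 * sigma` and
aggregates overlapping estimates with weights inversely proportional to the
retained-coefficient count; stage 2 re-matches on the stage-1 estimate and
applies empirical Wiener shrinkage.  The group DC coefficient is never
shrunk, so flat images pass through exactly, and `sigma = 0` is the exact
identity.  Priors are computed on full slices (not per patch) to avoid
block-boundary artifacts.

The per-slice noise level feeding BM3D is Donoho's estimator: the median
absolute deviation of the finest-scale diagonal wavelet detail divided by
0.6745.  This is accurate for white noise but *structurally biased low* on
reconstruction noise: filtered back-projection (FBP) noise is spatially
correlated and, at sparse view counts, streak-like — sparse, heavy-tailed
detail coefficients that a median-based estimator deliberately ignores.
Measurements on the simulator's 32x32 slices show the estimate at roughly
half the true noise standard deviation; no robust fine-scale estimator can
recover the remainder because half the noise power sits below the finest
scales.  The prior interface is therefore pluggable (`bm3d`, `gaussian`,
`nlm`, `median`): the scaled-down study protocol (below) uses the 3x3
median-filter prior, the classical choice against sparse streak noise,
while BM3D remains the default and is what full-scale (512x512, dense-view)
data should use.

## Synthetic data

The simulator emulates unpaired two-dose CT slice collections: a body-like
phantom (large soft-tissue ellipse, random interior ellipses at +-10%
water contrast, high-attenuation bone features, and at least one bone
containing a 1-3 px gap — a probe for hallucinated bridging), parallel-beam
Radon projection over [0, 180) degrees, Poisson photon statistics in the
sinogram, and FBP reconstruction mapped to a CT-number-like scale (water
~1000, range [0, 2000]) so display windows such as [800, 1300] are
meaningful.  Dose fractions follow the tube-current ratios
{1, 0.5, 0.25, 0.10, 0.05} of a five-level acquisition protocol; the 5%
arm is the default low-dose condition.  Transmitted counts are drawn as
`N ~ Poisson(dose * I0 * exp(-p))` and the noisy line integral is
`-ln(max(N,1) / (dose * I0))` (counts clamped at 1 before the log).

Projections are normalized so that a water path across the image width
accumulates a total attenuation of 5 (a body-scale value): photon
statistics are then independent of the grid size, and full-dose
transmission stays physical at any resolution.  Defaults: 720 views,
`I0 = 1e5` photons/bin at 100% dose, 512x512 slices.

What the simulator does *not* model: fan-beam/helical geometry, scatter,
beam hardening, detector cross-talk, anatomical texture, 3-D correlation
between slices.  Passing tests on this data demonstrates that the training
mechanics, losses and metrics behave as designed — not that the method
reaches any particular quality on real scanner data.

## Scaled-down study conditions

Full-scale training (512x512 slices, width-64 networks, tens of thousands
of epochs) is far outside a desk-scale budget, so the package's own
experiments run a scaled surrogate whose conditions are fixed once:

* 32x32 slices, 60 views, 5% dose, `I0 = 1.5e4` — calibrated so the
  low-dose arm lands in the quality regime real 5%-dose scans show against
  their normal-dose reference (~27-28 dB PSNR); at the spec-default
  `I0 = 1e5` a 32x32 reconstruction is far cleaner than real low-dose data
  and would make the denoising task trivial to state but meaningless.
* 64 slices per collection (48 train / 16 test), pairing broken by seeded
  shuffle; width-8 networks with the full six residual blocks (at width 8
  the convertor's capacity, not its depth, is the scarce resource, and the
  deeper convertor measurably improves reconstruction fidelity).
* 60 epochs x 48 steps = 2880 steps, decay from epoch 30, checkpoints
  every 2 epochs with prior-anchored checkpoint selection; median-filter
  prior (see above).
* Evaluation: PSNR (MAX = 2000, logged in every report), SSIM (Gaussian
  11x11, sigma 1.5, K1 = 0.01, K2 = 0.03), NMAD with the denoised image in
  the denominator exactly as the metric's printed definition has it (a
  deliberate asymmetry; a flag offers the reference-normalized variant).

At this scale the improvement of the denoised output over the raw low-dose
input is directional and stochastic — a few tenths of a dB up to ~1 dB
depending on the seed — while the gap to the no-prior ablation (alpha = 0)
is large and stable (the ablation typically loses 2-4 dB and visibly
hallucinates).  This mirrors the full-scale finding that the prior term,
not the adversarial term, carries the content fidelity.

## Numerical choices and edge cases

* PSNR of identical images is reported as +inf and excluded from means
  with a warning.  NMAD of an all-zero denoised image is an error.
* Display-window export rounds half to even after the affine map to
  [0, 255].
* Patch tiling is non-overlapping, row-major, origin-tagged; reassembly is
  bit-exact and order-invariant, and refuses missing or duplicate tiles.
* The pairing-breaking shuffle re-draws until non-identity (n > 1); a
  single-slice target cannot be de-paired and logs a warning.
* Counts clamped at 1 before the sinogram log; line integrals clamped at 0.
* Weight init: kernels N(0, 0.02), zero biases, per-network seeds derived
  from the master seed.  Checkpoint resume restores weights, Adam moments
  and the RNG bit-generator state, reproducing a direct run bit-for-bit.

## Known limitations

* The NumPy engine is single-core and float64: throughput is desk-scale
  (tens of ms per 32x32 step); full-scale runs need a GPU re-implementation
  behind the same interfaces.
* The wavelet noise estimator under-reads correlated FBP noise (discussed
  above); BM3D priors at sparse-view toy scale are weaker than the median
  prior for that reason.
* The alpha-sweep harness reproduces the protocol (one network per alpha,
  identical settings otherwise, seeded random evaluation subset), but toy
  curves need not peak at the same alpha as full-scale data.
* Slice collections are treated as exchangeable; no 3-D context.
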