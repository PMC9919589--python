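# Methods

This note records the models implemented in `seepvision`, the choices made
where the design was genuinely open, and what the synthetic test bed does
and does not establish about real imagery.

## Problem setting

ROV surveys of cold-seep habitats produce imagery with a strong blue-green
color cast (selective red attenuation), low contrast, veiling backscatter,
non-uniform lamp illumination and sensor noise. Supervised enhancement is
blocked by the absence of ground-truth clean frames, so the package follows
a two-stage strategy: (1) build a *clear* image domain automatically by
sweeping a classical one-parameter enhancer and keeping, per frame, the
parameter that maximises a no-reference quality metric; (2) train an
unpaired image-to-image translation model (CycleGAN) between the degraded
domain and that constructed clear domain, yielding a single feed-forward
enhancer (and, as a by-product, a degrader useful for data augmentation).

## Simplified MSRCR

The enhancer is the one-knob simplification of multi-scale retinex with
color restoration used by the GIMP retinex plug-in. Per channel, with mean
`Mean` and population standard deviation `Var` of the channel intensities,

```
Min = Mean - Dyn * Var        Max = Mean + Dyn * Var
out = (Value - Min) / (Max - Min) * 255,  clipped to [0, 255]
```

Design decisions:

* **`Var` is the standard deviation, not the variance.** This matches the
  GIMP "Dyn" slider the method descends from; with the variance the bounds
  would be nonsensical for any natural image (sigma^2 is typically in the
  hundreds, putting `Min` far below 0 at every useful `Dyn`).
* Statistics are computed on the floating-point working channel (after the
  optional pre-filter), never on re-quantised 8-bit values. Output is
  clipped then rounded half-away-from-zero at storage.
* A channel with zero dispersion (`Max == Min`) passes through unchanged;
  constant images are exact fixed points.
* Channels are processed independently; the one-parameter form defines no
  cross-channel color-restoration term and none is added.
* The optional multi-scale retinex pre-filter computes, per channel, the
  equal-weight mean over scales of `log(ch+1) - log(G_sigma(ch)+1)` with a
  separable reflective-boundary Gaussian surround (default sigmas 16, 80,
  240 px), rescaled per channel to [0, 255]; a constant response maps to
  mid-gray 127.5. Whether the historical pipeline ran this pre-filter
  before the stretch is ambiguous, so it is a flag: off by default in the
  library (the stretch alone is the reference behaviour that all oracle
  tests pin down), on by default in the `enhance` CLI command, which
  follows the plug-in lineage.

## UIQM

Quality is judged by the underwater image quality measure
`UIQM = c1*UICM + c2*UISM + c3*UIConM` with the published weights
c1=0.0282, c2=0.2953, c3=3.5753. All constants (weights, trim fraction
0.1 per tail, block 8 px, PLIP gamma 1026, eps 1e-7) live in
`MetricConfig` and are embedded in every dataset manifest, because UIQM
values are comparable only within one configuration.

* **UICM** uses the asymmetric alpha-trimmed mean of the opponent channels
  `RG = R-G`, `YB = (R+G)/2 - B` (trim count per tail `ceil(alpha*N)`); the
  dispersion term averages squared deviations from the trimmed mean over
  *all* pixels, the form given in the metric's original description.
* **UISM** multiplies the Sobel gradient magnitude elementwise into each
  channel and applies the blockwise EME log-contrast
  `(2/K) * sum ln((max+eps)/(min+eps))`, combining channels with luma
  weights 0.299/0.587/0.114. Partial edge tiles are discarded.
* **UIConM** applies the logAMEE entropy to the unweighted channel-mean
  intensity: per tile `r = plip_sub(max,min) / plip_add(max,min)` with
  PLIP arithmetic, combined as `(-1/K) * sum r*ln(r)`. The leading minus
  sign follows the convention of the metric's reference implementations,
  making the term non-negative and increasing with local contrast (the
  raw sum `r*ln r` is non-positive and would *penalise* contrast, which
  contradicts both the metric's intent and its published positive scores).
  Degenerate tiles (`max == min`) contribute exactly zero.

Known property worth stating plainly: UISM and UIConM reward high-frequency
energy, so additive noise *raises* UIQM. The metric is used here exactly as
in the field — as a relative selector within one image — not as a perceptual
ground truth.

## Metric-guided dataset construction

`Dyn` is swept over 0.4 to 6.0 in steps of 0.2 (29 values; outside that
range enhancement visibly deteriorates). Each candidate is scored with
UIQM and the per-image argmax is kept; at a tie the smallest `Dyn` wins
(mildest enhancement). Originals form domain A and the selected
enhancements domain B of an *unpaired* dataset: each domain is shuffled by
its own stream derived from one seed and split 80/20 (train size rounded
half-up), and no pairing index is stored. Enhanced frames are written as
PNG regardless of the input codec so JPEG re-compression cannot
contaminate domain B. Images are not resized at build time; resizing to
the training resolution belongs to the GAN data loader. The per-`Dyn`
report gives mean and *population* variance of UIQM across the image set
plus an `original` row and a `best value chosen` row; the best row's mean
necessarily dominates every fixed-`Dyn` row (mean of per-image maxima).
The split is global, not stratified by working condition.

## Synthetic test bed

The generator emulates the documented degradations parametrically:

```
out = clip((1-v) * blur(img * attenuation) * vignette + v * veil + noise)
```

with per-channel transmission factors (red lowest), a veiling color and
strength `v`, a radial (optionally off-centre) vignette, a Gaussian blur
of the attenuated radiance, and seeded additive Gaussian noise. The blur
term carries the visibility loss of turbid water; without it a simulated
"degradation" can *raise* UIQM through the noise-sensitive sharpness term,
which would invert the relationship the real imagery shows. Five presets
(blue cast, green cast, dark off-centre vignette, hazy, noisy low-light)
stand in for distinct camera/lighting working conditions. They are
declared stand-ins chosen to look plausible at 64 px — not radiative
transfer, not calibrated to any particular optics: no Jerlov water types,
no wavelength-dependent path radiance, no bubbles or particulates. Scenes
are compositions of oriented gradients, random rectangles/ellipses and
band-limited texture, stretched to full range per channel. Consequently,
passing tests establish that the pipeline's *mechanics and directions* are
right (degradation lowers UIQM, selection raises it, training descends);
they say nothing quantitative about real cold-seep footage, whose UIQM
distributions depend on unpublished camera and water parameters. One
visible artifact of the gap: on the synthetic textures the sweep's
selected `Dyn` clusters at the low (aggressive) end of the grid, because
hard clipping of band-limited texture maximises the sharpness term; on
real footage mid-range values win and the extremes visibly deteriorate.

## CycleGAN

Generators G (enhance, A→B) and F (degrade, B→A) are
encoder/residual/decoder ResNets; discriminators DM/DN are 3-stage
patch classifiers emitting a score map. The objective is

```
L = L_GAN(G, DN) + L_GAN(F, DM) + lambda * L_cyc(G, F)
L_cyc = E||F(G(m)) - m||_1 + E||G(F(n)) - n||_1
```

minimax over (G, F) vs (DM, DN). Choices:

* **Least-squares adversarial loss** (real target 1, fake target 0, 1/2
  weighting on the discriminator side): the standard stable choice for
  this architecture family; swappable behind `adversarial_losses`.
* **lambda = 10**, the canonical weighting of cycle consistency.
* **"Six-layer ResNet" read as 6 residual blocks** in the generator
  bottleneck (the common architecture), not 6 convolutions; depth is a
  config field either way.
* Decoder upsampling is nearest-neighbour + convolution rather than
  transposed convolution (avoids checkerboard artifacts); padding is
  zero-padding throughout. Instance normalisation without affine
  parameters.
* Identity loss is omitted by default (`identity_weight = 0`) and
  available behind that flag.
* Adam (beta1 0.5), lr 2e-4, linear decay to zero over the second half of
  training; batch 1 at full scale.
* The data loader resizes bilinearly to `image_size` and maps intensities
  to [-1, 1]; the generator's tanh output maps back linearly, and
  inference restores the original resolution.

The networks and their gradients run on a small reverse-mode autodiff
engine written on numpy (im2col convolutions through BLAS matmuls, float32
throughout), gradient-checked against central finite differences in the
test suite. Epoch shuffles derive from `(seed, epoch)`, so runs are
deterministic and a resumed run reproduces an uninterrupted one to
optimizer-state precision.

Two profiles are configured. The full-scale profile (512x512, 6 residual
blocks, 64 base channels, 350 epochs) reproduces the published training
configuration and is GPU-scale. The toy profile (64x64, 2 residual blocks,
16 base channels, batch 2, 30 epochs, 20 images per domain) is the
package's own test-bed scale: it is what the test suite and the acceptance
script run, chosen so a full training fits in a few minutes on one CPU
while still showing the qualitative training behaviour (descending cycle
loss; trained enhance→degrade reconstruction beating a random-initialised
model).

## Numerical conventions

* All image math in float64 until quantisation; quantisation is clip to
  [0, 255] then round half away from zero.
* Ties in the sweep resolve to the first (smallest) grid value via strict
  `argmax` semantics.
* `eps = 1e-7` stabilises log ratios in EME/logAMEE; degenerate tiles and
  channels contribute zero rather than raising.
* One global seed fans out to stage seeds through `SeedSequence`, keeping
  stages independently reproducible; manifests and reports are
  byte-identical across reruns with the same inputs and seed.

## Known limitations

* The UIQM configuration is a choice, and scores are not comparable across
  configurations; no attempt is made to match any externally reported
  UIQM values.
* The degradation model is photometric, not physical; domain gap to real
  turbid-water optics is expected.
* Toy-scale GAN results demonstrate trainability, not enhancement quality;
  video streams and deployment concerns are out of scope.
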