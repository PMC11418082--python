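# Methods

## Problem setting

A low-resolution (LR) fluorescence image `y` is modeled as `y = D(x) + n`,
where `x` is the unknown high-resolution (HR) image, `D` a known, non-invertible
downscaling operator and `n` observation noise. At large upscaling factors
(8x-32x) the inverse problem is massively underdetermined; the package makes it
well-posed by constraining `x` to the range of a pretrained style-based
generator `G` and searching its extended latent space for the maximum a
posteriori (MAP) solution.

## The objective

With `n` assumed Laplace, the negative log-likelihood of the observation is an
L1 data term, and the search solves

```
W+* = argmin_{W+}  || D(G(W+)) - y ||_1 / m
                   + lambda1 * P1(W+) + lambda2 * P2(W+)
```

where `W+ = (w_1 ... w_L)` holds one style vector per synthesis layer and `m`
is the number of LR pixels (the data term is a mean, so the lambdas transfer
across resolutions; the Laplace scale is absorbed into the lambdas, only
their ratios matter).

* `P1(W+) = -(1/L) sum_l log p(w_l)` is the style-density prior. `p` is the
  exact density of a masked autoregressive flow fitted to mapped style
  vectors; the term pulls every copy toward high-density style space, i.e.
  toward images the generator was trained to produce. Averaging over copies
  keeps `lambda1` meaningful for any `L`.
* `P2(W+)` is the mean squared pairwise Euclidean distance between the
  copies (an unsquared variant is available via `pairwise_squared=False`).
  On the trained manifold all copies coincide, so this prior measures how far
  the extended latent strays from plain `W`. Squared distances are used by
  default for smooth gradients.

Writing the image prior on `w` instead of on `G(w)` silently drops the
Jacobian term of the synthesis network; this is exact only for a generator
trained with a path-length penalty that makes the Jacobian determinant
constant. The miniature generator here is not trained at all, so the
assumption is inherited as-is and stated in the API docs.

Defaults follow the study settings: `lambda1 = 5e-5` (validated range
`1e-6..5e-4`), `lambda2 = 0.01` (validated `0.005..0.05`), Adam with 200
iterations at learning rate 0.5, all `L` copies initialized at the mean of
10,000 mapped latents. Configs outside the validated lambda ranges warn but
run. The returned iterate is the best-so-far by total objective rather than
the last one; at learning rate 0.5 the iterates oscillate late in the run and
the best-so-far choice makes the result robust to that.

### Desk-scale optimizer setting

The package's experiments run a miniature generator whose style space has
per-coordinate scale ~0.3, far smaller than a full-size model's. A constant
step of 0.5 in that space oscillates without converging, so every experiment
that needs tight inversion uses `learning_rate=0.2` with cosine decay
(`pipelines.DESK_RLS_CONFIG`); with it, in-range targets are recovered
essentially exactly (median PSNR gain over bicubic ~39 dB, final data term
~3e-4). The robustness sweep instead keeps the constant-0.5 defaults: its
summary statistic is a *ratio* of corrupted-case to clean-case residuals,
which is informative only when the clean-case residual is not already at
numerical precision, and the original robustness protocol is defined at those
settings.

## Generators

`StyleGenerator` is a frozen pair (mapping `F: z -> w`, synthesis
`G: W+ -> image`) with two desk-scale instances:

* `style_mini` — pixel-norm + 3-layer leaky-ReLU mapping MLP (`d=16` at test
  scale), and a synthesis stack of exactly 8 style-modulated, demodulated 3x3
  convolutions with nearest-neighbour upsampling interleaved to reach the
  target resolution from a learned 4x4 constant, a 1x1 to-RGB projection and a
  final tanh bounding the output to [-1, 1]. Weights are drawn once from a
  seed and never trained: the contribution under test is the search, not the
  generator. Two canvas sizes share identical weights given the same seed
  (only the upsample schedule differs), so one flow serves both.
* `linear_oracle` — `G(w) = reshape(A w)` with full-column-rank `A` and
  identity mapping. Linearity gives closed-form least-squares/ridge inverses
  (`closed_form_linear_map`), used as the independent oracle for the
  optimizer. `pipelines.build_image_basis_generator` constructs a linear
  oracle whose columns are an orthonormal basis fitted to rendered cell
  images (uncentered PCA via SVD, columns rescaled to unit coefficient RMS so
  the latent distribution has order-one scale): its range contains
  phenotype-bearing images, which makes end-to-end in-range phenotype
  experiments possible.

All gradients (synthesis, flow, objective) are computed by a small
reverse-mode automatic-differentiation engine over numpy arrays
(`latsr._autodiff`); gradient correctness is pinned against central finite
differences throughout the test suite. Finite-difference checks avoid points
where a leaky-ReLU argument changes sign inside the bracket, where central
differences are invalid.

## Normalizing flow

The style distribution produced by a random leaky-ReLU mapping network is
far from Gaussian (squared norms of `w` average ~1.8 against 16 for a
standard normal at `d=16`, with whitened excess kurtosis up to ~5). The flow
`f: W -> U` Gaussianizes it and supplies the exact prior density through the
change of variables `log p(w) = log N(f(w)) + log |det J_f(w)|`.

Architecture: masked affine autoregressive blocks (MADE-style two-hidden-layer
conditioners, sequential degree assignment) separated by fixed reversal
permutations. Density evaluation is one parallel pass; inversion is
sequential (one conditioner pass per dimension). Conditioner output layers are
zero-initialized, so an untrained flow is exactly the identity (up to the
permutations) — this gives closed-form unit tests and stable early training.

Full-scale defaults mirror the study (5 blocks, hidden 1024, 100k samples);
the desk scale uses 5 blocks x hidden 64 on 20k samples. Heavy tails of the
mapped distribution required explicit tail control, chosen on training-side
validation behaviour:

* `tanh` conditioner activations (extrapolate more conservatively than ReLU),
* a soft clamp of the per-block log-scale at +-3,
* decoupled weight decay (0.05) on conditioner weights,
* per-batch jitter of training samples (0.05 x per-dim std), which smooths
  the target density,
* a calibration stage fitted on a clean 10% held-out slice: a per-dimension
  affine z-score layer followed by a radial quantile-matching layer that maps
  the empirical radius distribution of `f(w)` onto the chi(d) law of a
  standard normal (radial Gaussianization). Both are exact bijections with
  tractable log-determinants — the radial layer contributes
  `log s'(r) + (d-1) log(s(r)/r)` — and both participate in `flow_forward`,
  `flow_inverse`, `log_density` and the gradients consistently.

Training maximizes average log-density with Adam (lr 1e-3, batch 256,
gradient-norm clip 50); a NaN loss aborts with the epoch index. Optional
early stopping on held-out NLL exists but is off by default (it counteracts
the jitter smoothing).

Gaussianization is assessed by the squared-norm diagnostic: `||f(w)||^2`
should be chi-squared with `d` degrees of freedom (mean `d`, variance `2d`).
At desk scale the trained flow lands within 3% of the reference mean and
within ~11% of the reference variance across seeds, against ~89% mean
deviation for untransformed `w`.

## Degradation operators

The canonical forward operator is antialiased bicubic downscaling in a fixed
dialect so the data term is bit-reproducible: Keys kernel with `a = -0.5`
(Catmull-Rom), kernel support stretched by the scale factor, half-sample
symmetric boundary handling, rows normalized to sum to one. Downscaling (and
Gaussian blur) are expressed as constant per-axis factor matrices, which makes
them linear, exactly differentiable, and cheap inside the search loop. Only
power-of-two factors (1..32) are supported. Robustness corruptions — additive
Gaussian noise (clipped to [-1, 1]; clipping can be disabled), salt-and-pepper
replacement (each element to +-1 with equal odds), Gaussian blur (radius
`ceil(3 sigma)`, reflect padding) — are applied to the *downscaled*
observation and carry their own seeds. Stochastic steps model unknown
acquisition noise and are not part of the reconstruction forward model, which
uses the deterministic steps only.

`bicubic_upscale` (same kernel, no antialiasing) is provided purely as the
baseline comparator for PSNR benchmarks.

## Synthetic microscopy

`synthetic_microscopy` renders 3-channel single-cell crops (DNA / reporter /
cell body) with controlled phenotypes so the whole pipeline is testable
without downloads: a jittered nuclear ellipse inside a cell ellipse, soft
edges via light Gaussian smoothing, and a mild low-frequency texture on the
cell body. The translocation assay moves reporter intensity between cytoplasm
and nucleus with fraction `t` (negative control `t=0.1`, positive `t=0.9`);
the Golgi assay places `n_spots` non-overlapping perinuclear discs of radius
`spot_radius` (compact control: 1 disc of radius 5; scattered: 8 discs of
radius 1.5), with bounded placement retries and an explicit error when the
geometry cannot fit. Noise follows the standard camera model — Poisson shot
noise at `photon_scale` (default 200 photons per unit intensity) plus Gaussian
read noise (default 0.01) — and every render is deterministic given its seed.
Exact geometry (masks, spot centers and areas) is returned alongside the image
for feature-extractor tests.

What the simulator does **not** emulate: real stain textures and organelle
substructure, multi-cell fields, illumination gradients, dose-response
continua, or the correlated chromatic structure of real cell-painting data.
Tests passing on these renders show the pipeline's mechanics and sensitivity,
not performance on real microscopy.

## Quantification

* Translocation ratio: nucleus = Otsu threshold of the smoothed DNA channel
  (sigma 1), largest 8-connected component, holes filled; cytoplasm = ring of
  width 4 px around it; value = (mean reporter in nucleus + eps) / (mean in
  ring + eps). Ratios above 1 indicate nuclear accumulation.
* Mean Golgi spot area: reporter channel thresholded at its Otsu level within
  the cell mask (from channel 2); 8-connected components below 2 px discarded;
  value = mean component area (0 with 0 objects for a blank reporter).
* PSNR on [0, 1] images, capped at 100 dB below MSE 1e-10; MS-SSIM with the
  standard 5-scale construction (11x11 Gaussian window, sigma 1.5, weights
  0.0448/0.2856/0.3001/0.2363/0.1333, 2x2 mean-pool between scales), scales
  auto-reduced with renormalized weights for small images, and per-scale terms
  floored at 0 so the score lies in [0, 1] and equals 1 iff inputs are
  identical; channels are averaged.
* Two-condition separation uses a transparent threshold at the midpoint of
  the class medians, scored by balanced accuracy — a deliberately
  interpretable stand-in for a learned classifier.

All segmentation constants (smoothing sigma, ring width, minimum spot area)
are exposed as keyword arguments.

## Uncertainty

Around the MAP latent, K plausible solutions are drawn from an isotropic
Gaussian `N(w_MAP, sigma^2 I)` per W+ copy. The scale `sigma` carries an
inverse-gamma prior (alpha = beta = 1) and is estimated by bounded 1-D MAP:
Laplace log-likelihood of the MAP residual (`-m E / sigma - m log(2 sigma)`,
`E` the MAP data term, `m` the LR pixel count) plus the inverse-gamma
log-prior; no additional scale penalty is added beyond the prior. A zero
residual is degenerate (the likelihood carries no scale information) and
returns the prior mode `beta / (alpha + 1)`. Each sample is optionally
refined by 60 Adam steps on the full objective at a small, cosine-decayed step size (0.02 -> 0) —
large enough to restore data consistency, small enough not to wash out the
sampled perturbation; samples whose data term exceeds 2x the MAP data term
after refinement are flagged, never dropped. With `sigma = 0` the sample set
degenerates to K copies of the MAP image by construction. The per-pixel
standard deviation across the K images summarizes reconstruction uncertainty.

## Experiment scales

Chosen as the package's own desk-scale study conditions: `d = 16` style
space, 64x64 canvas at 8x downscaling for the inversion benchmark (20
fixed-seed in-range targets), 32x32 at 4x for the ablation (20 trials),
robustness (6 targets) and uncertainty experiments, and the two-step assay at
64x64/4x with 100 cells per condition and a 48-dimensional image-basis
generator. The flow trains on 20k mapped latents. The end-to-end CLI
(`latsr e2e`) runs a reduced version of the same workflow.

## Known limitations

* The generator is frozen and random (or a linear image basis): results
  quantify the search machinery, not what a trained StyleGAN can express.
* Pure-numpy gradients make large-scale runs slow; the design favors exact,
  testable numerics over throughput.
* The flow's density is only as good as 20k training samples allow; its tail
  behavior is explicitly regularized rather than learned.
* MS-SSIM values are floored at 0 per scale, so strongly anti-correlated
  images score 0 rather than negative.
* The uncertainty model is a deliberately simple isotropic Gaussian with a
  shared scalar scale; it ignores posterior correlations between latents.
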