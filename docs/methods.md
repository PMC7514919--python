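# Methods

## Model

A grayscale image is a raster `I : D → [0, L]` with level ceiling `L` (1.0
for normalized data, 255/65535 for 8/16-bit). A region of interest is
characterized only by its luminance statistics: a center β and a half-width
α on the image's intensity scale. The enhancement transforms are pointwise
bell-shaped maps into [0, 1] that peak at exactly 1 at `I = β`, are even in
`I − β`, and push everything outside the band `[β − α, β + α]` toward a
background level:

| family              | kernel                                                   | background |
|---------------------|----------------------------------------------------------|------------|
| `sigmoid`           | `2 / (1 + exp(λ d))`, `d = |I − β| / α`                  | 0          |
| `modified_sigmoid`  | `1 / (1 + exp(−λ / d))`, value 1 at `d = 0`              | 1/2        |
| `qsig_low`          | `2 / (1 + exp_q(λ d))`, intended `q < 1`                 | 0          |
| `qsig_high`         | `1 / (1 + exp_q(λ F))`, `F = −1/d`, intended `q > 1`     | 1/2        |

with the deformed exponential `exp_q(x) = [1 + (1 − q) x]^(1/(1−q))`,
cut off to 0 where the base is non-positive. The deformation adds one
shape parameter: for `q < 1` the low family's tail is polynomial rather
than exponential (heavier, hence a wider visible region at fixed α, and
pointwise ≥ the classical sigmoid), monotonically so in q; for `q > 1` the
high family's peak sharpens with q while its tail still settles at 1/2.

The exponent of the modified families is read as `−λ · d⁻¹`: this is the
reading consistent with the printed auxiliary function `F = −1/d`, with the
`d⁻²` factor appearing in its derivative, and with the 1/2 asymptote.

### Calculus

For `I > β` the four closed-form derivatives are implemented as derived
from the kernels (for the low family, `−(2λ/α)(1 + g)⁻² base^{q/(1−q)}`
with `g = base^{1/(1−q)}`, and analogously for the others); the `I < β`
branch is the sign-flipped expression by symmetry. At the peak the sigmoid
and low families have one-sided slope `−λ/(2α)` — independent of q — which
`analytic_derivative` returns by convention (right-side limit). The
modified/high families have no closed form at β (the flat side gives 0, but
the deformed high family's behavior there depends on q, diverging like
`−1/√ΔI` for large q); callers are directed to the forward difference
quotient `D(I, ΔI)` instead. Near-linearity of the low family just right of
the peak is certified by the Taylor ratio
`R(I) = qsig_low(I) / (1 − (λ/2α)(I − β))`, which stays below 1.07 at
`I = β + α/2` across the whole q ∈ (0, 1) grid.

### Numerical choices

* `|q − 1| < 1e−9` dispatches to the classical closed forms, avoiding the
  `1/(1 − q)` blow-up.
* The deformed power is computed as `exp(log(base)/(1 − q))` with underflow
  clamped to 0; overflow saturates harmlessly inside `a/(1 + x)` kernels.
  Logistic factors use `scipy.special.expit` products for stable tails.
* Out-of-intent q ranges are opt-in (`extend_q_range`): the low family with
  `q > 1` maps pixels past the cutoff to 0 (the one-sided limit of the
  expression); the high family with `q < 1` follows the literal cutoff
  (q-exponential 0, output 1). No closed-form derivative is offered there.
* The fractional-logistic comparison function uses the signed power
  `(I − I₀)^b` for (near-)integer b and rejects negative arguments
  otherwise, since the real power is undefined there; only b ∈ {1, 2} is
  exercised by the analyses.

## Synthetic scenes

`gaussian_scene` emulates the controlled test image: a normalized 2-D
Gaussian intensity profile on a 256×256 raster, peak renormalized to
exactly 1 at the pixel nearest the center (175, 175), spread δ = 30 px.
δ is read as a standard deviation in pixels (the variance reading is
available via `delta_is_variance`). The ground truth is the spatial 3δ
disc around the center, clipped at the borders — an intensity interval
around the center value would be meaningless on a [0, 1]-normalized image —
with the intensity-threshold variant `exp(−k²/2)` available for
sensitivity analysis (the two coincide on unclipped rasters).

Noise series use additive zero-mean Gaussian noise with variance
`mean(signal²)/snr` (linear power-ratio SNR, clipped to [0, L]); a series
spanning SNR 0…100 replaces the degenerate 0 endpoint with the smallest
positive value of the series. Speckled-lesion fixtures place a darker
ellipse on a brighter background under unit-mean gamma speckle
(shape = number of looks; 4 by default, a realistic single-image
multi-look level). These fixtures reproduce only the qualitative structure
of ultrasound data — multiplicative granular noise, low lesion contrast,
fuzzy boundaries — not beam physics, attenuation or shadowing; conclusions
from passing tests transfer to real scans only at that qualitative level.
All generators are pure functions of (spec, seed).

## Baselines and metrics

Histogram equalization (scikit-image's CDF mapping, monotone by
construction), percentile gray-level slicing (default window: 2nd–98th
percentile, clamp or reject mode), and Otsu thresholding. Otsu uses a
fixed `[0, L]`-anchored 256-bin histogram with `floor(v/L·(nbins−1))`
binning and lower tie-break, making thresholds bit-exact across 8/16-bit
inputs; it is validated against an exhaustive between-class-variance search
and against scikit-image's implementation (whose data-range binning can
differ by up to a bin width).

Hull areas are shoelace polygon areas of the convex hull of pixel centers
(scipy's ConvexHull; degenerate point sets count as 0), with a pixel-count
variant for sensitivity checks. Err is not clamped: an achieved hull larger
than the truth hull goes negative, which honestly records overshoot. The
similarity index averages the Jaccard overlap with the fraction of the
truth's one-pixel outer ring (3×3 dilation minus the truth) not touched by
the segmentation; it is undefined for an empty truth or a truth filling the
raster.

## The achieved-region rule

The sweep experiments need a rule mapping a transformed image to its
"achieved region", and the choice is genuinely open. Two conventions are
shipped:

* **midpoint** — threshold halfway between the family's background and the
  peak (0.5 for dark-background families, 0.75 for mid-gray ones). Natural
  for a single image, and the default of `extract_region`. But it cannot
  rank the q > 1 family above the classical sigmoid in the phantom sweep:
  at any fixed threshold t the high family's level-set half-width is
  `αλ(q − 1)/((t/(1−t))^{q−1} − 1)`, strictly decreasing in q, so its
  region (and hull) can only shrink as q grows.
* **display** (experiment default) — the region *visibly brighter than
  background on an 8-bit rendering*: pixels whose rounded 8-bit level
  exceeds the background's rendered level (level ≥ 1 for dark-background
  families, ≥ 129 for mid-gray ones), then the largest 8-connected
  component. This matches how achieved regions are captured from rendered
  output images, and under it the sweep's qualitative orderings all hold
  and are structurally stable: Err is non-increasing in α and
  non-decreasing in q ≤ 1 because the thresholded regions are *nested
  pointwise* (the kernels are monotone in α and in q at fixed threshold),
  and the q > 1 family — whose entire output sits above mid-gray — always
  covers at least the classical sigmoid's visible region.

Every experiment records the rule in its provenance, and both conventions
remain available to callers.

## Experiment protocol and problem sizes

The Err sweep fixes β = 1.0, λ = 1.0 on the default phantom and scans
α ∈ {0.01, 0.015, 0.02, 0.025, 0.03} × q ∈ {0.7 … 1.0} ∪ {1.001, 1.1, 1.2},
dispatching the low family for q < 1, the classical sigmoid at q = 1 and
the high family for q > 1. The AMBE batch applies eight method instances
(equalization, slicing, and q-sigmoids at β = 0.15, α = 0.01, λ = 1 for
q ∈ {0.1, 0.5, 0.999, 1.0, 1.1, 2.0}) to a generated lesion corpus; the
default test corpus is 20 fixtures of 128², a size at which the per-method
mean and spread are already stable. The noisy-series study runs the
segmenter (Otsu by default; any mask-producing callable can stand in for a
learned model) on each image with and without q-sigmoid preprocessing and
scores both against the truth disc; note that on the clean phantom a broad
q-sigmoid is a monotone intensity remap, so it shifts Otsu's operating
point rather than enabling a qualitatively better segmentation — the
benefit the similarity index is designed to detect concerns segmenters
sensitive to absolute contrast.

## Known limitations

* The printed reference Err tables for this protocol are not exactly
  reproducible — the original achieved-region rule is unstated and the
  tables disagree internally — so the sweep asserts orderings, not values.
* The display rule depends on the 8-bit rendering convention; other bit
  depths shift the visibility threshold.
* Speckle fixtures are statistical stand-ins; no claim is made about
  enhancement quality on real ultrasound beyond the qualitative trends.
* The similarity study replaces learned segmenters with thresholding, so
  it exercises the metric and the pipeline, not the learning behavior.
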