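# Methods

This note records the model, its assumptions, the parameters that
matter, and the places where the design was genuinely open and a choice
had to be made.

## The anomaly-detection model

The premise: tumor tissue is an anomaly relative to normal tissue. A
generative model trained exclusively on normal tissue learns to
reconstruct normal texture well; whatever it reconstructs poorly is
flagged. No tumor annotations enter training at any point — the only
supervised ingredient is the evaluation itself.

**Reconstruction.** The generator is a convolutional encoder–decoder
trained as a context encoder: a centered square covering fraction
`f = 0.5` of the patch side is filled with the training-set mean color,
and the network must restore it. At inference the reconstruction is
composited — unmasked pixels are copied from the input verbatim, masked
pixels come from the generator — so reconstruction error outside the
mask is exactly zero for the copied region and the error signal
concentrates where the model had to hallucinate. A config flag restricts
the downstream error computation to the masked region only; the default
uses the whole patch.

**Progressive growth.** Training starts at 4×4 and doubles resolution
per stage. Each stage has a fade-in sub-phase in which the new
resolution's contribution is blended in with weight α ramping linearly
from 0 to 1 over the images seen, followed by a stabilization sub-phase
at α = 1. The growth rule is constructed so that at α = 0 the grown
generator output equals the previous generator's output upsampled by
nearest neighbor, and the grown discriminator equals the previous one
applied to the average-pooled input — growth is exactly
behavior-preserving at the moment it happens (tested to 1e-5 in
float32). Channel widths halve as resolution grows (32 at 4–8 px,
down to 4 minimum).

**Loss.** `lambda_rec * L1 + lambda_adv * LSGAN`, defaults 1.0 and
0.05. L1 is chosen because the downstream statistic is the absolute
error; least-squares GAN because it is stable at very small scale.
Setting `lambda_adv = 0` gives a pure context encoder, which is often
the right call for the tiny desk-scale runs the built-in NumPy autodiff
engine is meant for. The engine is plain float32 NumPy (im2col
convolutions, Adam), single-threaded and deterministic given the seed;
it is not a GPU framework and resolutions above 64 px are not practical
with it.

**Normal error reference distribution (NERD).** Per-pixel absolute
errors are 3-vectors over RGB. All pixels of all Phase-2 patches are
pooled into one 3-variate Gaussian — a per-pixel-position model is not
meaningful because patches are not spatially registered. Moments are
accumulated streaming (sums and outer-product sums), exactly equivalent
to a batch fit and order-invariant; covariance uses the n−1 denominator
and is regularized by `epsilon = 1e-6` on the diagonal before
inversion.

**Thresholding.** The anomaly score is the Mahalanobis distance of the
error vector from the NERD. The cut-off τ is the nearest-rank
(1−q)-quantile of scores pooled over Phase-3 normal slides; `q` (default
0.05) is the accepted false-flag rate on normal pixels and is the single
most consequential tuning parameter of the pipeline. A pixel is
anomalous iff `d > τ` (strict). Under an exact Gaussian error model, d²
is χ²₃ and τ(q=0.05) ≈ √7.815 ≈ 2.796; in practice absolute errors are
folded (non-negative), the tail is slightly heavier, and the empirical
quantile lands somewhat above the closed form — which is why calibration
is empirical rather than parametric.

## Pipeline conventions

- Coordinates are level-0 pixels, 0-based, x = column; patch extents are
  half-open `[x, x+s)×[y, y+s)`.
- Otsu's threshold is computed on the 8-bit Rec.601 luminance of a
  thumbnail (default downsample 32). The returned threshold T is the
  *lower edge of the upper class* (candidates T ∈ 1..255, classes
  `{v < T}` / `{v ≥ T}`, ties → smallest T), so the tissue test
  `luminance < T` selects exactly the dark class; with the
  last-bin-of-lower-class convention a two-spike histogram would exclude
  the tissue value itself.
- Pyramid levels are successive 2×2 area means (the mirror of the
  discriminator's average pooling); nearest-neighbor is available for
  ablation. The full power-of-two ladder is emitted because every
  doubling step is trained.
- Tiling is a non-overlapping grid anchored at (0,0);
  `min_tissue_fraction = 0.5` by default. The tissue fraction of a grid
  cell is computed exactly from the thumbnail mask footprint (matches a
  per-pixel count).
- Polygonization uses 4-connected components and pixel-boundary tracing
  (union of per-row pixel runs), not marching squares: polygon area
  equals the member-pixel count exactly, making the confusion matrix an
  integer computation. Defaults: `min_area = 256 px²` at level 0,
  `closing_radius = 0`.
- When the reconstructor works below the tiling patch size, masks are
  computed at model resolution and polygons scaled to level-0 by the
  size ratio (the area floor is rescaled accordingly).
- Rasterization for evaluation uses pixel-center inclusion with a 1e-9
  lower-left nudge so adjacent polygons never double-count a center on a
  shared edge. The default evaluation region is the tissue bounding box:
  counting TN over a whole slide's whitespace inflates specificity.
  Both conventions are available and recorded in the report.
- 0/0 metrics (e.g. sensitivity on a slide without annotated tumor) are
  reported as an explicit undefined marker and excluded from cohort
  means with a warning, never silently coerced to 0 or 1.

## The synthetic world

The generator emulates what the pipeline's math needs from a slide, not
histology: a bright whitespace background (luminance 245), an elliptical
"tissue" region textured as a correlated Gaussian random field
(correlation length 4 px, noise SD 0.03 per channel, ~50% of the
variance shared across channels) around an H&E-like pink base color
(0.80, 0.58, 0.72), planted anomaly discs whose mean color is shifted by
L2 magnitude 0.3 toward a blue-purple tone with 1.5× noise, and optional
green ink strokes reproducing the classic false-positive artifact.
Truth polygons are the planted geometries. Everything is deterministic
per seed, including file bytes.

The oracle reconstructor stands in for a trained GAN: bright pixels pass
through; tissue pixels are reconstructed as the base color plus 0.3
times the Gaussian-smoothed (σ = 2 px) deviation from it. Normal
texture therefore reconstructs with error ≈ the noise SD, while a
color-shifted anomaly retains ≈ 70% of its shift as error — the same
qualitative error geometry a trained model produces, with none of the
training cost. A green end-to-end test on this world establishes that
the calibration, thresholding, polygonization and scoring machinery is
correct; it does not establish segmentation quality on real tissue,
where texture is non-stationary, stain varies, and anomalies are not
clean color shifts.

Cohort phase assignment mirrors the three-phase design: normals are
apportioned to Phases 1/2/3 by largest remainder over ratios
(0.71, 0.14, 0.14) — which reproduces a 100/20/20 split of 140 normal
slides — with a floor of one slide per phase for tiny cohorts; tumor
slides all go to inference.

## Known limitations

- A pixel-level detector calibrated to flag q of normal pixels cannot
  give a zero-false-positive *slide-level* presence call by itself: on
  spatially correlated normal texture the flagged pixels cluster, and
  the cluster-size tail occasionally crosses the minimum polygon area
  (measured here: the largest normal-slide noise component is 200–330
  px² against the 256 px² floor, so roughly one normal slide in three
  draws a single small false polygon). A principled fix is a slide-level
  presence floor calibrated on held-out normal slides, analogous to τ;
  the presence rule's `min_area` parameter is surfaced for exactly this
  purpose but the package default remains "any nonempty prediction".
- The NumPy training path is desk-scale only; the architecture supports
  the full 4→1024 ladder but nothing here makes 1024² training
  practical.
- Ink and other non-tumor anomalies are detected as anomalies by
  construction; no ink-removal preprocessing is included.
- Stain normalization, overlapping tiling and mixture models for the
  error distribution are out of scope.
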