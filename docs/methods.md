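# Methods

## Problem setting

In a location-unknown search task an observer scans an image for a target
(here: a spiculated mass in a tomosynthesis-like breast image) without
knowing where — or whether — it is present. Visual-search model observers
split the task into a *search stage*, proposing fixation candidates, and a
*decision stage*, scoring them. `fixsearch` implements only the search
stage, in three variants that fuse second-order texture statistics with a
multiscale Gabor bank, plus the evaluation utilities needed to compare
their outputs with each other and with recorded gaze points.

## Texture features

For an integer-quantized patch, the co-occurrence matrix at offsets δ is
`P(i, j | δ) = N(i, j | δ) / Σ N`, with counts pooled over the listed
offsets and **directional** (each δ counted once; pass δ and −δ for
symmetric counts). The two derived statistics are the GLCM mean
`Σ i·P(i, j)` and GLCM contrast `Σ (i−j)²·P(i, j)`.

Choices the formulas leave open, and how this package resolves them:

* **Quantization** (default `per_image`): global min–max of the image is
  split into G equal bins, top edge inclusive; a constant image maps to
  level 0. A shared gray scale across patches is what makes the GLCM mean
  comparable between patches — the texture-first pipeline's clustering
  assumes it. `per_patch` and fixed ranges are available.
* **Offsets** (default: unit displacements at 0°, 45°, 90°, 135°, pooled
  into one matrix): standard orientation-pooled practice; reduces
  anisotropy artifacts of any single direction.
* **Lattice** (default window 100 px, stride = window): tiled patches;
  partial border patches are dropped so all cells share the same patch
  area. `texture_at_locations` instead clamps a centered window to the
  image bounds, so border candidates still receive features.

## Gabor bank

Each channel is `exp(−4 ln2 r²/Ws²) · cos(2π f_c (x cosθ + y sinθ) + φ)`;
the `4 ln2` factor makes `Ws` the full width at half maximum of the
isotropic envelope (the envelope is exactly 0.5 at radius Ws/2, a property
tested numerically). Responses are computed in the template-matching
(cross-correlation) sense: the response at a pixel is the dot product of
the kernel with the image window centered there. One consequence worth
stating explicitly: an impulse input reproduces the kernel itself only for
even (φ = 0) channels; for odd phases it yields the point-reflected
kernel, which is exactly how correlation differs observably from
convolution. Borders are handled by reflect padding (avoiding spurious
edge maxima); the correlation itself is evaluated by FFT, which is
numerically equivalent to the direct dot product to ~1e−12 relative.

The default bank for a target of radius r pixels has four octave-spaced
frequencies `f_c ∈ {1/(8r), 1/(4r), 1/(2r), 1/r}` with envelope
`Ws = min(1/f_c, r)` and θ = φ = 0. Tying Ws to the wavelength gives one
cycle per FWHM where possible; the cap at r keeps every kernel
(size 2·⌈2Ws⌉+1 ≤ 4r+1 px) smaller than any image a target of that size
can plausibly occupy, and turns the two coarsest channels into blob
detectors matched to the target scale — appropriate for a roughly
isotropic mass, which is also why orientation is left at 0 by default.
Kernels are truncated at support ⌈2Ws⌉, where the envelope has fallen to
2⁻¹⁶ of its peak. The bank is fully user-overridable (YAML config), since
no canonical channel parameterization exists for this task.

## Candidate selection

* **Reversed watershed:** flood the negated map into catchment basins
  (8-connectivity, no pre-smoothing) and emit each basin's argmax of the
  original map. On maps with all-distinct values this equals the set of
  8-neighbourhood regional maxima — the correctness anchor both finders
  are tested against, exactly, on random maps.
* **Regional maxima:** 8-connected, plateau-aware; a plateau emits its
  rounded centroid, and a plateau covering the whole map emits nothing
  (constant maps yield an empty set — a warning, not an error).
* **Merging:** per-channel maxima are unioned and deduplicated greedily,
  strongest producing-channel response first, with ties broken by
  location; default dedupe radius is half the target radius (two
  candidates within half a lesion radius are perceptually one fixation).
  Each survivor carries the responses of *all* channels at its pixel.
* **Thresholding:** the comparator keeps candidates whose strongest
  channel response reaches a quantile (default 0.75) of that statistic
  over the set — a quantile rather than an absolute threshold because
  responses are scale-dependent. Survivor sets are nested across
  increasing quantiles by construction.

## Mixture clustering

Features are z-scored per dimension before EM — the GLCM mean lives in
[0, G−1] and the contrast in [0, (G−1)²], and EM on raw scales collapses
onto the high-variance axis. Fits use full covariances (dimension is only
2 or 6), five seeded restarts keeping the best log-likelihood, a 1e−6
diagonal regularization floor (singular covariances are regularized, never
fatal), and a 1e−6 relative log-likelihood tolerance capped at 500
iterations; a fit is deterministic given data and seed. A diagnostic
single-run trace (`em_loglik_trace`) exposes the per-iteration
log-likelihood, which is asserted non-decreasing in the tests.

The texture-first pipeline uses K = 5 (one component absorbing the
background); the Gabor-first pipeline defaults to K = 3, configurable,
with a documented fallback to K = min(K, n) when candidates are few.
"Which cluster contains the lesion" is resolved two ways: **oracle** mode
takes the label of the point nearest a known lesion center (reproducing
ground-truth-based evaluation), and **heuristic** mode — this package's
extension for prospective use — declares the most populous cluster
background and picks the remaining cluster with the highest mean along
the GLCM-mean dimension. The two agree on most high-contrast-lesion
phantoms (tested ≥ 80% of seeds).

## Synthetic phantoms

The generator produces clustered lumpy backgrounds: a Poisson number of
cluster centers uniform over the image, each spawning a Poisson(5) number
of Gaussian blobs (σ jittered around 10 px, amplitude jittered around 1)
scattered around the center, plus white Gaussian noise (σ = 0.05). Three
density regimes scale cluster density and blob amplitude
(fatty 0.6/0.8×, scattered 1/1×, heterogeneous 1.6/1.3×), which enforces
strictly increasing spatial variance across regimes for matched seeds.
Pixel pitch defaults to 0.1 mm/px, so the default 10 mm mass radius is
100 px. The mass is purely additive: a hemispheric core taper
`contrast·√(1−(d/r)²)` (mean uplift 2/3 of peak contrast inside the core)
combined by pointwise maximum with 8 linear-ramp spicules at jittered
equal angles, tapering to zero at 1.5 r. All generation is bit-exact under
its seed.

What this emulates — and does not: the phantoms reproduce the patch-scale
texture heterogeneity that GLCM features respond to and a dominant
bright target for the Gabor bank, which is what the pipelines' logic
consumes. They contain no anatomical ductal structure, no
reconstruction artifacts, no detector noise correlations, and the lumpy
texture is stationary apart from cluster granularity. Passing hit-rate
tests therefore demonstrate that the pipelines correctly localize a
target dominating a textured background at the stated contrast — not
clinical-image performance.

## Evaluation utilities and problem sizes

The end-to-end checks run 50 seeded 600×600 phantoms (mass contrast 5×
the background RMS, oracle cluster mode) and require a final candidate
within one lesion radius of truth in ≥ 90% of runs for each fusion
pipeline and ≥ 80% for the threshold comparator; the acceptance script
reports the same hit rates on 20 phantoms, a size chosen so a full
reproduction completes in minutes on one core while keeping the binomial
resolution (5 percentage points) adequate for the ≥ 80–90% claims.

`feature_correlation` reports Pearson r between the GLCM mean and each
channel's response magnitude (absolute value: the sign of an even filter's
response is contrast polarity, not salience), per candidate by default
(per-patch pooling is the alternative pairing). On lesion-free lumpy
phantoms the coarse-channel correlation is strongly positive — the full
correlation report is produced rather than a single headline number,
since the channel and pairing behind any single coefficient are a free
choice. `gaze_overlap` scores (row, col)-converted gaze tables by the
fraction within a radius of any candidate plus the mean
nearest-candidate distance; an optional first-T-ms cut restricts to
early-stage gaze. No fixation-sequence or decision-stage modeling is
attempted.

## Known limitations

* The heuristic cluster selector assumes the lesion-bearing cluster has
  an elevated GLCM mean; low-contrast or fatty-masked lesions can violate
  this.
* The default bank is isotropic in orientation; strongly oriented targets
  would need θ-varied channels (supported via config, not defaulted).
* Candidate locations are pixel-resolution; no sub-pixel refinement.
* Texture patches are 100 px tiles, so pipeline A's mask has patch
  granularity — a candidate a few pixels outside the lesion's patch can
  be screened out even when the lesion is detected by the Gabor stage.
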