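# Methods

## Problem and pipeline

A non-neoplastic cervical squamous cell nucleus shows chromatin as
alternating dark and bright regions. "How dark counts as chromatin" is
observer-dependent, so the pipeline segments at five *sensitivity
levels* — five successively looser intensity thresholds — and
quantifies the detected regions at each level. The stages are: crop →
grayscale → contrast stretch → fuzzy C-means intensity clustering →
five-level thresholding with overlap resolution → region/image/cohort
features → cross-level statistics → model construction.

## Pre-processing

* Centered square crop (default off; 500 px is the conventional crop
  size for 100× oil-immersion captures, not a requirement — any input
  size is accepted). Odd remainders floor the top-left offset.
* RGB → gray with ITU-R BT.601 weights (0.299, 0.587, 0.114), rounded
  half away from zero. The most common imaging default; already-gray
  input passes through unchanged.
* Linear contrast stretch mapping the observed min → 0 and max → 255.
  Strict min/max by default, because the method's definition of the
  stretch is "occupy the entire dynamic range"; percentile clipping is
  available as a config knob (`low_percentile` / `high_percentile`)
  for data with hot pixels, default off. A constant image is returned
  unchanged (the documented degenerate case). The stretch is idempotent
  and order-preserving.

## Fuzzy C-means on the intensity histogram

The objective is the classic fuzzified within-cluster sum of squares
W_m with the membership-normalisation constraint; memberships and
centroids alternate through the standard update equations until the
objective improves by less than `tol`. Defaults: m = 2.0,
max_iter = 100, tol = 1e−5.

Design choices:

* **Histogram weighting.** Clustering is 1-D (intensity only), so each
  distinct intensity is one datum weighted by its pixel count. This is
  algebraically identical to per-pixel FCM — the objective and both
  updates depend on the data only through the intensity multiset — and
  the test-suite proves the equivalence against an independently
  written per-pixel implementation (centroids agree to 1e−6, objective
  traces match iteration by iteration). It keeps the cost at
  O(256·c) per iteration regardless of image size.
* **Cluster count rule.** c is the intensity *value* at the histogram
  peak of the (stretched) nucleus image, the literal reading of the
  peak rule; ties take the lowest intensity. It is clamped to
  [c_min, c_max] = [6, 255]: the lower clamp guarantees at least five
  distinct thresholds downstream. Since the stretched background peak
  is typically bright, c can run into the hundreds; images with fewer
  distinct intensities than c reduce c to that number (flagged in the
  result). A fixed cluster count is available as
  `cluster_strategy="fixed"` — used, e.g., when the tier structure of
  an image is known by construction.
* **Deterministic initialisation.** Centroids start evenly spaced
  between the observed min and max intensity. The method itself does
  not pin down an initialisation; a deterministic one makes every
  result bit-reproducible.
* **Exact coincidence.** A datum equal to a centroid gets crisp
  membership, split equally among coinciding centroids (the membership
  update is otherwise singular there).
* Convergence is declared on |ΔW_m| < tol; the trace of W_m is exposed
  and asserted non-increasing.

The labelled image replaces every pixel by the rounded centroid of its
maximum-membership cluster (ties toward the lower centroid, i.e. the
darker class).

## Sensitivity levels and overlap resolution

The five lowest distinct intensities of the labelled image are the
thresholds t₁ < … < t₅; fewer than five distinct values is a
configuration error naming the cluster count. Masks are cumulative
level sets (≤ t_k), hence nested — picture the intensity surface as a
mountain whose contour lines sink with k.

Components are 8-connected (the usual choice for small blob detection;
configurable). `min_area_px` defaults to 1 (no size filter).

The overlap rule: level 1 keeps all components of the strictest mask.
At level k ≥ 2, a component sharing *any* pixel with previously
accepted regions is discarded and those regions are preserved
unchanged; untouched components join with `birth_level = k`. This makes
region sets nested across levels, pairwise disjoint within a level, and
it damps the growth of total area with k (the darker cores' boundaries
win over the merged blob). Whether the non-overlapping remainder of a
discarded component should survive is genuinely open; the default
discards the whole component, and `keep_residual=True` relabels and
keeps the remainder — both behaviours are tested.

## Features

* **Area**: pixel count per region; per-image total A and mean A/n;
  cohort mean as the pooled ratio ΣA/Σn (ratio of totals — *not* the
  mean of per-image means; the two differ whenever region counts vary,
  and the pooled form is the defined estimator).
* **Nearest-pair distance**: Euclidean distance between region
  centroids; per region the minimum over *other* regions (the
  self-distance of zero is excluded as meaningless); per image the mean
  of these minima, undefined (NaN) when n < 2; cohort mean over the
  images where it is defined. Undefined values propagate as NaN and are
  counted, never coerced to zero.
* **Eccentricity**: from the region's second central moments, the
  eccentricity sqrt(1 − λ₂/λ₁) of the ellipse with the same moments —
  0 for a circle, → 1 for a line. Pixels are treated as unit squares
  (1/12 added to the axial moments), so single-pixel and one-pixel-wide
  regions stay strictly inside [0, 1). A verbal definition as the
  major/minor axis-length *ratio* (≥ 1) circulates for this feature,
  but only the moment eccentricity is consistent with values like 0.47
  and with "closer to zero = rounder"; the ratio is still exposed as
  `axis_ratio_from_pixels` for anyone who wants the literal quantity.
* **Unit conversion**: lengths scale by `pixel_size_um`, areas by its
  square. Default 0.032 μm/px, the value implied by the published
  distance pair (15.88 px ≡ 0.508 μm). The published area pair implies
  a different calibration (≈ 0.0506 μm/px); because the two conflict,
  `build_model` accepts a separate optional area calibration and makes
  no guess about which is the acquisition truth.

## Cross-level statistics

Per-image mean area and mean nearest-pair distance form N×K block
tables (images × levels). Rows with undefined entries are dropped
listwise and counted.

* **Friedman test** with within-row mid-ranks and the tie-corrected
  χ² statistic, K−1 degrees of freedom. All-constant rows give
  statistic 0, p = 1. Against an exchangeable null with N = 150 the
  empirical size at α = 0.05 sits within Monte-Carlo error of nominal;
  the χ² tail is an approximation, good to a few hundredths at N = 10.
* **Post hoc**: for each of the K(K−1)/2 pairs,
  z = (R̄_i − R̄_j)/√(K(K+1)/(6N)) with two-sided normal p — the
  standard Friedman mean-rank comparison; the exact pairwise statistic
  used in prior work is not documented, so this choice is recorded in
  the output metadata. Adjustments:
  * **Holm**: step-down with divisors m, m−1, …, 1.
  * **Shaffer (static)**: step-down where the divisor at step i is the
    largest number of pairwise hypotheses that can simultaneously be
    true after i−1 rejections. Equality among levels is transitive, so
    the achievable counts are Σ C(g, 2) over partitions of the K
    levels; for K = 5 the divisor sequence is
    (10, 6, 6, 6, 6, 4, 4, 3, 2, 1). Shaffer never exceeds Holm's
    divisor, so it rejects a superset.
  * Adjusted p-values are running maxima along the sorted raw-p order,
    clipped at 1; significance at α = 0.05 by default.

## Chromatin model

`build_model` condenses a cohort summary at one level into: region
count per nucleus (cohort average, rounded), per-nucleus total area,
pooled mean area, mean nearest-pair distance, mean eccentricity, in px
and μm. `render_model` draws the model: n elliptical spots of the mean
area and eccentricity (small spread, random orientation), dark on a
bright background, on a hexagonal layout with lattice spacing equal to
the target nearest-neighbour distance, jittered and then rescaled about
the canvas centre so the realised site-level mean NN distance equals
the target. Spots are forbidden to touch (8-connectivity), so the
ground truth count is exact. Rendering is bit-deterministic given the
seed, and infeasible packings raise with the reason. "Evenly
distributed" is realised as the jittered hexagonal layout; the
rendering could equally sample areas/distances from wider
distributions, but fixed means with small jitter is the implemented
reading.

## Synthetic data generator

`chromaquant.synthesis` generates the study conditions used throughout
the tests and the acceptance script. One image = a uniform bright
background (intensity 200) carrying rasterized filled ellipses in up to
five intensity tiers (darkest first), placed on the jittered, rescaled
hexagonal layout described above with rejection of touching spots.
Ground truth records every spot's pixels, area, centroid, eccentricity
and tier. Options: radial background gradient, Gaussian noise, and
"halos" — a lighter blob of the next tier wrapped around a darker core,
which exercises the overlap-resolution rule (the halo's component
contains the core, so the core must be preserved and the halo blob
discarded).

The `table4_preset` cohort emulates the published non-neoplastic
chromatin model at sensitivity level 4: 67 spots across tiers 1–4
(17/17/17/16) plus 8 tier-5 spots per nucleus on a 500×500 canvas;
per-tier mean areas on a decreasing ramp (1.3 : 1.1 : 0.9 : 0.7 : 0.6)
scaled so the pooled level-4 mean is 63.44 px (per-spot SD 8 px);
lattice spacing 15.88 px; eccentricity 0.47 ± 0.10. The decreasing area
ramp reproduces the observed trend that mean region area falls as the
sensitivity level rises.

The preset is noise-free: tiers are piecewise-constant, i.e. the
generator emulates the *stain structure the clustering is meant to
recover*, not raw camera noise. That is deliberate — it gives every
downstream measurement an exact ground truth, and it lets the default
literal histogram-peak cluster rule run unmodified (the peak at the
bright background requests c = 255, which collapses to the six distinct
intensities present). What passing tests therefore demonstrate is that
the pipeline machinery (clustering, thresholds, overlap rule, features,
statistics) is correct under the assumed image model; they do not
demonstrate robustness to the blur, shading and sensor noise of real
micrographs, where the behaviour of the literal peak rule depends on
details (its published elaboration is in supplementary material not
reproduced here) and a fixed cluster count or percentile clipping may
be the more robust configuration.

## Problem sizes and numerical choices

* Synthetic cohorts: 150 images of 500×500 px for the headline
  acceptance run (≈ 10 s on one CPU); smaller canvases (96–200 px) for
  the property suites.
* FCM tolerance 1e−5 on the objective; membership row sums asserted to
  1e−9; histogram-weighted vs per-pixel equivalence to 1e−6.
* Friedman null simulation: 1,000 replicates at N = 150, K = 5; size
  within 2 SE of α.
* Model round trip: rendering re-segmented with a fixed two-cluster
  fit at level 1 (the render is two-tone); recovery within 15% over 10
  seeds, typically within 2%.
* Ties: histogram-peak ties take the lowest intensity; membership ties
  take the darker centroid; rank ties use mid-ranks.

## Known limitations

* The literal histogram-peak cluster rule is faithful to its one-line
  description but its refinement lives in unpublished supplementary
  material; on noisy real images the literal rule approaches per-
  intensity clustering and the five thresholds then select only the
  darkest few intensity values. The strategy switch (`fixed` count) is
  the practical alternative.
* The published μm calibrations for length and area are mutually
  inconsistent; pixel-space quantities are the reliable ones.
* No nucleus localisation: the whole crop is segmented, as in the
  original protocol where a pathologist crops manually.
* Eccentricity of very small regions (≲ 10 px) is noisy at the ±0.1
  level; cohort means are accurate but per-region values should not be
  over-read.
* The post hoc z statistic assumes full exchangeability for its
  variance; for a single shared-distribution pair among otherwise
  well-separated levels it is conservative.
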