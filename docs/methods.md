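# Methods

## Morphometric model

An alveolus in a 2-D optical section is represented by two simple closed
polygons in physical micrometres: the outer wall border and the inner
(lumen) border. Coordinates follow the image convention (x right, y down,
origin at the image's top-left corner, 0-based pixel indexing); pixel-space
traces are converted with a micrometre-per-pixel calibration whose default,
0.20839 µm/px, matches high-resolution confocal acquisition of single
alveoli at 1024 × 1024 px (a ~213 µm field of view).

Three per-alveolus readouts are computed:

* wall thickness `T = 100 (A_out − A_in)/A_out` in % of the total alveolar
  surface area, where areas are shoelace areas of the traced polygons. The
  normalisation is by the *outer* area, so T is the fraction of the alveolar
  cross-section occupied by wall.
* circularity `C = min(1, 4π A_in / P_in²)` of the inner border, with the
  perimeter as the sum of edge lengths including the closing edge. The cap
  at 1.0 absorbs the (positive only in pathological cases) discretisation
  overshoot of near-circular dense traces; for a regular n-gon the value
  approaches 1 from below as n grows.
* morphological quotient `MQ = C/(T/100)`. The denominator is the thickness
  *fraction*, not the percentage: with baseline values C ≈ 0.86 and
  T ≈ 27 %, this puts MQ near 3.2 — the scale on which published baseline
  means sit — whereas dividing by the raw percentage would shift the scale
  by ×100. MQ is computed per alveolus and only then averaged; a
  ratio-of-group-means is deliberately not used (it differs from the mean
  per-alveolus MQ whenever thickness varies).

All three metrics are invariant to translation, rotation and uniform
scaling. Validation rejects (never repairs) traces with fewer than three
vertices, self-intersections or zero area — via shapely's validity
predicates — and alveolus pairs whose inner border is not contained in the
outer.

## Synthetic data generator

The generator emulates the *measured objects* of an alveolar imaging study,
not the raw optics. An alveolar outline is a star-convex radial-harmonic
curve `r(θ) = R (1 + Σ_k a_k cos(kθ + φ_k))`; such curves cannot
self-intersect while `r > 0`, which is enforced by capping `Σ|a_k|` at 0.9
(excess amplitude is damped and logged). Circularity is controlled through a
single roughness amplitude distributed over harmonics k = 2, 6, 12, 20 with
fixed weights (1, 0.8, 0.6, 0.5); the mix spans circularity from 1.0 down to
≈ 0.15, covering severely crumpled injured lumens. The amplitude for a
target circularity is found by bisection against the geometry module itself,
using the same harmonic phases the emitted outline will use, so realised
circularity matches its target to 1e-4.

The inner border is the outer curve scaled radially about its centre by
`s = √(1 − T/100)`. Areas of similar polygons scale exactly as s², so the
realised wall-thickness percentage equals the target to machine precision —
no iterative calibration is needed. Ground truth for every emitted trace is
computed by running the measurement code on the emitted polygons, making
generator truth and measurement identical by construction.

Cohorts are hierarchical: animal-level means are drawn around condition
means, per-alveolus values around animal means, everything reproducible from
one seed. Default condition parameters are the published animal-level group
statistics for healthy vs gastric-aspiration-injured porcine lung — wall
thickness 26.86 ± 0.4998 vs 50.55 ± 4.468 %, circularity 0.8783 ± 0.01965 vs
0.4133 ± 0.04366 (mean ± SD across animals), 5 animals per condition and 10
alveoli per animal. Within-animal SDs are not published anywhere; they were
fixed once at 3 %/8 % (thickness, baseline/injury) and 0.05/0.10
(circularity) as spreads consistent with per-animal box plots showing larger
variability under injury. Per-alveolus draws are clipped to physically
meaningful ranges (thickness 2–98 %, circularity 0.15–0.995). The default
alveolar radius is 50 µm, sized so one alveolus fills most of the default
field of view, as in single-alveolus acquisitions of porcine lung.
`sample_animal_means` exposes the generator's animal-level statistical layer
directly (animal mean + within-animal SE) for Monte-Carlo studies that do
not need polygons.

Rendering fills the band between the two borders at a wall intensity (200)
over background (20), applies Gaussian optical blur (σ 0.3 µm), adds
Gaussian noise (SD 8 grey levels) and quantises to 8-bit — a deliberately
minimal emulation of a fluorescently labelled wall. What it does *not*
emulate: nuclei or second channels, uneven staining, out-of-focus light,
neighbouring structures (bronchioles, ducts), or the tracing behaviour of a
human annotator. Passing round-trip tests therefore demonstrates that the
computational pipeline is unbiased and noise-robust under this image model,
not that segmentation of real confocal data is solved.

Cumulative injury scores are emulated as `round(intercept + slope·MQ +
noise)` on an integer grid 0–15 (five scored histological features at 0–3
each — feature ranges are a free parameter since published scales vary).
Defaults slope −3.5, intercept 13, noise SD 0.3 give healthy animals scores
near 1–2 and injured animals near 9–10 with a strong negative MQ–score
correlation, matching the direction and strength reported when blinded
scoring and morphometry agree.

## Segmentation

The automated tracing route is classical: Gaussian pre-smoothing (default
σ 0.25 µm), Otsu thresholding refined to the midpoint of the two class
plateaus (medians, so blurred edge shoulders do not drag the level — for a
blurred step edge the midpoint iso-level crosses at the true border,
removing a wall-width bias of up to ~1 % that a raw Otsu cut introduces),
hole-filling and labelling of candidate wall bands, then sub-pixel
iso-contours of the smoothed *intensity* image at the threshold level: the
largest closed contour is the outer border, the largest closed contour
nested inside it the lumen. Contouring the intensity image rather than the
binary mask avoids marching-squares staircase artefacts that would inflate
the perimeter and depress circularity by ~0.02. Contours are
Douglas-Peucker-simplified at 0.02 µm.

Alveoli touching the image border are rejected (truncated areas); regions
below a minimum area (default 100 µm²) are discarded and counted. At default
rendering conditions the round trip generator → renderer → segmentation →
measurement recovers thickness well within 1 % absolute and circularity
within 0.02. Residual errors have two parts: a small positive bias
(smoothing rounds sharp lobes of very rough shapes), roughly constant in
noise, and a dispersion that grows monotonically with noise. Degradation
tests therefore track the dispersion (SD of signed recovery error), which is
the noise-driven component.

## Statistics

* Distribution summaries: mean; 95 % CI of the mean from the t-distribution
  (not z — animal-level n is small); sample SD; adjusted Fisher–Pearson
  (small-sample-corrected) skewness and excess kurtosis, the conventions of
  mainstream desktop statistics packages; frequency histograms with
  fixed-width bins aligned to zero. Default bin widths are 3 (thickness),
  0.4 (circularity) and 0.5 (MQ). The 0.4 circularity width is deliberately
  coarse — it occupies only ~3 bins on a (0, 1] variable — so the width is a
  parameter everywhere and 0.04 is the natural fine-grained alternative.
* Aggregation: alveoli are averaged per animal and all hypothesis tests run
  on animal-level means — animals, not alveoli, are the independent
  experimental units. Normality is likewise assessed on the samples actually
  compared, i.e. the animal means.
* Test selection (α = 0.05 throughout, two-sided): Shapiro–Wilk per group;
  if both pass, an F-test arbitrates equal variances — Student's unpaired t
  if equal, Welch's t if not; if either group fails (or is degenerate:
  all-tied samples make Shapiro–Wilk undefined) the Mann–Whitney U test is
  used, with the degenerate fallback logged. The F-test choice is a
  convention; "equal standard deviations" admits several arbiters and the
  F-test is the simplest matching one. The whole rule is a deterministic
  function of the two samples. Under the generator's null (identical
  conditions, 5 animals/group) the composite procedure rejects at ≈ 4.5 %,
  within binomial error of the nominal 5 %.
* Regression: ordinary least squares of cumulative score on per-animal MQ,
  with R², the two-sided slope p and a t-based 95 % slope CI.
* No multiple-testing correction is applied, mirroring the underlying
  workflow's single-comparison-per-variable design.

## Numerical and design notes

* Shoelace area/perimeter are vectorised numpy; shapely is used for
  validity/containment, scikit-image for rasterisation, blurring,
  thresholding and contouring, scipy.stats for every statistical primitive.
* Polygon closure is implicit; an explicit duplicate closing vertex is
  dropped only on exact equality (a tolerance could swallow genuine tiny
  edges of far-from-origin traces).
* Bisection for circularity amplitude runs 60 iterations max with tolerance
  1e-4; targets outside the reachable range clamp to the range ends.
* Rendering pixel (row, col) sits at physical (x, y) = (col, row) × pixel
  size, so conversion is a pure scaling; `polygon2mask` decides inclusion at
  integer pixel coordinates.
* Problem sizes in the validation suite — 1000 alveoli for ground-truth
  consistency, 50 alveoli plus a 4-level × 20-seed noise sweep for the
  round trip, 1000 Monte-Carlo replicates for the operating
  characteristics — were chosen to give stable statistics at desk scale.
* Known limitations: no separation of touching alveoli; no multi-channel
  (e.g. nuclear) information; segmentation assumes one closed band per
  region; the generator's star-convex outlines cannot represent re-entrant
  (folded) alveolar walls; published headline values from the original
  in-vivo cohorts (e.g. baseline thickness 27.37, MQ 3.345) are generator
  *targets*, since the raw images behind them are unavailable — the package
  reproduces their directions and scales, not their exact sample statistics.
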