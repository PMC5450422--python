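# Methods

This note records the models, parameter choices and numerical decisions
behind leafletkit, and what the synthetic validation does and does not
establish about real scans.

## Coordinate and unit conventions

Images are (row, col) arrays, origin top-left.  Contour points are
(x, y) = (col, row); contours are closed and oriented so the shoelace area
is positive.  All geometry is measured in pixels; millimetre conversion
(25.4 / dpi per axis) is applied only when a feature table is exported with
`units="mm"`.  The acquisition default is 800 dpi, used when a file carries
no resolution metadata.

Areas of pixel-traced blades use the lattice-point correction
`shoelace + n_boundary/2 + 1` (Pick's theorem), which agrees with
foreground pixel counts to ~0.01% on digital disks; perimeters of traced
contours are taken after a light circular Gaussian smoothing (sigma = 2
points) that removes the ~5% stair-step bias of 8-connected chains without
affecting shape-scale structure.  Compactness is 4*pi*A/P^2, 1 for a
circle; the chosen definition makes the roundest blade score highest.

## Segmentation and trichome removal

Dark-background scans are thresholded by Otsu on BT.601 luma; gray
backgrounds by green dominance G - max(R, B) > 15 (thresholdable), since a
neutral gray can overlap leaf tissue in luma.  Holes are filled, components
below 500 px^2 dropped.  Trichome (hair) pixels are classified in YCbCr
chroma space: |Cb - 128| < 12, |Cr - 128| < 12 and Y > 120 (grayish-white,
bright), and only structures thinner than 4 px are removed — a morphological
opening protects pale but thick blade regions, so the hairless blade
interior is provably untouched on every generated fixture.

## Leaflet separation

The junction between a blade and its petiole/rachis is a pair of "turning
points": two contour positions that nearly coincide in space — and hence in
both the radial-distance and the angle profile — while lying far apart
along the contour, because the boundary doubles back across the thin stalk
neck.  Junction candidates are local minima of the (5-point smoothed)
distance profile below `depth_fraction x median distance`; a candidate pair
is accepted when its spatial gap is at most `max_gap` (default 30 px) and
its circular index separation at least 20 points, and the spatially closest
such pair wins.  On a stalk-less ellipse the two minor-axis minima are far
apart in space, so no pair forms and the search correctly fails.

`depth_fraction` defaults to 0.8.  The geometry imposes a floor: the
distance from the blade centroid to the junction cannot drop below the
centroid's own distal offset, which for realistic blades lands the junction
at 0.5–0.7 of the median profile distance, while sinus bottoms stay above
~0.85.  For blades with aspect ratio (semi-major/semi-minor) beyond about
2.3, distal-margin sinuses sink into the same range and the turning-point
rule loses its margin of separation; the species this tool targets has
round-obovate leaflets well inside the valid regime, and the synthetic
presets keep aspect <= 2.0.

Whole-leaf separation works per blade: a morphological opening with a disk
of radius `stalk_width/2 + 2` erases the thin stalk network, leaving the
three blade bodies; every leaf pixel is assigned to its nearest body, and
turning points are detected on each blade's own radial profile — the regime
where the centroid sits inside the blade — restricted to the neighborhood
of its stalk stub.  Each blade is cut straight across its junction pair,
which realizes the two sequential cuts (laterals off the petiole, terminal
off the rachis) in one pass.  Roles: the petiole tip is the far-reaching
thin pixel farthest from the blades; the blade farthest from it is
terminal, and the other two are left/right of the petiole-to-terminal axis
as seen on the scan.  Manual corrections (sidecar JSON with explicit
junction endpoint pairs, and optional midvein control points) override
detection.

## Serration detection

The raw radial profile superimposes the slowly varying blade outline
(amplitude tens of px) and the serration signal (a few px).  Detection
works on the residual after subtracting an outline baseline: a fourth-order
Whittaker smoother with circular fourth differences, solved exactly in the
Fourier domain, whose 8th-power transfer rolls off around harmonic 6 of the
profile — between the outline scale and the widest credible tooth.  A
second pass strips samples deviating from the first baseline by more than
half the prominence floor and refits, so wide teeth cannot drag the
baseline into themselves.  The junction cut and the basal notch (margin
points contiguous with the cut below 0.8 x median distance) are excluded
and bridged by linear interpolation before filtering, with an exclusion
buffer of n/12 points against filter ringing at the bridge kinks.

Tips are strict local maxima of the residual (plateaus collapse to their
midpoint) with local prominence of at least `1.5 px + 2% of the median
radial distance`; prominence is evaluated in a window of n/4 points so a
remote deep feature cannot inflate a sub-threshold ripple.  Valleys mirror
the condition on the negated residual; between consecutive tips exactly one
valley is kept (the deepest raw-profile point when none is detected), and
the outermost teeth receive flank valleys where the residual returns to the
baseline.  Indices are then refined to raw-profile extrema so measurements
are not biased by smoothing.  Tooth and valley geometry (heights, areas,
perimeters, triangle angles) is computed on the raw contour.

Known limitation: on a *smooth* blade with aspect ratio near 2, residual
leakage of mid harmonics at the distal pole approaches the prominence
floor and can produce a single false tooth; the smooth-margin phenotypes
this matters for are rounder than that in practice.

## Elliptic Fourier description

Classical four-coefficient elliptic Fourier expansion with arc-length
parameterization; contours are resampled to 16384 equally spaced points
before coefficient estimation, which holds rotation/start-point invariance
of the amplitudes to better than 1e-4 of the leading amplitude.
Normalization removes translation (constant term), rotation and starting
point via first-harmonic phase alignment; size is deliberately preserved,
so amplitudes scale linearly with the blade.  Band powers are sums of
A(f)^2 over Delta (1–19), Alpha (20–55) and Beta (56–120) and partition the
total exactly.

The 50% frequency accumulates the combined amplitude A(f) (the sum of the
A(f) values, halved; A(f)^2 accumulation is available as an option) and
excludes the first harmonic: the gross ellipse holds well over half of the
total for any blade, and including it pins the descriptor at 1 for every
leaflet.  With this definition the heteroblasty preset reproduces the
expected developmental signal — the 50% frequency falls monotonically from
the youngest, most finely serrated stage to the oldest (about 9.0 to 5.4 on
group means) — whereas squared-amplitude accumulation buries the serration
signal under outline power and loses the trend.

Reconstruction inverts the raw (image-frame) coefficients with unselected
harmonics zeroed.  The spectral low-pass filter is the same machinery with
harmonics 1..cutoff; it removes hair-like spikes of ~1 px (which carry
almost no arc length and live far above any practical cutoff) but is not a
substitute for chroma-based trichome removal when hairs are long: a long
hair contributes real arc length and its spectral content reaches down into
the serration band.

## Synthetic leaves

A leaflet blade is a polar outline r(alpha) = superellipse + sawtooth +
smoothed noise around the blade center: semi-axes default 110 x 65 px
(4.2 mm at 800 dpi — on the small side of the species' range, keeping
fixtures fast), teeth as asymmetric triangular bumps confined to the distal
`toothed_arc` fraction of the margin (default 0.6), margin noise 0.4 px
(sd, smoothed), a 45 x 8 px stalk, and a recessed proximal notch (Gaussian
dip to 0.45 x semi-minor, half-width 0.5 rad) that seats the petiolule the
way real blade bases do and gives the junction its depth.  Tooth tips,
junction endpoints, blade length/area and the hairless mask are returned as
ground truth.  Rendered leaves place the terminal blade above a rachis and
the two laterals on short petiolules beside the node, on a dark or gray
canvas, with optional 1–2 px grayish hair strokes along the margins.

Populations draw size-like parameters log-normally around group means with
a coefficient of variation of 0.05–0.06 (blade and margin measures of real
leaves are right-skewed and strictly positive); tooth counts are rounded
draws from the same scheme, matching the tight standard errors reported
for real developmental series rather than Poisson scatter.  Presets:

- `heteroblasty6` — six developmental stages, 32 leaflets each: tooth
  number 40 -> 10 nearly linearly, blade size peaking at stages 2–3,
  length/width ratio declining below 1 by stage 6, tooth height declining
  (so mean tooth area still rises as bases widen).
- `mutants5` — wild type plus five strongly contrasted shape mutants,
  including one with a completely smooth margin.
- `ecotypes4` — four accessions with moderate, overlapping differences.

What passing on these fixtures shows: the geometry, spectral and
classification machinery is correct and calibrated on shapes with known
truth.  What it does not show: robustness to overlapping leaflets (real
protocols dissect overlaps physically), venation texture, shadows, torn
margins, or scanner artifacts — none of which the generator emulates.

## Statistics and classification

Group comparisons report one-way ANOVA and Kruskal–Wallis side by side
(margin parameters are generally non-normal), per-group mean ± s.e. and
dispersion (sd/mean), and flag pairs whose t-based 95% confidence intervals
do not overlap.  No multiple-testing correction is applied across
parameters; comparisons are reported per parameter.

Classification standardizes (z-scores) the selected 3–4 features — required
when mixing px^2 areas with dimensionless ratios.  k-means (10 restarts,
seeded) is scored against true groups by the accuracy-maximizing bipartite
matching of clusters to labels.  The network classifier is a single hidden
layer of 3–15 units (default 8) trained with lbfgs over 30 stratified
random 75/25 train/test splits; both the mean held-out accuracy and the
pooled-confusion accuracy are reported (stratification keeps every group
present in each quarter at small n).  The genetic algorithm searches
fixed-size feature subsets (population 40, 60 generations, tournament-of-3
selection, union crossover, single-feature swap mutation, elitism 2, all
fitness values cached) and returns every evaluated subset reaching the
accuracy threshold, ranked.  Morphospace summaries are per-group mean
vectors and covariances with chi-square 95% scaling (semi-axes
sqrt(chi2_{0.95,3} x eigenvalues)).

All randomness flows from explicit integer seeds; result objects record
their seed, and batch exports embed the software version and a config
digest, so identical inputs and configuration reproduce byte-identical
tables.

## Problem sizes used in validation

The validation suite measures 50 single leaflets (5–40 teeth) for count
recovery, 30–50 rendered trifoliate scans for the image round trip, the
full `heteroblasty6` (192 leaflets) and `mutants5` (96) presets for
classification, a 20-feature/3-informative table checked against exhaustive
subset search, and 100 seeded replicates for test calibration.
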