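# Methods

`wormpheno` quantifies growth and motility of single *C. elegans* worms
from time-lapse brightfield clips of microfluidic growth chambers, and
turns the per-worm phenotypes into control-normalised dose-response
curves with IC50 estimates. Because no public video corpus exists for
this assay format, the package ships a synthetic worm-video generator
with exact ground truth; every stage of the analysis is validated by
recovering what the generator put in.

## The synthetic worm

### Kinematics

The body midline is a constant-arclength curve of length *L* whose local
tangent angle carries a traveling sine wave:

    theta(s, t) = A(s) sin(2 pi s / lambda - 2 pi f t + phi),
    A(s) = A0 (1 - b s / L)

with arclength *s* (s = 0 at the head), undulation frequency *f*
(default 1 Hz), wavelength `lambda = 0.65 L`, peak bend `A0 = 0.55 rad`,
and a head bias `b = 0.4` so the head oscillates more than the tail —
the standard low-dimensional model of nematode swimming, and the basis
for the head/tail orientation heuristic downstream. Positions are
integrated from theta at segment midpoints, so consecutive points are
spaced exactly `L/(K-1)` apart (K = 101). The integrated curve is
re-anchored at its centroid each frame (a real worm oscillates around
its axis of progression, not around its head) and translated at
`speed_um_s` along the heading. A bend field winding by more than a full
turn (grossly self-intersecting body) is rejected.

### Rendering

Each frame paints a dark tube (intensity 0.25) of tapered half-width
around the midline on a brighter background (0.75): full half-width
`width_um` along the trunk, tapering linearly to 25% over the terminal
10% of arclength, with disk end caps. The tube raster — *before*
degradation — is the ground-truth mask. Degradation is a Gaussian blur
(sigma 1 px, the point-spread scale of a 10x brightfield objective at
this sampling) plus additive Gaussian intensity noise. Default
calibration is 1.3 µm/px, so a 1280 µm chamber fills a 984 px frame;
clips default to 10 s at 5 fps. Ground truth per clip: midline
coordinates per frame, raster centroids and areas, cumulative head/tail
and centroid path lengths, and the wave frequency.

### Dose-response experiment layer

`GrowthDoseModel` emulates a logarithmic-dilution anthelmintic assay
(control + 1 nM ... 1 mM). Control length is logistic in time,
`L(t) = L0 + (Lmax - L0) / (1 + e^{-k (t - t_mid)})` (L0 = 250 µm,
Lmax = 1100 µm, t_mid = 30 h, k = 0.12 /h), and the compound attenuates
growth and motility by independent four-parameter-logistic factors
(defaults: IC50 46 µM for growth with Hill 1.2; IC50 5 µM for motility
with Hill 1 — motility is deliberately the more sensitive phenotype
family, so the analysis can be checked for preserving that ordering).
Worm-level variability is lognormal: a persistent size factor and a
persistent "vigour" factor (both CV 10%), plus 5% per-measurement noise.
Group sizes can be drawn from a range (default 5–12 worms/condition,
matching realistic chip occupancy).

Two attenuation conventions are provided. The default scales the whole
length (`L(t, c) = L(t) g(c)`; mean at c = IC50 is half the control
mean). For *rendered* experiments, `attenuate_increment_only=True`
scales only post-hatch growth (`L0 + (L(t) - L0) g(c)`): worms never
fall below hatchling size — a 25 µm "worm" cannot exist or be imaged —
and the percentage response becomes an affine 4PL with the same IC50
and a nonzero bottom plateau, i.e. the partial-agonist shape. We found
the whole-length convention plus the unavoidable minimum-length clamp
biases video-recovered IC50s low by ~25–30%; the increment convention
removes that bias entirely.

The statistical layer (`simulate_phenotype_table`) draws the six
phenotypes per worm and time point from this model without rasterising
video; large repetition studies (hundreds of experiments) run on it.
The rendering layer (`simulate_experiment`, `end_to_end_video_ic50`)
exercises the full image pipeline.

### Embryo tables

Embryo-stage observables are table-based only (in this assay format
embryogenesis is scored by an operator, not by the video pipeline):
Bernoulli hatching (default 70%), Normal twitching-to-hatching times
truncated at zero (9 ± 1 h), Bernoulli death during L1 among hatched
(10%).

## Segmentation

The worm is the only moving dark object; static chamber structures
cancel in background subtraction.

* **Background**: per-pixel temporal *percentile* across frames, default
  the 90th. A median (percentile 50) fails for slow or chamber-confined
  worms whose spine pixels are occupied in more than half the frames;
  because the worm is darker than the chamber, a high percentile
  recovers the empty-chamber intensity whenever a pixel is worm-free in
  ≥ 10% of frames. A user-supplied wormless reference frame (chambers
  are imaged before worm loading) replaces the temporal estimate when
  the worm barely moves at all — the only regime where no temporal
  estimator can work. Fewer than 3 frames: first frame, flagged.
* **Threshold**: Otsu's method on the difference image, floored at half
  the robust contrast (mean of the top-200 difference pixels). On a
  histogram dominated by background zeros Otsu lands low and dilates a
  thin worm by ~1 px per side — a 20–35% area error for L1 larvae; the
  half-maximum contour is the unbiased boundary of a blur-limited
  object. A fixed threshold can be set explicitly.
* **Morphology and selection**: opening (disk r=1), closing (disk r=2)
  on an edge-replicated window (so border-touching worms are not
  eroded), largest connected component, hole filling. Components below
  30 px are "empty" frames — carried as gaps, not failures; a clip with
  > 50% empty frames fails clip-level QC. Empty frames never contribute
  zeros to any statistic.

## Centerline

The mask is thinned to a 1-px skeleton and treated as an 8-connected
graph (diagonal edges that shortcut an orthogonal 2-step are dropped —
otherwise every L-step is a spurious 3-cycle). Spurs shorter than 10% of
the skeleton length are pruned iteratively, shortest first; a surviving
cycle or more than two endpoints marks the frame "coiled", and coiled
frames are dropped from kinematics rather than force-resolved. The
longest endpoint-to-endpoint path is the body axis.

A parametric smoothing spline (budget 1 px² per path point; 0
interpolates) is evaluated densely and resampled at K = 101 points of
equal arclength (spacing uniform to < 2%). Tips are then extended along
the terminal tangent (estimated over a ~4 px window; the adjacent-sample
tangent is too noisy) to the mask boundary, capped at 1.5x the local
half-width — thinning retracts tips by about half a width — and past
the boundary by a blur-loss correction: a tip tapering below the PSF
never reaches the detection threshold. Modelling tips as tapering over
10% of the body from trunk half-width W to 0.25 W, the sub-resolution
segment is `0.1 len max(0, psf/W - 0.25)/0.75` px with psf = 1.2 px
(blur sigma ⊕ pixel sampling): zero for W > ~5 px, 2–3 px for the
thinnest larvae. With it, length recovery is within ±2% from 150 µm to
1100 µm; without it, L1 larvae read 5% short.

**Orientation**: endpoints are corresponded frame-to-frame by
nearest-endpoint matching (flip each frame to minimise summed endpoint
displacement to the previous valid frame). The endpoint family with the
larger cumulative path over the clip is the head — heads oscillate and
forage more; the criterion is invariant to reversing frame order. When
the two families' path lengths differ by < 10% the orientation is kept
but flagged low-confidence. The mid-body bend angle is the signed angle
between the head→mid and mid→tail chords.

## Phenotypes

Per clip (one worm, one time point), requiring ≥ 10 valid frames:

* **length, area**: medians over valid frames (robust to occasional
  segmentation outliers).
* **central velocity**: summed centroid displacement over consecutive
  valid frames divided by the spanned time; gaps are bridged by dividing
  by the actual time gap, so dropped frames do not inflate speed.
* **beating frequency**: zero crossings of the mean-subtracted mid-body
  bend series, with hysteresis; one thrash = two crossings. The band
  adapts to the series (0.3x robust SD, clipped to [0.02, 0.05] rad): a
  2 Hz worm's chord-bend amplitude is only ~0.1 rad and a fixed 0.05 rad
  band half-counts it, while the 0.02 rad floor sits above centerline
  jitter so a static worm reads exactly 0 Hz. With ≥ 3 crossings the
  frequency comes from interpolated crossing instants (immune to
  half-period truncation at clip edges). Estimates ≥ 75% of the fps/2
  sampling limit are flagged aliasing-unreliable.
* **head/tail amplitude**: cumulative path of the tip over valid frames
  ("total movement" read as distance travelled); the peak excursion from
  the mean tip position is emitted as a secondary value.
* **responsiveness**: convex hull of all valid-frame midline points
  must exceed pi L² (a circle of radius one body length).

All six are invariant to frame-wide intensity offsets and rigid motion
of the field of view.

## Dose-response analysis

Responses are percent of the mean control value at the same time point
(mean ± SEM per condition; absent values excluded, never zero-filled;
the normalisation is scale-invariant). The dose model is the 4PL

    R(c) = bottom + (top - bottom) / (1 + (c / IC50)^hill)

with bottom free ("partial agonist"); the control cannot sit on a log
axis, so it anchors top through normalisation and is excluded from the
fit. Fitting is nonlinear least squares on log10(c), weighted 1/SEM²
(SEM floored at 1 percent point; unweighted available), multistart
(log-IC50 grid over the tested range ± 1 decade, bottom ∈ {0, min},
hill ∈ {0.7, 1.5}), best start polished at tolerance 1e-15 — noiseless
4PL samples are recovered to machine precision. The fit *refuses*
(verdict `no_ic50`) when any of: no convergence; IC50 outside
[cmin/10, cmax·10]; SE of log10(IC50) > 0.5 decades (from the Jacobian
covariance); fitted drop (top − bottom) below 4x the residual RMS (no
resolvable dose effect); R² < 0.3. All thresholds are configurable; on
flat-noise nulls the refusal rate is ~98%.

The **time-averaged index** averages each worm over its available time
points first (a worm missing one time point still contributes), then
forms condition means/SEMs, normalises by control and fits the 4PL —
per-worm-first averaging keeps each animal one statistical unit.
**Growth curves** are logistic in time per condition,
`plateau / (1 + e^{-rate (t - midpoint)})`, least squares with
multistart; plateau ratios between condition and control give
"drop of maximum length/area" summaries; flat series are reported
non-converged rather than given a spurious plateau. **Embryo
statistics**: per condition the hatch fraction, dead-L1 fraction among
hatched, and mean ± SEM twitching-to-hatching time (hatched only, SEM
absent below n = 2), with classical one-way ANOVA across conditions on
development time. Longitudinal repeated-measures designs are
deliberately reduced to per-worm time-averaging + one-way ANOVA.

## What the generator does and does not emulate

Emulated: the acquisition regime (10 s, 5 fps, 10x over a 1280 µm
chamber), a single dark worm per chamber, brightfield blur and noise,
growth over 0–80 h, dose-dependent attenuation of growth and motility
with realistic inter-worm variability, uneven group sizes, embryo-stage
event statistics. Not emulated: bacteria/debris texture, illumination
drift, pillar/filter structures (renderer hooks exist but the default
chamber is clean), coiling and omega turns, self-occlusion, progeny,
sleep-like activity cycling, and any real anthelmintic pharmacology
beyond the two 4PL factors. Passing the recovery suites therefore shows the
*algorithms* are correct and well-calibrated on ideal-to-noisy single
worms; it does not certify performance on cluttered real chambers or
coiled postures (coiled frames are detected and dropped, not resolved).

## Problem sizes and tolerances used in validation

The test suite renders scaled-down versions of each study (8 clips for
segmentation IoU, 4 body sizes for morphometry, 6 clips for motility,
200 statistical-layer experiments for IC50 recovery, 1000 null ANOVA
simulations); `scripts/acceptance.py` runs the full sizes (20 clips,
7 sizes, 12 clips, plus an 88-clip end-to-end video dose-response at
8 worms x 11 concentrations). Recovery tolerances asserted: IoU ≥ 0.90;
length within 3% and area within 10% over 150–1100 µm; velocity within
5%; frequency within 0.1 Hz below 2 Hz; tip paths within 10%; median
|log10 IC50 error| ≤ 0.1 at 5–12 worms/condition; ≥ 90% preservation of
the motility-before-growth ordering; ≥ 95% refusal on nulls; hatch
fraction ± 0.01 at n = 10⁴; ANOVA type-I error in [3.5%, 6.5%];
byte-identical reruns at fixed seed.

## Known limitations

* Head/tail assignment relies on differential tip movement; for a
  paralysed worm it is guesswork and is flagged low-confidence, not
  withheld.
* A worm that never moves cannot be segmented from its own clip; a
  wormless reference frame is required (and is part of the platform's
  acquisition anyway).
* The magnification-to-pixel calibration of the emulated instrument is
  an estimate (1.3 µm/px); it is configurable everywhere and recorded in
  output metadata.
* Frequency estimation is zero-crossing based; above ~2 Hz at 5 fps it
  degrades and is flagged rather than corrected (no spectral fallback).
* The spline smoothing level of any particular real rig is unknown; the
  default (1 px²/point) is exposed in configuration and stamped into
  outputs.
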