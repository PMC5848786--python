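# Methods

This note records the models, parameter choices and numerical details
behind `greencam`, and what the synthetic validation does and does not
demonstrate.

## Chromatic coordinates and per-image statistics

Gcc and Rcc are computed from the ROI-mean digital numbers, not as
per-pixel ratios averaged afterwards: the index is defined on the
channel means, and this form is exactly invariant under multiplicative
exposure scaling of the raw pixels. Channel summaries use the
population SD (divisor N — the ROI is a complete enumeration, not a
sample) and linear-interpolation percentiles (the common default;
any percentile convention differs only at the sub-DN level for
realistic ROI sizes). Pearson correlations between channel pairs are
reported as missing when a channel has zero variance. A channel sum of
zero (a fully black ROI) yields missing chromatic coordinates rather
than an error, since a single bad frame should not abort a
multi-year run.

Solar elevation comes from the NOAA solar-calculator ephemeris (Meeus
series: declination + equation of time + hour angle), implemented
directly rather than via an ephemeris dependency. Atmospheric
refraction is ignored; its maximum effect (~0.5° at the horizon) is far
below the 10° elevation filter it feeds. Accuracy against an
independent algorithm is a few hundredths of a degree; the test suite
cross-checks against a separate Fourier-series implementation at 0.5°.

## Quality filters and aggregation

Filters (solar elevation ≥ 10°; ROI brightness sum in [100, 665] DN)
use strict inequalities, so boundary values pass. The 3-day grid is
anchored at day-of-year 2, 5, …, 365 regardless of year length; the
final window holds two days in non-leap years and absorbs day 366
under the label 365 in leap years, keeping the grid fixed across
years. The midday image (closest to 12:00 local standard time on the
window's middle day, ties to the earlier image) is selected *without*
quality filtering: its statistics are reported separately precisely so
that a window with no valid images still documents what the camera
saw. Sample SDs over fewer than two images are reported missing, not
zero. If a 3-day window's middle day has no images at all, no midday
image is reported even when the flanking days have some — the midday
column refers to a specific calendar day, not to the window.

## Spline smoothing and outlier rejection

Each of the eight series (gcc/rcc × mean, 50th, 75th, 90th) is fitted
with cubic smoothing splines over a fixed grid of 30 log-spaced
smoothing parameters (1e-2 … 1e8, spanning near-interpolation to
near-linear on day-unit time axes); the grid is fixed for determinism.
Model selection minimizes the Hurvich–Simonoff–Tsai corrected AIC,

    AICc = ln(RSS/n) + (1 + edf/n) / (1 − (edf + 2)/n),

with edf the trace of the linear smoother matrix, computed exactly by
passing the identity through the fit. Candidates with n ≤ edf + 2 are
excluded; if all are (pathologically short series), the stiffest
candidate is used with a warning. Series with fewer than 8
observations are left unsmoothed.

Residuals are modelled as Laplace — camera greenness artefacts are
heavy-tailed — so the residual SD is √2 × (mean absolute residual).
The SD is estimated from *all* points' residuals about the current
spline, while the spline itself is fitted to unflagged points only.
This choice matters: estimating the SD from unflagged residuals alone
lets each pass shrink the scale and progressively swallow ordinary
noise (~3.5% false positives on calibrated synthetic series), whereas
the all-points estimate keeps the scale honest once gross outliers
leave the fit (measured 100% recovery of injected artefacts with ~0.6%
false positives). Flagging is asymmetric — 4 SD above, 2 SD below —
because real artefacts (snow, fog, droplets) overwhelmingly depress
Gcc. Flags accumulate across up to 20 passes; a degenerate fit
(SD ≤ 1e-9) flags nothing; flagging more than half the series aborts
with a data-quality error. One consequence of the all-points SD: if
the flagged points are removed and detection is re-run, the slightly
smaller SD can flag an extra borderline point, so the final curve is
reproducible to within one residual SD rather than bit-for-bit.

The final spline (refitted on unflagged points) supplies the smoothed
columns, evaluated on every summary row including gaps; evaluation
outside the observed span is clamped to the boundary value rather than
extrapolated cubically. The confidence band is a constant ±1.96σ — a
leverage-weighted band was rejected because the downstream date CIs
are floored at one sampling step anyway, which dominates near
transitions. The interpolation flag marks rows strictly inside gaps of
≥ 14 days between usable observations; rows before the first or after
the last observation are not "inside" a gap.

## Stage segmentation and transition dates

PELT is implemented with the Gaussian change-in-mean cost on the
smoothed series standardized by its own SD (the penalty β = 0.5 only
has meaning on a fixed scale), a minimum segment of ⌈14/step⌉ samples,
and candidate pruning delayed by one minimum-segment length — with a
minimum segment constraint, the dominating candidate is not yet
admissible at the moment of domination, and pruning immediately gives
(verified) suboptimal segmentations. Output is identical to the
exhaustive O(n²) optimal-partitioning dynamic program, which the test
suite checks on hundreds of random series.

Changepoints need not coincide with the curve's extrema, so after
merging same-direction segments each inter-stage boundary is relocated
to the extremum of the smoothed curve over the two adjacent stages:
the baseline/peak of a stage is, by definition, the trough/peak
*between* stages, and both neighbours share it. Stages whose amplitude
falls below max(2 × RMSE, 0.002 Gcc) are discarded; the 0.002 floor is
the quantization resolution of Gcc for 8-bit channels at a typical ROI
brightness sum of ~300 DN, and suppresses spurious micro-stages on
effectively noiseless flat sites (evergreen canopies) where 2 × RMSE
alone goes to zero.

Threshold crossings (10/25/50% of amplitude above the stage minimum)
are reported at the series' native date resolution — first grid date
past the crossing for rising stages, last grid date before it for
falling — with no sub-step interpolation, since the CI floor equals
one step. CI endpoints are the crossings of the spline ± its band with
the same threshold, clamped to the stage boundary if the band never
crosses, then widened to at least the nearest usable observation on
each side (which simultaneously implements the ±1-step floor and the
growth of uncertainty across data gaps).

## Calibration utilities

The sensor-response fit excludes points above DN 220 (approaching
saturation), initializes from ordinary least squares on ln(DN), and
refines with nonlinear least squares on the DN scale. Reference-panel
screening (solar elevation > 5°, brightness sum in [200, 565],
inclusive bounds) precedes a sample SD of panel Gcc; 2.5 × SD is
reported as a conservative 99% half-width. Relative Gcc maps the
dormant-season mean (day > 290 or < 110) to 0 and the peak-summer mean
(day 150–180, exclusive) to 1; the transform is linear, hence
invariant to affine distortions between cameras, and a seasonal
amplitude below 1e-9 is rejected as unscalable.

## Synthetic sites

The generator produces Gcc trajectories as a baseline plus one or more
double-logistic pulses (defaults: baseline 0.35, amplitude 0.10,
spring midpoint day 140 at rate 0.10 d⁻¹, autumn midpoint day 270 at
rate 0.08 d⁻¹ — a typical temperate deciduous season), additive
Laplace noise parameterized by its SD (default 0.004, the day-to-day
variability observed for stable cameras), optional snow days pulled to
the achromatic 1/3, gross negative outliers at 10 × the noise SD, and
per-image multiplicative illumination factors in [0.8, 1.2]. True
transition dates are solved from the noiseless trajectory by extremum
scanning plus Brent root finding — an oracle independent of the
pipeline. Rendered archives write one midday JPEG per step (quality
95, chroma subsampling off, ROI colours dithered so the ROI mean hits
the target coordinates to within 8-bit rounding), TIFF masks, the ROI
list, and site metadata; a field-of-view shift translates the scene
and adds a second mask entry. Site geometry defaults to a mid-latitude
location (42.5°N) where noon sun stays above the 10° filter all year.

What the synthetic tests show: that every processing stage implements
its stated contract, that the chain recovers known dates to within its
sampling resolution, and that outlier screening achieves its nominal
operating point under calibrated contamination. What they do not show:
robustness to the structured, autocorrelated disturbances of real
imagery — weather runs, exposure-control feedback, mixed pixels,
understory greening, camera colour-balance drift — nor the judgment
involved in drawing ROIs and vetting mask sequences, which remain
manual steps.

## Problem sizes

The test suite and acceptance script run synthetic series of one
site-year (122 three-day windows or 365 daily images) and 50-seed
ensembles for recovery statistics; these sizes give stable rates
(binomial SE on a 90% criterion over ~100 stage-rows is ~3%) while
keeping a full run in the low minutes on one core.
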