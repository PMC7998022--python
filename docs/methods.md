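# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `shagcarpet`.

## The measurement model

Systemic low-frequency oscillations (sLFOs, 0.01–0.1 Hz) are a blood-borne
component of the BOLD signal: the same waveform appears in most brain
voxels, offset by the time the blood (and with it the oscillation) takes
to arrive.  A gadolinium bolus in DSC-MRI and an inhaled-CO₂ bolus in a
CO₂-challenge scan behave analogously, with much higher contrast.  The
package models a voxel's time series as

    x_v(t) = s(t − d_v) + ε_v(t),

a shared base signal delayed by a voxel-specific arrival time `d_v` plus
noise, with a fraction of voxels carrying no coherent pattern at all.
All processing targets two quantities: the per-voxel delay map `d_v`, and
the *transit time* — the spread of arrival times visible as the tilt of
an intensity edge once voxels are sorted by delay.

## Delay estimators

**Resting state.**  Each voxel row is band-passed to 0.01–0.1 Hz with a
zero-lag (forward–backward) 4th-order Butterworth filter, upsampled to a
0.072 s grid by cubic splines, and cross-correlated against the
global-mean sLFO over lags in ±10 s.  The lag of the maximum Pearson
cross-correlation coefficient (MCCC) is the delay; the MCCC is the
quality.  The ±10 s default lag bound exceeds the expected 4–6 s transit
range while staying near half the shortest sLFO period; beyond ±5 s a
0.1 Hz component can in principle wrap by one period, which the quality
floor largely suppresses.  The bound is configurable.

**DSC.**  Each voxel's bolus-induced signal dip is fitted by least
squares with a four-parameter gamma-variate,
`baseline − A·((t−t0)/tp)^α · exp(α(1−(t−t0)/tp))`, initialized from the
raw minimum and an onset estimate.  The time-to-peak `t0 + tp` (the
analytic extremum of the fitted curve), reported on a 0.0001 s grid, is
the delay; fit R² is the quality.  Voxels whose minimum is not deeper
than 4× a robust noise scale below baseline are flagged as having no
detectable dip.

**CO₂ challenge.**  Rows are band-passed to 0.001–0.02 Hz, upsampled to
0.1 s, and cross-correlated against the measured end-tidal CO₂ trace
(interpolated onto the same grid) over ±15 s.  Because the reference is
external, all delays share a common physiological response lag (≈ the
response time constant); delay *differences*, and hence spans and edge
tilts, are unaffected.

**Zero-lag filtering detail.**  Forward–backward filtering uses
reflective padding of three filter lengths.  Longer, period-scale padding
was measurably worse on short records: it amplifies end-of-record
mismatch, which distorts the very-low-frequency CO₂ band most.

## Null-calibrated quality floors

A voxel containing only noise still reaches a sizeable MCCC: band-passing
leaves few effective degrees of freedom and the maximum is taken over
many lags.  Fixed floors are therefore miscalibrated across bands — a
floor of 0.3 sits near the *median* of the null distribution for the
rs configuration.  The default floor is instead the quantile of a seeded
Monte-Carlo null simulation (white-noise voxels processed exactly like
the data; 2 000 draws, lag scan at the native grid, where the
band-limited correlation function is smooth).  Two different error rates
are controlled:

- **rs (0.999 quantile).**  The floor gates a *contiguous* crop: one
  spurious super-threshold noise voxel interrupts the removable block,
  so the relevant error is family-wise over all noise voxels.
- **CO₂ (0.95 quantile).**  The floor only flags individual voxels (the
  two-block protocol leaves no cropping role), so per-voxel control is
  appropriate.  In this very narrow band the null 99.9 % quantile would
  exceed the quality of genuine responses.

## Carpet construction and cropping

Rows are z-scored (zero mean, unit sd per voxel) and sorted by delay in
descending order — largest delay (latest arrival) in row 0; ties break by
voxel id; undefined delays sort to the bottom.  Cropping removes only the
maximal contiguous blocks of below-floor voxels at the top and bottom of
the sorted matrix: low-quality voxels end up there because their
estimated delays are extreme.  Interior low-quality voxels are retained.
Z-scoring is one of several defensible scalings (percent signal change,
global factors); it makes intensity "contrast" values directly comparable
across voxels and is what renders the 0.2 contrast threshold meaningful.
The choice affects absolute contrast values, not transit times.

## Slope detection

Per edge: (i) 2-D Gaussian blur, default σ = 5 rows × 2 time samples;
(ii) horizontal central-difference derivative `[−1, 0, +1]/(2·dt)`;
(iii) within a column window around the edge center, per-row argmax
(argmin for falling edges) gives breakpoint times; (iv) OLS of breakpoint
time on row index.  Transit time = slope × (R − 1) row gaps — the fitted
time difference between the first and last row — signed positive when the
edge reaches the smallest-delay row first, which makes a bolus transit
positive by construction.  Edge centers are the n strongest derivative
peaks of the row-averaged global signal (n bounded by the *edge budget*
`floor(duration × f_max)`, e.g. 36 for 360 s at 0.1 Hz), separated by at
least 5 s (half the shortest oscillation period).  Peaks within the blur
kernel's support of the record boundaries are discarded, and windows that
do not fit inside the scan are rejected: breakpoints of a cut-off edge
are not measurable.  The search window defaults to the mean peak-to-peak
interval of the global signal, capped at ±5 s.

Edges are kept when the global-signal contrast around them (following
local extremum minus preceding opposite extremum) exceeds 0.2 and the
derivative at the center clears a rate floor, by default the 25th
percentile of the candidate peaks — a percentile adapts across SNR
regimes where any fixed rate value would not.  Excluded edges are
retained with their exclusion reason.

## Statistics

Transit summaries report mean, sd (ddof = 1), and the count of negative
(counter-tilted) edges.  The top-fraction grouping thresholds the global
signal at its (1 − f) quantile (default f = 0.15) and assigns an edge to
the top group when the local maximum it leads into exceeds the threshold
("leads into" reads the single following peak; testing every sample in
the window is a defensible alternative).  The median-difference CI is the
Hodges–Lehmann construction on the m·n pairwise differences with the cut
rank from the normal approximation of the rank-sum statistic, rounded to
the nearest integer; the rounding acts as a continuity correction, and
the resulting ranks coincide with exhaustive enumeration of the exact
distribution for all group sizes up to five.  The rising-vs-falling
comparison is a standard two-sample t-test (pooled by default, Welch
optional).  No mixed-effects modelling is included: the grouping rule and
interval construction are method content, the regression is a routine
off-the-shelf fit.

## Synthetic data

The phantom module generates the three modalities with known truth.
Base signals: rs — a sum of 3–8 sinusoids with frequencies drawn in
0.01–0.1 Hz (built on a 0.01 s grid so that sub-TR shifts are exact up to
spline error); DSC — baseline minus a gamma-variate dip (α = 3, peak at
t0 + tp); CO₂ — a two-block breathing protocol (+10 mmHg blocks of 120 s
with 120 s baselines) convolved with a single-exponential response
(τ = 8 s default).  Delay models: uniformly spaced over a span, or
uniform random.  Noise voxels are pure Gaussian rows with sd matched to
the clean-signal rms; measurement noise is i.i.d. Gaussian; optional
whole-brain motion spikes offset one time column in every voxel.
Generation is reproducible from the seed.

What the phantoms do *not* emulate: structured physiological noise
(cardiac/respiratory aliasing), regionally varying hemodynamic response
shapes, spatial autocorrelation, scanner drift, or multi-subject
variability.  Passing tests therefore demonstrate correctness of the
estimators and detector under the stated signal model, not performance on
real scans.

## The robustness grid and its base carpet

The grid rescales a clean single-edge carpet to target contrasts (0.5–3.5),
adds i.i.d. Gaussian noise (sd 0.1–1.0), and re-runs the detector for 30
trials per cell; the baseline is the transit detected on the clean base.
Contrast is measured on the smoothed image as the mean above the 90th
percentile minus the mean below the 10th; rescaling acts on the clean
component only, per the two-component (clean + noise) image model.

The base is synthetic (no scan is distributable): 20 000 rows — the order
of a masked whole-brain DSC acquisition — of gamma-variate dips at TR
1.5 s over 180 s, with a 4.2 s transit and native contrast 3.0.  True
bolus onsets deviate from the linear delay-rank trend by a slowly varying,
linearly detrended profile (sd 0.75 s, correlation length 40 rows) plus
independent per-row scatter (sd 0.3 s).  This deviation is essential, not
cosmetic: perfectly collinear onsets alias against the TR sampling
lattice and bias the detected slope in a way no measured carpet
reproduces, because real per-voxel event times are never exactly
collinear with delay rank (sorting keys are themselves estimates, and the
underlying physiology is not linear in rank).  The deviation amplitude is
set to cover about one sampling cell so lattice phases average out; it is
linearly detrended so the underlying transit is exactly preserved.

## TR-sampling error sweep

An ideal, perfectly linear step edge (1 500 rows over 60 s) is sampled at
a fixed TR for each of 50 sampling-start offsets over [0, TR); the
detector runs with the known edge center, and the signed error
(estimated − true) is recorded per offset.  The error is bounded by the
TR in magnitude and shrinks as the true transit grows relative to the TR.
For a 4.5 s transit at TR 1.5 s the sweep spans roughly −0.5 to +0.25 s —
asymmetric because per-row breakpoints quantize onto the sampling grid
through the argmax, which interacts with the three-cell span of the edge.

## Numerical choices and degenerate inputs

- Cubic-spline interpolation for all upsampling; values at original
  sample times are preserved.
- Cross-correlations are Pearson-normalized per lag on the overlapping
  segment, so MCCC ∈ [−1, 1] regardless of lag.
- Constant voxel rows cannot be z-scored; they are zeroed and flagged.
  An all-constant matrix, an empty mask, a crop that would remove >90 %
  of rows, a lag bound ≥ half the record, and a regressor that does not
  cover the scan are errors.
- Sorting ties break by voxel id; NaN delays sort to the bottom.
- The noise-sd estimator smooths along the voxel axis only (σ = 2 rows):
  in a delay-sorted carpet neighbouring rows carry nearly identical
  clean signal, while time-direction smoothing would leak oscillation
  signal into the residual.  The residual sd is corrected by the exact
  residual-variance factor of the discrete kernel.
- Problem sizes used by the test suite and the acceptance script
  (hundreds of voxels for phantoms, 20 000 rows for the grid base, 30
  trials per cell, 1 000 CI-coverage draws) were chosen as the smallest
  sizes at which the Monte-Carlo error is comfortably below the effects
  being measured.

## Known limitations

- A straight line is a first-order summary of an edge; real arrival-time
  profiles curve, and the OLS fit averages over that curvature.
- Gaussian noise is an idealization; real BOLD noise is structured.
- The rs delay reference is the global mean, which under-weights
  regional signals and can bias delays in voxels dominated by local
  fluctuations.
- Transit times quantify propagation through the *sorted, kept* voxels;
  cropping voxels at the extremes of the arrival path shortens the
  measured span.
- No perfusion quantification (CBF/CBV/MTT) is attempted: converting
  sLFO transit into perfusion parameters requires assumptions the data
  do not constrain.
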