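# Methods

This note records the models, parameter choices, numerical details and
known limitations behind `hddisorient`, in the order data flows through
the package.

## Coordinate and angle conventions

Positions are centimetres with the arena centre at the origin; angles
are degrees, counterclockwise-positive, 0° along +x. Head direction
(HD) is the angle of the green→red (back→snout) LED vector; the LEDs
are 10 cm apart. Angular head velocity (AHV) is the circular
per-sample HD step scaled to deg/s, CCW-positive. Tracking is sampled
at 60 Hz.

## Synthetic sessions

The generator produces sessions with the statistical structure the
analyses assume, not a biophysical simulation. Its defaults are the
study conditions of the three experiment designs it emulates: 8-min
light foraging baselines; bidirectional unrestrained rotation at
~111 or ~195 °/s with direction alternating every 5–10 s; constant
unidirectional unrestrained rotation at ~260 °/s; and head-fixed
motorised rotation at ~186 °/s, each optionally in darkness.

*Tracking.* Foraging heading is an Ornstein–Uhlenbeck angular velocity
(stationary SD 90 °/s, correlation time 0.35 s) integrated to heading;
position is a reflected 2-D OU walk in a 40-cm-radius arena. Any
ergodic walk would do; this one samples ≥ 90% of one-degree HD bins
within a few minutes, matching rat-like head-movement statistics.
Rotation phases impose the nominal angular velocity exactly, so the
mean rotation speed is within a fraction of a percent of nominal.
Head-fixed animals are stationary outside the rotation phase.

*Spiking.* An inhomogeneous Poisson process thinned on a 1-ms grid with
rate = background + (peak − background) · vonMises(HD − PFD_eff; κ).
Defaults: peak 35 Hz (the recorded-population median; cells span
~8–80 Hz), background 1 Hz, κ = 4 (tuning half-width ≈ 34°). Poisson
thinning is the standard desk-scale stand-in when no generative spiking
model is specified.

*Internal-state effects.* PFD_eff accumulates three documented
distortions:

- **Dark drift** — a Brownian rotation with scale `drift_rate_dark`
  (default 1.5°/√min), matching the reported ~1.5°/min darkness drift
  of HD cells. Only the net drift magnitude is constrained by
  observation; Brownian motion is the minimal model.
- **Underestimation** — during head-fixed rotation the internal heading
  update lags the platform by `underestimation` deg/s (default 4.5,
  between the reported per-direction values of ~3.5–5 °/s), shifting
  the measured PFD in the rotation direction at that rate.
- **Disorientation gain** — during rotation the directional modulation
  depth decays exponentially (time constant `disorientation_tau`,
  default 20 s) towards an asymptotic loss that scales linearly with
  rotation speed (saturating at 300 °/s) and is three times larger in
  darkness than in light; light head-fixed rotation is spared (gaze
  fixation). Gain recovers with the same time constant after rotation.
  This reproduces the observed pattern — directionality falling during
  disorienting rotation, more steeply at speed and in the dark, and
  recovering afterwards — without asserting an attractor-network
  mechanism. The 20-s time constant and the 1/3 light factor are
  phenomenological choices at the scale of the reported windowed
  time courses.

*Postrotational bursting.* After a dark head-fixed rotation ends, the
directionally tuned rate is replaced by background plus burst packets:
the first burst at rotation end, then each interburst interval equal to
the rotation period inflated by exp(t/τ) with t the recovery time at
the interval start and τ = `storage_time_constant` (default 3.8 s).
This realises "interburst intervals grow exponentially from the
rotation period" — the stored velocity signal decays as
speed·e^{−t/τ}, and the interval is the time the internal sweep takes
for one circle at the speed current when it starts. Packet width is
the field-crossing time at the current sweep speed (clipped to
0.10–0.5 s) and packet amplitude 1.5× the peak rate, since rebound
bursts ride on an otherwise silent background; these two constants are
set so packets are unambiguous to the burst detector at typical peak
rates, and they are not used by any analysis. Bursting is emitted only
for dark head-fixed sessions, which is the condition in which it is
observed; light and freely moving recoveries fall back to tuned firing.

Identical seed and specs give bit-identical sessions; per-cell spike
seeds are spawned from the session seed.

## Tracking preparation

LED swaps are repaired by comparing each frame's red/green assignment
against the last valid frame and swapping when the crossed assignment
is closer. Missing samples are filled by per-coordinate linear
interpolation and the track is smoothed with a Gaussian of σ = 2
samples — a fully specified stand-in for spline smoothers; at 60 Hz the
downstream analyses are insensitive to the smoother choice. Sessions
with under 50% valid samples are flagged and excluded from directional
(but not rate-based) analyses. AHV uses a 3-sample (0.05-s) box filter.

Phase detection thresholds the 10-point-median-filtered platform speed
at 130 °/s when an external speed channel exists, otherwise the
1-s box-filtered absolute HD speed at 60 °/s. Both thresholds are
configurable (the source values are approximate); absolute speed is
used throughout.

## Tuning curves and classification

The circular KDE bins angles at 1° and circularly convolves with a von
Mises kernel via FFT; "kernel width 0.1 rad" is interpreted as circular
SD 0.1 rad, i.e. κ = 1/0.1² = 100. At that width the 1° discretisation
error is negligible, and the curve agrees with a 6°-binned histogram
estimate to well under 15% of the peak on seeded sessions. Bins with
dwell-density mass below 1e-9 are masked. PFD ties break to the lowest
angle. Shuffle shifts wrap circularly in time, are uniform over
[20 s, T − 20 s] in 0.02-s steps, and each cell is compared with its
own shuffle distribution.

Windowed tuning tiles a phase with nonoverlapping 10-s windows, each
extended in 2-s steps (capped at the phase end) until ≥ 90% of the 360
bins carry dwell mass; coverage uses the KDE dwell (mass > 1e-9), so a
fast sweep sampled discretely at 60 Hz still covers the bins it passes
through. Windows that never reach coverage are flagged, with statistics
on the available bins. Per-revolution tuning splits the rotation phase
at each complete 360° of unwrapped heading.

## AHV maps and prediction

Dwell and spike maps on the 60 × 100 grid are smoothed separately with
a truncated 3×3 Gaussian (σ = 1.5 bins, renormalised to unit sum;
circular over HD, edge-replicated over AHV) and then divided; the
< 0.1-s occupancy mask is applied after smoothing, following the stated
processing order. Samples beyond ±300 °/s are dropped and counted.
Prediction multiplies the test session's dwell by the baseline
probability elementwise, with bins unvisited in either map masked in
both. Both indices are antisymmetric under exchanging observed and
predicted by construction.

## Bursts and the time constant

Burst-index bins are anchored at the session start; a spikeless session
returns 0 with a degenerate flag (no bin can exceed a zero mean
strictly). ISI statistics are confined to contiguous ±30° PFD-facing
epochs — never across them — with optional exclusion of the first six
rotations, and cells with fewer than 10 ISIs are flagged excluded.
Rate matching substitutes, with replacement, the baseline cell nearest
in PFD firing rate within ±1 Hz and drops unmatched cells.

Burst detection evaluates the smoothed 20-ms histogram in its own
units (spikes per bin mass); height and prominence thresholds of 0.25
are configurable since their units are stated only loosely at the
source. The minimum peak separation is the smallest bin count
exceeding 0.05 s.

The time-constant fit pools each cell's first four interburst
intervals per session, converts to speeds (360/interval), ranks them,
and fits speed = a·e^{b·rank} (curve_fit, start values 100 and 0.25).
τ is the elapsed time at which the fit reaches 1/e of the rotation
speed. Ranks convert to seconds through the fitted interval sequence:
the speed of interval k estimates the internal velocity when interval
k *starts*, so the elapsed time at rank k is the cumulative sum of the
*preceding* fitted intervals (rank 1 ↦ 0), with linear interpolation
between ranks and linear extrapolation outside them. Anchoring rank k
at the interval's end instead inflates τ by roughly the mean interval
(on the generator's own 3.8-s cohorts, from ~3.8 to ~9.5 s), which is
why the start-anchored convention is used. Non-decaying fits (b ≥ 0)
report τ ≤ 0 and are excluded from the condition mean, as are cells
with fewer than two intervals. In the analysis window we include ~5 s
before rotation end so the burst at the rotation stop itself is not
clipped by the window edge.

## Drift regression and spectrograms

Circular-linear regression scans candidate slopes for the maximum mean
resultant length of (pfd − slope·t), then refines with bounded scalar
minimisation (xatol 1e-10). On (near-)regularly spaced revolutions,
slopes separated by 360/Δt are exactly indistinguishable, so the
default search range is half that alias spacing around zero and
near-ties break toward the smallest |slope|; callers may pass wider
bounds explicitly. For noiseless data with total drift under 90° the
estimate matches ordinary least squares on the unwrapped angles to
1e-6.

The spectrogram uses a 50-Hz instantaneous rate (20-ms bins, 40-ms
Gaussian bandwidth), 512-sample Hanning windows (10.24 s) with 90%
overlap and 1024-point frequency resolution. Columns are z-scored over
the full frequency axis before restricting the peak-frequency trace to
±0.2 Hz of the rotation frequency. Group spectrograms should be
medianed across sessions, then across cells. Because the ridge leaves
the ±0.2-Hz band within a few storage time constants, ridge-decay
analyses should window a limited span around the rotation end (the
package's own checks use −10 s to +20 s).

## Cohort statistics

Normalisation z-scores against the first visual baseline; PFD drift is
instead the signed circular difference to the baseline PFD. The GLM is
identity-link normal (equal to OLS, and verified against the closed
form to 1e-8) with darkness, restraint and unidirectionality coded 0/1
and baselines at speed 0; standardized coefficients come from
re-fitting after z-scoring all five design columns, including the
interaction column (coefficients are invariant to the 0/1 vs effect
coding up to sign and scale). Rank-deficient designs raise an error
naming the collinear columns. The model-representation helper
evaluates the fit at 111/195/260 °/s for a freely moving,
unidirectionally rotating animal. The V test uses the large-sample
normal approximation u = V√(2/n); Holm–Bonferroni families are
defined per analysis panel. One-way ANOVA and Dunn–Šidák pairwise
comparisons are thin wrappers over scipy.

## Behaviour-bias test calibration

The postrotation bias test z-scores the recovery-window cumulative
angular deviation against 1000 random baseline windows and reads a
two-sided p from the standard-normal CDF. Sign ties (a cumulative
deviation of exactly zero) count as half a match, and an all-zero
baseline yields chance 0.5 by that rule. The normal approximation is
accurate when the baseline contains many *independent* windows: the
calibration suite uses 30-min stationary baselines and achieves the
nominal 5% type-I rate with uniform p-values. With session-scale
(8-min) baselines the shuffle variance is estimated from ~16
independent windows and the test becomes mildly anticonservative
(observed type-I ≈ 7–12% depending on baseline length); users testing
single sessions should prefer empirical shuffle percentiles if exact
calibration matters.

## Problem sizes in the checks

The test suite and examples run on desk-scale problems chosen to make
each property measurable: 4–8-min sessions, cohorts of 6–20 cells,
and 200–500 replicates for calibration checks. Parameter-recovery
bands (e.g. the storage time constant recovered within [2.8, 4.8] s of
a 3.8-s truth over 20 cells) reflect the Poisson and detection noise
at those sizes.

## Known limitations

- The generator is phenomenological: no attractor dynamics, no
  eye-movement or nystagmus modelling, no habituation across repeated
  rotations, and AHV modulation of rate is off by default. Passing
  tests show the analyses recover the structure the generator encodes,
  not that real recordings contain it.
- Spike-level structure (refractoriness, theta rhythmicity, bursting
  within the field) is absent, so ISI-based metrics on synthetic data
  exercise the code paths rather than realistic ISI distributions.
- The LED-swap repair is sequential and assumes isolated swaps; long
  runs of swapped frames bounded by missing data can defeat it.
- The burst-interval recursion evaluates the stored velocity at the
  interval start; intervals late in recovery are therefore slightly
  longer than a continuous-integrator model would produce. The
  time-constant analysis is consistent with this convention.
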