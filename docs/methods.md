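# Methods

## Signal model

A video of spontaneously contracting SAN tissue is reduced to one number
per frame: the arithmetic mean gray value of the (ROI-restricted) pixels,
G̅_i ∈ [0, 255], kept in floating point. Contraction increases light
absorption, so each beat is a downward dip on a bright baseline. At a
1 kHz frame rate the trace oversamples the ~2 Hz beating by ~500×, which
is what makes millisecond-scale interval variability measurable at all:
the sampling grid, not the optics, sets the timing resolution. RGB input
from monochrome cameras is collapsed by the unweighted channel mean
(round half up), not luminance weights, because the channels are
duplicates of one sensor.

## Beat detection (optical)

1. Smooth with a 25-point centered moving average; at the trace edges the
   window truncates to the available samples (a reflected or zero pad
   would fabricate excursions).
2. Threshold: midpoint between (baseline − 2·noise SD) and the global
   minimum of the smoothed trace. The baseline level is the trace median.
   The noise SD is estimated as 1.4826/√2 · median|Δx|: first differencing
   removes the contraction waveform and drift, so the estimate reflects
   the sensor noise band; a plain MAD of the trace would count the dips
   themselves as noise and can push the threshold below shallow beats.
3. Runs of consecutive smoothed samples below threshold are candidate
   dips. Runs separated by fewer than `window` samples are merged first —
   on noisy traces the smoothed signal can pop briefly above threshold
   inside one dip, and a sub-window gap cannot separate two physiological
   beats. Runs touching either trace end are discarded (no confirmed
   return above threshold brackets their minimum).
4. The beat is the arg-min of the smoothed signal within each run; on an
   exact two-sample tie the second sample is taken. The beat's gray value
   (`minima_values`) is read from the **raw** trace as the mean over the
   detected frame and its two neighbours: the 3-frame average keeps the
   readout unbiased (the smoothed value under-reads the dip depth by its
   attenuation, ~1–3 gray for 40 ms dips) while cutting single-frame
   sensor noise by √3.

BBIs are the first differences of the beat times in ms (N_B beats give
N_B − 1 intervals).

## Baselines and contraction strength

Each beat gets its own baseline: the median of the raw samples strictly
between the previous and the current minimum (trace start to first
minimum for beat 0). Moving baselines absorb slow drift. Two structural
properties follow and are reproduced deliberately rather than "fixed":

* the median sits partly on the recovery tail of the preceding beat, so
  CS carries a small negative bias (≈0.2 gray at default conditions,
  <1% of the mean amplitude) — the cost of a baseline estimator that
  needs no waveform model;
* for burst-like doublets the inter-minimum segment contains almost no
  relaxed plateau and the baseline collapses; such beats are flagged with
  a `ShortGapWarning`, not corrected.

CS_b = |G̅_b − baseline_b| ≥ 0. ΔCS is the first difference of the
beat-minimum gray values (no baseline needed); rCS is its running sum
anchored at 0, hence exactly G̅_b − G̅_1. rCS is offset-free and
baseline-search-free; a residual linear drift does enter it as the
accumulated drift between first and current beat (quantified in the test
suite), whereas CS is drift-free through its moving baselines — the two
series fail in complementary ways, which is why both are computed.

## Nonlinear measures

**SampEn(m=2, r=0.15·SD)** with Chebyshev distance and self-matches
excluded. The normalisations follow the printed construction this
pipeline reproduces: per-template counts are divided by N−m+1 and
averaged over i = 1..N−m (and correspondingly at m+1). The constants
differ slightly from the more common convention, cancel almost entirely
in the ratio B^{m+1}/B^m, and are pinned by an independent naive
double-loop oracle in the tests. r uses the population SD of the full
series, making SampEn exactly affine-invariant. A series with no
(m+1)-matches yields +inf, flagged, never an exception — batch tables
stay aligned.

**Higuchi dimension** uses every integer delay k = 1..30 (no
subsampling), the floor-normalised curve lengths
L_m(k) = (1/k)·Σ|x(m+ik) − x(m+(i−1)k)|·(N−1)/(⌊(N−m)/k⌋·k), their means
L(k), and an OLS fit of ln L(k) on ln k; D_H = −slope, with the fit r²
reported as a linearity diagnostic (generator series give r² > 0.95
throughout). k above 30 is excluded because the double-log plot bends
there for series of a few hundred beats.

**DFA** integrates the mean-removed series, splits the profile into
non-overlapping windows of every integer size 4..30 (the range is too
small for log-spacing to matter), detrends each window linearly, pools
the squared residuals into F(n), and fits ln F(n) on ln n. First-order
DFA with windows this small carries a known upward bias for uncorrelated
data: the faithful estimator measures mean α ≈ 0.54–0.55 on white noise
(nominal 0.5) and ≈ 1.47–1.49 on Brownian noise (nominal 1.5), lengths
660 over 50 replicates. Alternatives were measured and rejected:
per-window RMS averaging inflates the bias (0.58), a residual-dof
normalisation overcorrects (0.43) and breaks the Brownian limit.

All log-log fits are natural-log OLS (the slope is base-invariant).

## Surrogates and statistics

Each per-beat series is shuffled 50 times (Fisher–Yates, one spawned
seed-stream child per shuffle, so any single surrogate is reproducible in
isolation). Shuffling preserves every order statistic and destroys only
temporal structure. Three evaluations: (1) per-series two-sided
one-sample t-test of the 50 surrogate values against the experimental
value (df = 49); (2) paired median test of experimental values vs their
per-series shuffle means across experiments; (3) paired median test of
control vs treated shuffle means.

The paired median test mirrors the decision behaviour of the
interpolated-order-statistic approach used for very small paired samples:
a Hettmansperger–Sheather CI for the median of the differences
(interpolating between the order statistics whose exact binomial coverage
brackets the level, symmetric on both ends), with the two-sided p-value
defined as the smallest level at which zero leaves the interval, found by
bisection and floored at 10⁻⁴ (report as "< 0.001"). df is reported as
n − 1 as a sample-size convention, without asserting a distributional
meaning. Empirical type-I error at nominal 0.05 with n = 9 pairs is
≈0.05 (within [0.01, 0.10] over 1000 null studies — the property this
test family is chosen for).

## Synthetic data: what it emulates and what it does not

The generator draws beat intervals and dip amplitudes as
mean·(1 + cv·z) with standardised deviates z from white, AR(1) or
fractional-Gaussian-noise models (fGn via exact covariance Cholesky;
H > 0.5 gives the long-range correlation that shuffling destroys),
clipped at ±3 SD so intervals stay positive for cv < 1/3. Defaults are
the study conditions: mean interval 512 ms (control) vs 614 ms (ACh,
~+20%), mean amplitude 21 vs 13.2 gray (~−37%), cv 5% (intervals) / 10%
(amplitudes), 1 kHz sampling, baseline 120 gray, nine paired experiments
with ±5% lognormal between-animal scatter. The ACh arm's amplitude
sequence is more strongly correlated (AR(1), φ = 0.9) than the control's
(fGn, H = 0.85), encoding "weaker but more regular" without asserting a
mechanism.

The contraction dip is raised-cosine fall (40 ms) → symmetric cosine hold
(15 ms) → smooth exponential recovery (~90% relaxed at 120 ms, truncated
and renormalised to zero at 240 ms), peak exactly 1 so dip depth equals
the per-beat amplitude. The short symmetric hold is deliberate: with an
asymmetric cusp at the bottom, the 25-point smoothing displaces the
arg-min systematically (~8 samples toward the shallower flank) and biases
the amplitude readout; a locally symmetric bottom zeroes that shift. The
fast return to baseline matters too — the moving-median baseline needs a
relaxed plateau covering more than half of each inter-beat segment, as
the real recordings show.

Default sensor noise is 0.1 gray SD. This is the physical regime of
frame-mean traces: averaging 25,600 pixels divides per-pixel noise by
160, so even several gray levels of pixel noise leave well under 0.1 gray
on the trace. At this noise level beat timing is recovered exactly and
detection jitter is nil. The generator will happily render much noisier
traces; detection then degrades gracefully (beat counts stay exact down
to SNR ≈ 10, while millisecond timing does not survive — the arg-min
jitter grows as (σ/slope)^{2/3} and no physiological dip shape is steep
enough to pin 1 ms at SNR 10).

What the generator does **not** emulate: biophysical pacemaker dynamics
(calcium/membrane clocks), motion artefacts, illumination flicker,
non-stationary beating modes (bursts appear only if configured), or
realistic video texture (frames reproduce the target mean exactly with
arbitrary spatial pattern). Passing recovery tests therefore demonstrate
the correctness of the *pipeline arithmetic* under controlled conditions,
not robustness to every failure mode of real recordings.

Electrode-like traces place one biphasic sine spike per beat (downward
zero-crossing on the beat sample) with an optional start lag of a few
beats; the unbiased cross-correlation alignment (|lag| ≤ 5 beats — the
bound prevents spurious distant maxima, observed lags are 1–3) removes
that asynchronism before optical/electrical interval comparison. The
electrical detector time-stamps downward threshold crossings, optionally
on the first temporal derivative, with a 50 ms refractory window against
double counting on noisy downslopes, and a standard zero-phase 4th-order
Butterworth band filter (1.5 Hz – 1.5 kHz) for real recordings.

## Degenerate inputs and flags

Flat trace → "no contractions detectable". Constant per-beat series →
SampEn/DFA raise, the batch runner catches per series and flags the row.
Undefined SampEn (no m+1 matches) → +inf with a flag. Constant vector in
a rank correlation → NaN with df, not an exception. Incomplete
experiments (one arm missing) are listed in the manifest, not dropped
silently.

## Problem sizes

Test-suite and driver sizes were chosen to exercise every code path at
full fidelity while staying desk-scale: 300-beat recordings for pipeline
recovery, 600-beat series × 9 experiments × 50 shuffles for the surrogate
direction study, 1000 null studies for type-I calibration, 50 replicates
of length 660 for the DFA calibration.

## Known limitations

* Absolute contraction force is not measured; CS is a relative optical
  proxy and carries the small moving-median bias described above.
* The amplitude readout deviates from a strict single-frame reading by
  the 3-frame average; for 1 kHz recordings of ~300 ms dips this is
  physiologically inert but should be revisited for much faster events.
* The median-test p-value is a CI-inversion construct; below the 10⁻⁴
  floor only "< 0.001" statements are meaningful.
* DFA with windows ≤ 30 retains its small-window bias (+0.04–0.05 on
  white noise); comparisons should use identical window settings on both
  sides, as done throughout this package.
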