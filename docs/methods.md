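# Methods

## The signal and the analysis model

The pupillary respiratory-phase (PRP) response is a small cyclic
modulation of pupil size locked to the breathing cycle: the pupil is
smallest around inhalation onset and largest during exhalation. The
package models the analysis — not the physiology — as three coupled
problems: recovering a usable pupil trace from blink-ridden recordings,
assigning each time point a respiratory phase angle, and testing
whether pupil size varies systematically over that angle.

Respiratory phase is defined piecewise-linearly by four landmarks per
cycle: inhalation onset (0°), inhalation peak (90°), exhalation onset
(180°), exhalation peak (270°), and the next inhalation onset
(360° ≡ 0°). Phase is exact at landmarks by construction and strictly
increasing within a cycle; each sample belongs to exactly one cycle.
The circle is partitioned into 18 half-open 20° bins (bin k =
[20k, 20k+20)).

## Pupil cleaning

Cleaning runs per eye in a fixed order; durations are configured in ms
and converted through the sampling rate:

1. *Initial validity rules.* Valid runs shorter than 250 ms are
   distrusted; valid runs shorter than 500 ms flanked on both sides by
   invalid runs longer than 2 s are distrusted. Flanks must be actual
   invalid data — a run at the trace edge is not "surrounded".
2. *Removal.* Invalid runs longer than 500 ms are unlikely to be
   blinks and are permanently removed; they are never interpolated and
   count as invalid for the exclusion rule.
3. *Interpolation.* Each remaining gap is extended by 2 buffer frames
   per side (the buffers are first marked invalid, so interpolation
   never overwrites a sample that stays valid); a cubic spline through
   the 3 nearest valid samples on each side fills the extended gap.
   Anchors may skip over intervening invalid runs but must lie within
   2 s of the gap. If the filled range exceeds the anchor range by
   more than 30% (20% during rechecks), the fit is retried with 3 and
   4 buffer frames, then falls back to a linear fill through the two
   buffer frames and the flank anchors (monotone, hence always within
   the guard). Gaps touching the trace edge, or without enough
   anchors, stay unfilled.
4. *Rapid-change recheck.* Samples whose first difference exceeds
   16 × MAD of the valid first differences (a configurable robust
   speed threshold; the criterion is deliberately conservative) are
   re-marked invalid, dilated by the buffer width, and re-interpolated
   with the 20% guard. A zero-MAD (constant) trace yields no
   detections.
5. *Post-interpolation validity rules.* The 250 ms and 500 ms/2 s
   rules re-run, plus a long-island rule: valid runs shorter than 1 s
   inside invalid context longer than 5 s are distrusted.
6. *Outlier mask.* Valid samples outside mean ± 3 SD (computed over
   the trace's valid samples) are invalidated. With 60 Hz × 5 min
   Gaussian noise this masks ≈ 0.27% of samples.
7. *Finalization.* Every remaining invalid sample becomes a permanent
   removal, so a finalized trace is exactly partitioned into valid and
   removed.

A session is excluded only when **both** eyes exceed 30% invalid data
after interpolation. Eyes are averaged samplewise; where only one eye
is valid, that eye is used alone (configurable), which maximizes data
use while agreeing with the two-eye average whenever both exist.
z-scoring uses the population SD (divisor n) over the pooled valid
samples of all of a participant's included sessions; a per-session
scope is available. Downsampling (e.g. 100 Hz variants) is
nearest-neighbour with validity carried from the selected sample.

Re-running the cleaning on its own output is a no-op for the removal
and interpolation stages. Exact end-to-end idempotence additionally
requires that the ±3 SD mask fires on no new samples the second time;
this holds on traces without genuine outliers (the shipped idempotence
test uses such a trace) but can tighten marginally on heavy-tailed
noise, because masking shrinks the SD estimate.

## Breath segmentation

Airflow is low-pass filtered at 5 Hz (4th-order Butterworth, zero-phase
forward–backward, unit DC gain) and mean-centred. Inhalation onsets
are negative-to-positive zero crossings, exhalation onsets the reverse;
crossings closer than 250 ms to the previous accepted one are debounced
as noise-driven micro-cycles. Crossing times are refined to sub-sample
precision by fitting free-amplitude half-sine templates to the two
flanking half-breaths and minimizing the residual over a grid of
candidate crossing times (two passes, 2 ms then 0.5 ms steps); peaks
and troughs are refined by an iterated local quadratic vertex fit
(±400 ms window), clipped into their segment. Incomplete leading and
trailing half-cycles are dropped. Half-breaths shorter than 500 ms or
longer than 6 s are invalid; their samples contribute no observations
downstream.

On generated sessions with sensor noise at 5% of the inhalation
amplitude, ≥ 99% of inhalation onsets are recovered within one sample
at 60 Hz, and ≥ 95% of peaks within three samples. Peak localization
is intrinsically worse than onset localization: a near-sinusoidal flow
is flat at its extrema, so noise moves the argmax much more than it
moves a steep zero crossing. At 10% noise, onset recovery degrades to
roughly 90% within one sample — a known limitation.

Phase is evaluated directly at the pupil timestamps (mathematically
equivalent to resampling the breathing channel to the pupil rate, and
free of an extra rounding step); `resample_trace` is available when an
explicitly resampled channel is wanted.

## Inference

**Permutation test.** Within each condition, the observations of bin k
are the individual jointly valid z-pupil samples pooled across
participants and sessions (a per-participant-mean mode is available;
the pooled mode matches per-bin observation counts in the tens of
thousands for realistic cohorts). For each bin, t = x̄/(s/√n) with
sample SD. The null flips the sign of every observation independently;
per permutation the maximum |t| across the 18 bins is recorded, and
the family-wise corrected p of a bin is the proportion of permuted
maxima ≥ its observed |t|. No +1 smoothing is applied, so p = 0 is
representable (reported as < 1/n_permutations in text). Sign flips
leave Σx² invariant, so only the flipped means are simulated —
permutations cost one matrix-vector product per chunk. Each bin draws
from its own counter-based (Philox) stream keyed by (seed, bin), so
results do not depend on iteration order; ties at |t_obs| are counted
as ≥ with a relative tolerance of 1e-9 so that sign patterns
reproducing the observed statistic exactly are never lost to float
jitter. The correction spans the 18 bins of one condition; conditions
are corrected independently.

**Circular summaries.** Per participant, the mean direction is the
angle of Σ wₖ e^{iθₖ} with weights wₖ = bin means (used as-is; negative
weights flip their unit vector) and θₖ the bin centres (10°, 30°, …).
A zero resultant raises an explicit undefined-direction error rather
than returning 0. Group level: resultant length R of the unit vectors
of the participant directions, the Rayleigh uniformity test
p = exp(√(1 + 4n + 4(n² − (nR)²)) − (1 + 2n)), and the proportion of
directions in the exhalation half [180°, 360°).

**ANOVA.** One- and two-way within-subject ANOVA on complete cases
(participants present in every cell; < 3 complete is an error) via
direct sums-of-squares partitioning. For every effect with more than
two levels, Mauchly's W is computed from the eigenvalues of the
orthonormal-contrast covariance with the chi-square approximation
including Box's second-order term (matching R's `mauchly.test` and
pingouin to ~1e-15); when p < α the Greenhouse–Geisser ε (Box's
formula, clipped to [1/(k−1), 1]) rescales both degrees of freedom.
A singular contrast covariance (e.g. fewer subjects than levels, as
happens with 18 phase bins and small groups) triggers the Friedman
fallback: rank-based chi-square with ties correction and Kendall's
W = χ²/(n(k−1)). η² is SS_effect/SS_total (partial η² available).

**Derivative.** Each consecutive-sample difference is attributed to
the phase bin of its second sample; pairs spanning invalid samples or
cycle boundaries are dropped. Per cycle the bin sums telescope exactly
to the cycle's endpoint difference (asserted in tests); the reported
derivative is the across-cycle mean per bin.

## Synthetic data

The generator emulates resting human sessions: cycle durations from a
truncated normal (1.2–12 s) matching a configurable breaths/min (mean
13, SD 3.6, via the delta method on the period); inhale fraction
0.45 ± 0.05 of the cycle; airflow as a positive half-sine inhalation
followed by a negative half-sine exhalation whose amplitude is scaled
by Ti/Te so every cycle has zero net flow — the physically faithful
choice (inhaled volume equals exhaled volume), which also keeps the
detector's mean-centred crossings aligned with the true onsets; white
sensor noise at 5% of amplitude. The pupil in z units is
A·cos(θ − θ_peak) + random-walk drift (step SD 0.001/sample) + Gaussian
noise (SD 1) correlated 0.8 between eyes (so eye averaging demonstrably
reduces noise), mapped to millimetres around a 4.5 mm baseline at
0.3 mm per z. Defaults: A = 0.15 z, θ_peak = 220° (mid-exhalation, a
testing convention inside the expected 180–270° sector). Blinks are
Poisson (12/min) gaps of 100–400 ms; long dropouts (0.6–2 s, ~2 per
session per eye) exercise the removal rule; optional spikes flanking
blinks exercise the rapid-change detector. Between participants, the
amplitude (SD 0.05, truncated at 0) and peak phase (SD 20°) are
jittered. All randomness descends from one seed through
per-participant child streams; identical seeds give byte-identical
CSVs.

The single-cosine component is a deliberate simplification: empirical
PRP curves are asymmetric. Passing recovery tests therefore shows the
pipeline recovers a phase-locked component of realistic size under
realistic artifact load — not that real pupil data are cosine-shaped.
Real recordings also contain structure the generator omits (hippus,
light and near responses, gaze-dependent foreshortening, apnea pauses),
so real-data effect sizes and p-values are not reproduced here.

## Problem sizes and numerical choices

Validation studies run at sizes chosen to make their statistical
guarantees testable while staying desk-scale: the recovery cohort uses
40 participants × 5 min at 60 Hz with 2,000 permutations (pooled per-bin
n ≈ 36,000 puts the true-effect |t| near 20, so family-wise p-values sit
far from the 0.05 boundary and the permutation count is not the limiting
factor); the null calibration uses 200 cohorts × 18 bins × 500
observations × 500 permutations; the enumeration check uses 2 bins × 4
observations against all 2⁸ sign patterns with 10,000 Monte-Carlo
permutations. Reports are serialized with sorted keys and fixed
rounding, making determinism byte-level testable.

Degenerate inputs are handled explicitly: s = 0 with x̄ ≠ 0 gives
t = ±∞ (sorting above all finite maxima); s = 0 with x̄ = 0 gives t = 0;
empty phase bins are flagged missing; constant traces yield no
rapid-change detections and an unchanged outlier mask; z-scoring a
constant trace is an error (a constant pupil signals upstream failure).

## Known limitations

- Landmark recovery beyond ~5% airflow noise degrades below the
  one-sample level; the half-sine crossing template also assumes the
  smoothed flow is near-sinusoidal between crossings.
- The 270°–360° segment maps linearly to the next inhalation onset, so
  inter-breath pauses are absorbed into late exhalation rather than
  modelled separately.
- End-to-end cleaning idempotence is exact only in the absence of
  fresh ±3 SD outliers on the second pass (see above).
- The two-way ANOVA requires a fully crossed within-subject design;
  unbalanced designs are reduced to complete cases.
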