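# prp — pupillary respiratory-phase analysis

Pupil size in humans is modulated by the breathing cycle: it is
smallest around inhalation onset and largest during exhalation (the
*pupillary respiratory-phase response*, PRP response). Detecting this
small (~0.1–0.3 z) cyclic component in noisy, blink-ridden pupillometry
requires careful artifact handling and inference that makes no
parametric assumptions. `prp` is a tested pipeline for exactly that,
aimed at researchers analysing synchronized pupil + respiration
recordings.

The pipeline:

1. **Pupil cleaning**, per eye, in a fixed stage order: short/isolated
   valid stretches are distrusted (250 ms / 500 ms-in-2 s rules),
   invalid runs longer than 500 ms (too long to be blinks) are
   permanently removed, remaining gaps are filled by buffered piecewise
   cubic splines with range guards (30% first pass, 20% on recheck,
   linear fallback), rapid changes (|Δx| > 16·MAD) are re-interpolated,
   ±3 SD outliers are masked, and sessions with > 30% invalid data *in
   both eyes* are excluded. Eyes are averaged; traces are z-scored at
   the participant level.
2. **Respiratory phase.** Airflow (inspiration-positive) is low-pass
   filtered at 5 Hz, segmented at mean-centred zero crossings into
   inhalation/exhalation onsets with sub-sample refinement, and each
   sample receives a phase angle by piecewise-linear interpolation:
   inhalation onset = 0°, inhalation peak = 90°, exhalation onset =
   180°, exhalation peak = 270°, wrapping at the next onset.
   Half-breaths outside 0.5–6 s are invalid.
3. **Phase-binned statistics.** Jointly valid z-pupil samples are
   aggregated into 18 bins of 20°. Per bin, a one-sample statistic
   t = x̄ / (s/√n) is tested against zero by a sign-flip permutation
   test with max-|t| family-wise error control (default 10,000
   permutations). Per-participant weighted circular mean directions
   (direction = atan2(Σ wₖ sin θₖ, Σ wₖ cos θₖ), weights = bin means)
   are summarized by the Rayleigh uniformity test and the proportion
   pointing into the exhalation half [180°, 360°). Phase-bin cell
   means feed one- or two-way repeated-measures ANOVA with Mauchly's
   sphericity test, Greenhouse–Geisser correction, and a Friedman
   fallback when the covariance is singular. A per-bin pupil-size
   derivative (cycle-wise summed consecutive differences) separates
   dilation from constriction phases.
4. **Synthetic cohorts.** A generator emits recordings with known
   ground truth — variable breathing cycles, a phase-locked cosine
   component, drift, correlated eye noise, blinks and long dropouts —
   so every stage is testable without any real recordings.

## Worked example

```bash
python analysis/04_cohort_recovery.py
```

generates a 40-participant cohort (5-minute sessions at 60 Hz, true
component amplitude 0.15 z peaking at 220°, with blinks), runs the full
pipeline, and prints:

```
group circular mean direction: 214.2 deg (truth 220 deg)
participant directions toward exhalation: 0.97
trough bins (30/50 deg) significantly negative: True
peak bins (210/230 deg) significantly positive: True
group bin means (z): [-0.141, -0.141, -0.137, -0.12, -0.091, -0.054, 0.006,
 0.058, 0.091, 0.136, 0.137, 0.133, 0.118, 0.083, 0.026, -0.024, -0.07, -0.11]
```

The bin means trace the injected cosine: minimum near inhalation onset
(bins around 30–50°), maximum during exhalation (bins around 210–230°);
the permutation test marks both flanks significant after family-wise
correction, and 97% of participants' mean directions point into the
exhalation half of the cycle.

The other numbered scripts under `analysis/` write a small inspectable
demo cohort (`01`), quantify cleaning fidelity (`02`, interpolation
RMSE ≈ 0.4% of the component amplitude; all injected long dropouts
removed) and check the permutation test against an exhaustive
enumeration oracle plus its family-wise error calibration (`03`).

There is also a CLI for running the pipeline on recordings on disk:

```bash
prp simulate --n 2 --duration 60 --seed 1 --out data/
prp run --config config.yaml --out results/run1
```

with a YAML/JSON config naming either `input_paths` (canonical CSVs:
`time_ms, pupil_left, pupil_right, valid_left, valid_right, airflow`)
or a `simulate` block.

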