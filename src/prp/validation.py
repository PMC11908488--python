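"""Synthetic validation studies of the full pipeline.

Each function runs one self-contained study on generated data with
known ground truth and returns a small dict of summary numbers:

* phase construction exactness on analytic landmarks,
* interpolation fidelity on smooth traces with blink gaps,
* Monte-Carlo vs exhaustive-enumeration agreement of the sign-flip test,
* family-wise error calibration under a null cohort,
* parameter recovery of the phase-locked pupil component at cohort scale.

The studies double as the package's acceptance checks and as the
analyses driven by the scripts under ``analysis/``.
"""

from __future__ import annotations

import itertools

import numpy as np

from prp import breath, stats
from prp.breath import BreathLandmarks, compute_phase
from prp.pipeline import RunConfig, run_pipeline
from prp.preprocess import CleaningConfig, PupilTrace, clean_trace
from prp.simulate import GeneratorConfig, generate_recording
from prp.stats import one_sample_t, signflip_max_t_test


def phase_exactness() -> dict:
    """Phase at the four landmark types and segment midpoints, analytically.

    Builds landmarks at 0/1000/2000/3000 ms (next onset 4000 ms) and
    evaluates the phase series at landmarks and midpoints; the maximum
    deviation from {0, 90, 180, 270} / {45, 135, 225, 315} degrees is
    returned (exact construction gives 0).
    """
    lm = BreathLandmarks(
        inhale_onset=np.array([0.0, 4000.0]),
        inhale_peak=np.array([1000.0, 5000.0]),
        exhale_onset=np.array([2000.0, 6000.0]),
        exhale_peak=np.array([3000.0, 7000.0]),
        next_onset=np.array([4000.0, 8000.0]),
    )
    t = np.array([0.0, 500, 1000, 1500, 2000, 2500, 3000, 3500])
    expected = np.array([0.0, 45, 90, 135, 180, 225, 270, 315])
    ph = compute_phase(lm, t)
    err = np.max(np.abs(ph.phase_deg - expected))
    return {"max_phase_error_deg": float(err), "n": len(t)}


def interpolation_fidelity(seed: int = 0) -> dict:
    """Cleaning fidelity on a smooth trace with blinks and dropouts.

    Generates a noiseless phase-locked session with blink gaps (<= 400
    ms) and rare long dropouts, cleans it, and reports the RMSE of the
    interpolated samples against the known smooth signal (as a fraction
    of the component amplitude) plus the fraction of injected long
    dropouts that were permanently removed.
    """
    cfg = GeneratorConfig(session_duration_s=300.0, prp_amplitude=1.0,
                          noise_sd=0.0, drift_sd=0.0, amplitude_jitter_sd=0.0,
                          phase_jitter_sd_deg=0.0, long_dropout_rate=6.0,
                          seed=seed)
    rng = np.random.default_rng(seed)
    rec, truth = generate_recording(cfg, "P1", "S1", "nose", rng)
    cleaned = clean_trace(PupilTrace(rec.pupil_left, rec.valid_left,
                                     rec.sampling_rate), CleaningConfig())
    truth_vals = cfg.baseline_mm + cfg.mm_per_z * truth.prp_component_z
    filled = ~rec.valid_left & cleaned.valid
    amplitude = cfg.prp_amplitude * cfg.mm_per_z
    rmse = float(np.sqrt(np.mean((cleaned.values[filled] - truth_vals[filled]) ** 2)))
    t = rec.time_ms
    removed_ok = []
    for s, e in truth.dropout_intervals_ms["left"]:
        sel = (t >= s) & (t < e)
        removed_ok.append(bool(cleaned.removed[sel].all()))
    return {
        "rmse_fraction_of_amplitude": rmse / amplitude,
        "n_interpolated_samples": int(filled.sum()),
        "dropouts_removed_fraction": float(np.mean(removed_ok)) if removed_ok else 1.0,
        "n_dropouts": len(removed_ok),
    }


def exhaustive_signflip_p(observations: list[np.ndarray]) -> np.ndarray:
    """Exact FWE p-values by enumerating every sign pattern."""
    sizes = [len(o) for o in observations]
    t_obs = np.array([one_sample_t(o) for o in observations])
    all_max = []
    for pattern in itertools.product(*[[-1, 1]] * sum(sizes)):
        pos = 0
        ts = []
        for b, o in enumerate(observations):
            eps = np.array(pattern[pos:pos + sizes[b]])
            pos += sizes[b]
            ts.append(abs(one_sample_t(eps * o)))
        all_max.append(max(ts))
    all_max = np.array(all_max)
    return np.array([float(np.mean(all_max >= abs(t))) for t in t_obs])


def permutation_vs_enumeration(seed: int = 0, n_permutations: int = 10_000) -> dict:
    """Monte-Carlo sign-flip p against the exhaustive 2^8 oracle.

    Two bins of four observations each; reports the largest absolute
    deviation between the Monte-Carlo and exact FWE p-values, and the
    largest deviation in units of the binomial standard error.
    """
    rng = np.random.default_rng(seed)
    obs = [rng.normal(0.8, 1.0, 4), rng.normal(0.0, 1.0, 4)]
    p_exact = exhaustive_signflip_p(obs)
    res = signflip_max_t_test(obs, n_permutations=n_permutations, seed=seed)
    diffs = np.abs(res.p_fwe - p_exact)
    ses = np.sqrt(np.maximum(p_exact * (1 - p_exact), 1e-6) / n_permutations)
    return {
        "max_abs_p_difference": float(diffs.max()),
        "max_difference_in_se_units": float(np.max(diffs / ses)),
        "n_permutations": n_permutations,
    }


def fwe_calibration(n_datasets: int = 200, n_bins: int = 18, n_obs: int = 500,
                    n_permutations: int = 500, alpha: float = 0.05,
                    seed: int = 0) -> dict:
    """Family-wise error rate of the max-t test under the global null.

    Each replicate draws ``n_bins`` x ``n_obs`` independent standard
    normal observations (amplitude 0) and tests all bins; a family-wise
    false positive is any bin with p_fwe <= alpha.  Under exact FWE
    control the rejection rate matches alpha up to binomial noise.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for rep in range(n_datasets):
        obs = [rng.normal(0.0, 1.0, n_obs) for _ in range(n_bins)]
        res = signflip_max_t_test(obs, n_permutations=n_permutations,
                                  seed=seed * 100_003 + rep)
        hits += bool(np.any(res.p_fwe <= alpha))
    rate = hits / n_datasets
    half = 1.96 * np.sqrt(alpha * (1 - alpha) / n_datasets)
    return {
        "familywise_rejection_rate": rate,
        "alpha": alpha,
        "n_datasets": n_datasets,
        "ci95_low": alpha - half,
        "ci95_high": alpha + half,
    }


def recovery_cohort(seed: int = 0, n_participants: int = 40,
                    n_permutations: int = 2000) -> dict:
    """Recover the injected phase-locked component at cohort scale.

    Forty participants, 5-minute sessions at 60 Hz with blinks, true
    amplitude 0.15 z peaking at 220 deg.  Runs the complete pipeline
    and summarizes how well the group statistics recover the injected
    minimum near inhalation onset and maximum during exhalation.
    """
    gen = GeneratorConfig(n_participants=n_participants, session_duration_s=300.0,
                          prp_amplitude=0.15, prp_peak_phase_deg=220.0, seed=seed)
    cfg = RunConfig(simulate=gen, n_permutations=n_permutations, seed=seed)
    report = run_pipeline(cfg)
    cond = report["conditions"]["nose"]
    p = np.array(cond["permutation"]["p_fwe"])
    t = np.array(cond["permutation"]["t_observed"])
    # bins whose centres flank the trough (40 deg) and the peak (220 deg)
    trough_bins = [1, 2]   # centres 30 and 50 deg
    peak_bins = [10, 11]   # centres 210 and 230 deg
    return {
        "group_direction_deg": cond["circular"]["group_direction_deg"],
        "proportion_toward_exhalation": cond["circular"]["proportion_toward_exhalation"],
        "rayleigh_p": cond["circular"]["rayleigh_p"],
        "trough_bins_significantly_negative": bool(
            all(p[b] <= 0.05 and t[b] < 0 for b in trough_bins)),
        "peak_bins_significantly_positive": bool(
            all(p[b] <= 0.05 and t[b] > 0 for b in peak_bins)),
        "max_trough_peak_p_fwe": float(max(p[b] for b in trough_bins + peak_bins)),
        "mean_breathing_rate_bpm": cond["mean_breathing_rate_bpm"],
        "n_participants": cond["n_participants"],
        "report": report,
    }


def derivative_telescoping(seed: int = 0) -> dict:
    """Telescoping identity of the per-bin derivative on a synthetic session.

    For every breathing cycle the per-bin derivative sums must equal the
    cycle's endpoint pupil difference; returns the maximum absolute
    violation across cycles.
    """
    cfg = GeneratorConfig(session_duration_s=120.0, blink_rate_per_min=0.0,
                          long_dropout_rate=0.0, noise_sd=0.3, seed=seed)
    rng = np.random.default_rng(seed)
    rec, truth = generate_recording(cfg, "P1", "S1", "nose", rng)
    phase = truth.phase_deg
    fin = np.isfinite(phase)
    bins = np.zeros(len(rec), dtype=int)
    bins[fin] = stats.assign_bins(phase[fin])
    cycle_id = np.full(len(rec), -1)
    t = rec.time_ms
    for c in range(len(truth.landmarks)):
        cycle_id[(t >= truth.landmarks.inhale_onset[c])
                 & (t < truth.landmarks.next_onset[c])] = c
    values = rec.pupil_left
    joint = fin & np.isfinite(values)
    cycles, per_bin_sums = stats.derivative_by_bin(values, bins, cycle_id, joint,
                                                   per_cycle=True)
    worst = 0.0
    for c, row in zip(cycles, per_bin_sums):
        # independent endpoint oracle for this cycle
        idx = np.flatnonzero(joint & (cycle_id == c))
        expected = values[idx[-1]] - values[idx[0]]
        worst = max(worst, abs(row.sum() - expected))
    return {"max_telescoping_error": worst, "n_cycles": int(len(cycles))}
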