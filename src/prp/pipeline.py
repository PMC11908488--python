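"""End-to-end orchestration: clean -> phase -> bin -> infer.

``run_pipeline`` executes the fixed stage order on a set of recordings
(loaded from canonical CSVs or freshly simulated), applies the
session-exclusion rule, z-scores at the participant level, joins pupil
and phase on the common time base, aggregates into 18 phase bins and
runs the inference battery per condition.  Everything in the returned
report is reproducible from the config and seed alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from prp import breath, stats
from prp.preprocess import (CleaningConfig, PupilTrace, clean_trace, combine_eyes,
                            session_excluded, validity_fraction, zscore_traces)
from prp.recordings import Recording, read_recording, write_results
from prp.simulate import GeneratorConfig, generate_cohort

STAGE_ORDER = (
    "validity_rules_initial", "remove_long_invalid", "interpolate",
    "rapid_change_recheck", "validity_rules_post", "outlier_mask",
    "exclusion_check", "eye_average", "zscore", "phase_join", "bin_aggregate",
    "inference",
)


@dataclass
class RunConfig:
    input_paths: list[str] = field(default_factory=list)
    simulate: GeneratorConfig | None = None
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    n_bins: int = 18
    n_permutations: int = 10000
    alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None
    permutation_pooling: str = "samples"  # or "participant_means"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.permutation_pooling not in ("samples", "participant_means"):
            raise ValueError("permutation_pooling must be 'samples' or 'participant_means'")


def _session_frames(rec: Recording, cfg: RunConfig) -> dict | None:
    """Clean one session; returns per-session intermediates or None if excluded."""
    left = PupilTrace(rec.pupil_left, rec.valid_left, rec.sampling_rate)
    right = PupilTrace(rec.pupil_right, rec.valid_right, rec.sampling_rate)
    cleft = clean_trace(left, cfg.cleaning)
    cright = clean_trace(right, cfg.cleaning)
    qc = {
        "participant": rec.participant_id,
        "session": rec.session_id,
        "condition": rec.route,
        "invalid_fraction_left": round(validity_fraction(cleft), 6),
        "invalid_fraction_right": round(validity_fraction(cright), 6),
        "excluded": False,
        "exclusion_rule": None,
    }
    if session_excluded(cleft, cright, cfg.cleaning):
        qc["excluded"] = True
        qc["exclusion_rule"] = (
            f"both eyes > {cfg.cleaning.max_invalid_fraction:.0%} invalid after interpolation"
        )
        return {"qc": qc}

    combined = combine_eyes(cleft, cright)

    filtered = breath.lowpass_airflow(rec.airflow, rec.sampling_rate)
    landmarks = breath.validate_cycles(breath.detect_landmarks(filtered, rec.sampling_rate, rec.time_ms))
    phase = breath.compute_phase(landmarks, rec.time_ms)
    return {
        "qc": qc,
        "combined": combined,
        "phase": phase,
        "landmarks": landmarks,
        "duration_s": rec.duration_s,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the machine-readable run report."""
    if config.simulate is not None:
        recordings, _ = generate_cohort(config.simulate)
    else:
        recordings = [read_recording(p) for p in config.input_paths]
        if not recordings:
            raise ValueError("no input recordings")

    sessions = []
    qc_rows = []
    for rec in recordings:
        out = _session_frames(rec, config)
        qc_rows.append(out["qc"])
        if "combined" in out:
            out["participant"] = rec.participant_id
            out["session"] = rec.session_id
            out["condition"] = rec.route
            sessions.append(out)
    if not sessions:
        raise RuntimeError(f"all sessions excluded by QC: {qc_rows}")

    # participant-level z-scoring over all included sessions of a participant
    by_participant: dict[str, list[int]] = {}
    for i, s in enumerate(sessions):
        by_participant.setdefault(s["participant"], []).append(i)
    for pid, idx in by_participant.items():
        zs = zscore_traces([sessions[i]["combined"] for i in idx])
        for i, z in zip(idx, zs):
            sessions[i]["z"] = z

    angles = stats.bin_centres_deg(config.n_bins)
    conditions = sorted({s["condition"] for s in sessions})
    results_rows = []
    report_conditions = {}
    two_way_cells = []

    for cond in conditions:
        cond_sessions = [s for s in sessions if s["condition"] == cond]
        pooled_obs: list[list[np.ndarray]] = [[] for _ in range(config.n_bins)]
        per_participant: dict[str, dict] = {}
        breathing_rates = []
        for s in cond_sessions:
            z: PupilTrace = s["z"]
            phase: breath.PhaseSeries = s["phase"]
            joint = z.valid & phase.valid
            bins = np.zeros(len(z), dtype=int)
            fin = np.isfinite(phase.phase_deg)
            bins[fin] = stats.assign_bins(phase.phase_deg[fin], config.n_bins)
            means, counts = stats.bin_means(z.values, bins, joint, config.n_bins)
            deriv = stats.derivative_by_bin(z.values, bins, phase.cycle_id, joint, config.n_bins)
            breathing_rates.append(breath.breathing_rate(s["landmarks"], s["duration_s"]))
            p = per_participant.setdefault(
                s["participant"],
                {"sum": np.zeros(config.n_bins), "n": np.zeros(config.n_bins),
                 "deriv": [], "sessions": 0})
            ok = counts > 0
            p["sum"][ok] += means[ok] * counts[ok]
            p["n"] += counts
            p["deriv"].append(deriv)
            p["sessions"] += 1
            for b in range(config.n_bins):
                sel = joint & (bins == b)
                if sel.any():
                    pooled_obs[b].append(z.values[sel])
            for b in range(config.n_bins):
                results_rows.append({
                    "participant": s["participant"], "session": s["session"],
                    "condition": cond, "bin_index": b,
                    "mean_z_pupil": means[b], "derivative_z": deriv[b],
                    "n_observations": int(counts[b]),
                })

        pids = sorted(per_participant)
        pm = np.full((len(pids), config.n_bins), np.nan)
        pderiv = np.full((len(pids), config.n_bins), np.nan)
        for i, pid in enumerate(pids):
            p = per_participant[pid]
            ok = p["n"] > 0
            pm[i, ok] = p["sum"][ok] / p["n"][ok]
            with np.errstate(invalid="ignore"):
                pderiv[i] = np.nanmean(np.vstack(p["deriv"]), axis=0)

        if config.permutation_pooling == "samples":
            obs = [np.concatenate(pooled_obs[b]) if pooled_obs[b] else np.zeros(0)
                   for b in range(config.n_bins)]
        else:
            obs = [pm[np.isfinite(pm[:, b]), b] for b in range(config.n_bins)]
        perm = stats.signflip_max_t_test(obs, config.n_permutations, config.seed)
        circ = stats.summarize_directions(pm, angles)

        cell_df = pd.DataFrame(
            [{"participant": pid, "bin": b, "mean_z": pm[i, b]}
             for i, pid in enumerate(pids) for b in range(config.n_bins)])
        try:
            anova = stats.rm_anova(cell_df, dv="mean_z", within=["bin"],
                                   subject="participant", alpha=config.alpha)
            anova_report = _anova_to_dict(anova)
        except ValueError as exc:
            anova_report = {"error": str(exc)}

        for i, pid in enumerate(pids):
            for b in range(config.n_bins):
                two_way_cells.append({"participant": pid, "condition": cond,
                                      "bin": b, "mean_z": pm[i, b]})

        report_conditions[cond] = {
            "n_participants": len(pids),
            "n_sessions": len(cond_sessions),
            "mean_breathing_rate_bpm": round(float(np.mean(breathing_rates)), 4),
            "bin_centres_deg": angles.tolist(),
            "group_bin_means": _roundlist(np.nanmean(pm, axis=0)),
            "group_bin_derivative": _roundlist(np.nanmean(pderiv, axis=0)),
            "permutation": {
                "t_observed": _roundlist(perm.t_observed),
                "p_fwe": _roundlist(perm.p_fwe),
                "n_permutations": perm.n_permutations,
                "seed": perm.seed,
                "pooling": config.permutation_pooling,
                "n_observations_per_bin": [int(len(o)) for o in obs],
            },
            "circular": {
                "mean_direction_deg": _roundlist(circ.mean_direction_deg),
                "group_direction_deg": round(circ.group_direction_deg, 6),
                "resultant_length": round(circ.resultant_length, 6),
                "rayleigh_p": round(circ.rayleigh_p, 9) if np.isfinite(circ.rayleigh_p) else None,
                "proportion_toward_exhalation": round(circ.proportion_toward_exhalation, 6),
            },
            "anova_phase": anova_report,
        }

    report = {
        "stage_order": list(STAGE_ORDER),
        "seed": config.seed,
        "n_bins": config.n_bins,
        "n_permutations": config.n_permutations,
        "alpha": config.alpha,
        "qc": qc_rows,
        "conditions": report_conditions,
    }

    if len(conditions) >= 2:
        df = pd.DataFrame(two_way_cells)
        try:
            res = stats.rm_anova(df, dv="mean_z", within=["bin", "condition"],
                                 subject="participant", alpha=config.alpha)
            report["anova_phase_by_condition"] = _anova_to_dict(res)
        except ValueError as exc:
            report["anova_phase_by_condition"] = {"error": str(exc)}

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results(pd.DataFrame(results_rows)[
            ["participant", "session", "bin_index", "mean_z_pupil",
             "derivative_z", "n_observations"]], out / "bin_table.tsv")
        (out / "run_report.json").write_text(report_json(report))
    return report


def _roundlist(a: np.ndarray, nd: int = 9) -> list:
    return [None if not np.isfinite(x) else round(float(x), nd) for x in np.asarray(a, dtype=float)]


def _anova_to_dict(res: stats.AnovaResult) -> dict:
    if res.fallback is not None:
        return {"friedman_fallback": res.fallback}
    out = {}
    for e in res.effects:
        out[e.name] = {
            "F": round(e.F, 6), "df_num": round(e.df_num, 6), "df_den": round(e.df_den, 6),
            "p": round(e.p, 9), "eta_squared": round(e.eta_squared, 6),
            "mauchly_W": None if e.mauchly_W is None else round(e.mauchly_W, 6),
            "mauchly_p": None if e.mauchly_p is None else round(e.mauchly_p, 9),
            "gg_epsilon": None if e.gg_epsilon is None else round(e.gg_epsilon, 6),
            "gg_corrected": e.corrected,
        }
    return out


def report_json(report: dict) -> str:
    """Canonical (byte-stable) JSON serialization of a run report."""
    return json.dumps(report, indent=2, sort_keys=True, allow_nan=False) + "\n"
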