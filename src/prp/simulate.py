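"""Synthetic recordings with known ground truth.

Generates cohorts of pupil + airflow sessions that emulate the study
conditions: ~5 min sessions at 60 Hz, breathing at a configurable rate
with variable cycle durations, a pupil trace carrying an optional
phase-locked cosine component (smallest near inhalation onset, largest
during exhalation), slow random-walk drift, Gaussian noise correlated
between the eyes, blink gaps, and rare long dropouts.  Ground truth
(landmarks, phase, injected component, blink intervals) is retained so
every pipeline stage can be checked against what was actually put in.

Airflow is built from half-sine inhalations and exhalations whose
amplitudes are balanced so each cycle has zero net flow (inhaled volume
equals exhaled volume), keeping the mean-centred zero crossings of the
detector aligned with the true onsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from prp.breath import BreathLandmarks
from prp.recordings import Recording


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the generator.

    Breathing-rate and pupil-baseline defaults follow resting human
    physiology (about 13 breaths/min with between-cycle SD ~3.6, mean
    pupil ~4.5 mm); the phase-locked component defaults to amplitude
    0.15 z peaking at 220 deg, i.e. mid-exhalation.
    """

    n_participants: int = 1
    sessions: tuple[str, ...] = ("nose",)  # condition label per session
    session_duration_s: float = 300.0
    rate_hz: float = 60.0
    breaths_per_min: float = 13.0
    breaths_per_min_sd: float = 3.6
    inhale_fraction: float = 0.45
    inhale_fraction_sd: float = 0.05
    prp_amplitude: float = 0.15
    prp_peak_phase_deg: float = 220.0
    noise_sd: float = 1.0
    drift_sd: float = 0.001  # random-walk step SD per sample, z units
    eye_noise_correlation: float = 0.8
    airflow_noise_sd: float = 0.05  # fraction of inhalation amplitude
    blink_rate_per_min: float = 12.0
    blink_duration_ms: tuple[float, float] = (100.0, 400.0)
    long_dropout_rate: float = 2.0  # per session, per eye
    long_dropout_ms: tuple[float, float] = (600.0, 2000.0)
    blink_spikes: bool = False  # artifact spikes flanking blink gaps
    baseline_mm: float = 4.5
    mm_per_z: float = 0.3
    amplitude_jitter_sd: float = 0.05  # between-participant, z units
    phase_jitter_sd_deg: float = 20.0  # between-participant
    min_cycle_s: float = 1.2
    max_cycle_s: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.session_duration_s, self.rate_hz, self.breaths_per_min) <= 0:
            raise ValueError("rates and durations must be positive")
        if not 0.2 < self.inhale_fraction < 0.8:
            raise ValueError("inhale_fraction must lie in (0.2, 0.8)")
        if not 0 <= self.prp_peak_phase_deg < 360:
            raise ValueError("prp_peak_phase_deg must lie in [0, 360)")


@dataclass
class GroundTruth:
    """What was injected into one session, sample-for-sample."""

    landmarks: BreathLandmarks
    phase_deg: np.ndarray  # NaN outside generated cycles
    prp_component_z: np.ndarray
    amplitude_z: float
    peak_phase_deg: float
    blink_intervals_ms: list[tuple[float, float]]
    dropout_intervals_ms: dict[str, list[tuple[float, float]]]


def _cycle_durations(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Cycle durations (s) matching the configured breaths/min."""
    mean_t = 60.0 / cfg.breaths_per_min
    # delta-method SD of the period implied by the breaths/min SD
    sd_t = 60.0 * cfg.breaths_per_min_sd / cfg.breaths_per_min**2
    n_max = int(np.ceil(cfg.session_duration_s / max(cfg.min_cycle_s, 1e-6))) + 2
    if sd_t == 0:
        durations = np.full(n_max, mean_t)
    else:
        durations = rng.normal(mean_t, sd_t, size=n_max)
    durations = np.clip(durations, cfg.min_cycle_s, cfg.max_cycle_s)
    ends = np.cumsum(durations)
    n = int(np.searchsorted(ends, cfg.session_duration_s)) + 1
    return durations[:n]


def generate_breathing(cfg: GeneratorConfig, rng: np.random.Generator
                       ) -> tuple[np.ndarray, BreathLandmarks, np.ndarray]:
    """Airflow series plus true landmarks and true per-sample phase."""
    n = int(round(cfg.session_duration_s * cfg.rate_hz))
    t_ms = np.arange(n) * 1000.0 / cfg.rate_hz
    airflow = np.zeros(n)
    phase = np.full(n, np.nan)

    durations = _cycle_durations(cfg, rng)
    if cfg.inhale_fraction_sd > 0:
        fracs = np.clip(rng.normal(cfg.inhale_fraction, cfg.inhale_fraction_sd,
                                   size=len(durations)), 0.2, 0.8)
    else:
        fracs = np.full(len(durations), cfg.inhale_fraction)

    cycles = []
    t0 = 0.0
    for dur_s, frac in zip(durations, fracs):
        ti = dur_s * frac * 1000.0
        te = dur_s * (1 - frac) * 1000.0
        start, end = t0, t0 + ti + te
        sel = (t_ms >= start) & (t_ms < end)
        tt = t_ms[sel] - start
        inhale = tt < ti
        wave = np.where(
            inhale,
            np.sin(np.pi * tt / ti),
            -(ti / te) * np.sin(np.pi * (tt - ti) / np.maximum(te, 1e-9)),
        )
        airflow[sel] = wave
        knots_t = np.array([0.0, ti / 2, ti, ti + te / 2, ti + te])
        phase[sel] = np.interp(tt, knots_t, [0.0, 90.0, 180.0, 270.0, 360.0]) % 360.0
        cycles.append((start, start + ti / 2, start + ti, start + ti + te / 2, end))
        t0 = end
        if t0 >= t_ms[-1]:
            break

    # drop the trailing cycle if it ran past the recording
    complete = [c for c in cycles if c[4] <= t_ms[-1] + 1000.0 / cfg.rate_hz]
    truncated_at = complete[-1][4] if complete else 0.0
    phase[t_ms >= truncated_at] = np.nan
    arr = np.array(complete)
    landmarks = BreathLandmarks(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4])
    if cfg.airflow_noise_sd > 0:
        airflow = airflow + rng.normal(0, cfg.airflow_noise_sd, size=n)
    return airflow, landmarks, phase


def generate_pupil(phase_deg: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator,
                   amplitude_z: float | None = None, peak_phase_deg: float | None = None
                   ) -> tuple[dict, np.ndarray]:
    """Two-eye pupil traces (mm) around the phase-locked component.

    Returns a dict with per-eye value arrays, validity masks and the
    injected interval bookkeeping, plus the phase-locked component in z
    units.
    """
    n = len(phase_deg)
    a = cfg.prp_amplitude if amplitude_z is None else amplitude_z
    peak = cfg.prp_peak_phase_deg if peak_phase_deg is None else peak_phase_deg
    theta = np.deg2rad(np.where(np.isfinite(phase_deg), phase_deg, 0.0))
    prp = a * np.cos(theta - np.deg2rad(peak))
    prp[~np.isfinite(phase_deg)] = 0.0

    drift = np.cumsum(rng.normal(0, cfg.drift_sd, size=n)) if cfg.drift_sd > 0 else 0.0
    rho = cfg.eye_noise_correlation
    shared = rng.normal(0, 1, size=n)
    z_eyes = {}
    for eye in ("left", "right"):
        own = rng.normal(0, 1, size=n)
        noise = cfg.noise_sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * own)
        z_eyes[eye] = prp + drift + noise

    dt_ms = 1000.0 / cfg.rate_hz
    total_ms = n * dt_ms

    def draw_intervals(rate_per_min: float, dur_range: tuple[float, float]) -> list[tuple[float, float]]:
        count = rng.poisson(rate_per_min * total_ms / 60000.0)
        out = []
        for _ in range(count):
            start = rng.uniform(0, total_ms)
            out.append((start, start + rng.uniform(*dur_range)))
        return sorted(out)

    blink_intervals = draw_intervals(cfg.blink_rate_per_min, cfg.blink_duration_ms)
    t_ms = np.arange(n) * dt_ms
    values, valid = {}, {}
    dropouts: dict[str, list[tuple[float, float]]] = {}
    for eye in ("left", "right"):
        v = np.ones(n, dtype=bool)
        vals = cfg.baseline_mm + cfg.mm_per_z * z_eyes[eye]
        for s, e in blink_intervals:
            sel = (t_ms >= s) & (t_ms < e)
            v[sel] = False
            if cfg.blink_spikes and sel.any():
                idx = np.flatnonzero(sel)
                lo, hi = idx[0] - 1, idx[-1] + 1
                if lo >= 0:
                    vals[lo] -= 10 * cfg.mm_per_z
                if hi < n:
                    vals[hi] -= 10 * cfg.mm_per_z
        per_session = cfg.long_dropout_rate / max(total_ms / 60000.0, 1e-9)
        eye_drop = draw_intervals(per_session, cfg.long_dropout_ms)
        for s, e in eye_drop:
            v[(t_ms >= s) & (t_ms < e)] = False
        dropouts[eye] = eye_drop
        vals[~v] = np.nan
        values[eye] = vals
        valid[eye] = v
    return (
        {"values": values, "valid": valid, "blinks": blink_intervals, "dropouts": dropouts},
        prp,
    )


def generate_recording(cfg: GeneratorConfig, participant_id: str, session_id: str,
                       route: str, rng: np.random.Generator,
                       amplitude_z: float | None = None,
                       peak_phase_deg: float | None = None
                       ) -> tuple[Recording, GroundTruth]:
    airflow, landmarks, phase = generate_breathing(cfg, rng)
    pupil, prp = generate_pupil(phase, cfg, rng, amplitude_z, peak_phase_deg)
    n = len(airflow)
    rec = Recording(
        participant_id=participant_id,
        session_id=session_id,
        route=route,
        sampling_rate=cfg.rate_hz,
        time_ms=np.arange(n) * 1000.0 / cfg.rate_hz,
        pupil_left=pupil["values"]["left"],
        pupil_right=pupil["values"]["right"],
        valid_left=pupil["valid"]["left"],
        valid_right=pupil["valid"]["right"],
        airflow=airflow,
        unit="mm",
        meta={"generator": "prp.simulate"},
    )
    truth = GroundTruth(
        landmarks=landmarks,
        phase_deg=phase,
        prp_component_z=prp,
        amplitude_z=cfg.prp_amplitude if amplitude_z is None else amplitude_z,
        peak_phase_deg=cfg.prp_peak_phase_deg if peak_phase_deg is None else peak_phase_deg,
        blink_intervals_ms=pupil["blinks"],
        dropout_intervals_ms=pupil["dropouts"],
    )
    _assert_consistent(rec, truth)
    return rec, truth


def _assert_consistent(rec: Recording, truth: GroundTruth) -> None:
    """Emitted flags must match the injected blink/dropout intervals."""
    t = rec.time_ms
    expect_invalid = np.zeros(len(rec), dtype=bool)
    for s, e in truth.blink_intervals_ms:
        expect_invalid |= (t >= s) & (t < e)
    both = {"left": expect_invalid.copy(), "right": expect_invalid.copy()}
    for eye in ("left", "right"):
        for s, e in truth.dropout_intervals_ms[eye]:
            both[eye] |= (t >= s) & (t < e)
    assert np.array_equal(~rec.valid_left, both["left"])
    assert np.array_equal(~rec.valid_right, both["right"])


def generate_cohort(cfg: GeneratorConfig) -> tuple[list[Recording], dict[tuple[str, str], GroundTruth]]:
    """Generate ``n_participants`` x ``sessions`` recordings.

    Each participant gets a jittered phase-locked amplitude and peak
    phase (between-subject spread); all randomness descends from
    ``cfg.seed`` through per-participant child streams, so output is
    reproducible regardless of generation order.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_participants)
    recordings: list[Recording] = []
    truths: dict[tuple[str, str], GroundTruth] = {}
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        pid = f"P{i + 1:03d}"
        amp = max(0.0, cfg.prp_amplitude + (rng.normal(0, cfg.amplitude_jitter_sd)
                                            if cfg.amplitude_jitter_sd > 0 else 0.0))
        peak = (cfg.prp_peak_phase_deg + (rng.normal(0, cfg.phase_jitter_sd_deg)
                                          if cfg.phase_jitter_sd_deg > 0 else 0.0)) % 360.0
        if cfg.prp_amplitude == 0:
            amp = 0.0
        for j, route in enumerate(cfg.sessions):
            sid = f"S{j + 1}"
            rec, truth = generate_recording(cfg, pid, sid, route, rng, amp, peak)
            recordings.append(rec)
            truths[(pid, sid)] = truth
    return recordings, truths
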