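"""Respiratory landmark detection and phase construction.

An airflow trace (inspiration-positive) is low-pass filtered at 5 Hz,
mean-centred, and segmented at zero crossings: negative-to-positive
crossings are inhalation onsets, positive-to-negative crossings are
exhalation onsets; the extremum between consecutive onsets gives the
inhalation peak / exhalation trough.  Each sample then receives a phase
angle by piecewise-linear interpolation: inhalation onset = 0deg,
inhalation peak = 90deg, exhalation onset = 180deg, exhalation peak =
270deg, wrapping to 0 at the next inhalation onset.  Half-breaths
shorter than 500 ms or longer than 6000 ms are invalid and contribute
no observations downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

MIN_HALF_BREATH_MS = 500.0
MAX_HALF_BREATH_MS = 6000.0


@dataclass
class BreathLandmarks:
    """Per-cycle landmark timestamps in ms.

    A cycle runs from one inhalation onset to the next; the end of cycle
    ``i`` is ``inhale_onset[i + 1]`` (the last cycle is dropped if it
    has no successor).  ``valid_inhale`` / ``valid_exhale`` flag the two
    half-breaths of each cycle.
    """

    inhale_onset: np.ndarray
    inhale_peak: np.ndarray
    exhale_onset: np.ndarray
    exhale_peak: np.ndarray
    next_onset: np.ndarray
    valid_inhale: np.ndarray = None  # type: ignore[assignment]
    valid_exhale: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.inhale_onset)
        if self.valid_inhale is None:
            self.valid_inhale = np.ones(n, dtype=bool)
        if self.valid_exhale is None:
            self.valid_exhale = np.ones(n, dtype=bool)
        stacked = np.column_stack(
            [self.inhale_onset, self.inhale_peak, self.exhale_onset,
             self.exhale_peak, self.next_onset])
        if n and not np.all(np.diff(stacked, axis=1) > 0):
            raise ValueError("landmarks within a cycle must be strictly ordered")
        # cycles are ordered; gaps are allowed where degenerate cycles were dropped
        if n > 1 and not np.all(self.next_onset[:-1] <= self.inhale_onset[1:] + 1e-9):
            raise ValueError("cycles must be ordered and non-overlapping")

    def __len__(self) -> int:
        return len(self.inhale_onset)

    @property
    def inhale_duration_ms(self) -> np.ndarray:
        return self.exhale_onset - self.inhale_onset

    @property
    def exhale_duration_ms(self) -> np.ndarray:
        return self.next_onset - self.exhale_onset


@dataclass
class PhaseSeries:
    """Per-sample respiratory phase in [0, 360) with cycle membership."""

    phase_deg: np.ndarray
    cycle_id: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.phase_deg)


def lowpass_airflow(signal: np.ndarray, rate: float, cutoff: float = 5.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass with unit DC gain."""
    if rate <= 2 * cutoff:
        raise ValueError(f"sampling rate {rate} Hz too low for a {cutoff} Hz cutoff")
    b, a = butter(4, cutoff / (rate / 2.0), btype="low")
    return filtfilt(b, a, np.asarray(signal, dtype=float))


def detect_landmarks(
    airflow: np.ndarray,
    rate: float,
    time_ms: np.ndarray | None = None,
    inspiration_positive: bool = True,
    debounce_ms: float = 250.0,
) -> BreathLandmarks:
    """Segment a (filtered) airflow trace into breathing cycles.

    The signal is mean-centred so that slow sensor offsets do not bias
    the crossings; crossings closer than ``debounce_ms`` to the previous
    accepted crossing are discarded as noise-driven micro-cycles.
    Incomplete leading/trailing half-cycles are dropped.
    """
    x = np.asarray(airflow, dtype=float)
    if not inspiration_positive:
        x = -x
    if time_ms is None:
        time_ms = np.arange(len(x)) * 1000.0 / rate
    time_ms = np.asarray(time_ms, dtype=float)
    x = x - x.mean()

    sign = np.sign(x)
    sign[sign == 0] = 1
    crossing_idx = np.flatnonzero(np.diff(sign) != 0) + 1  # first sample after crossing
    if len(crossing_idx) == 0:
        raise ValueError("no breathing detected: airflow never crosses zero")

    # debounce: drop crossings too close to the last accepted one
    kept: list[int] = []
    for i in crossing_idx:
        if kept and (time_ms[i] - time_ms[kept[-1]]) < debounce_ms:
            continue
        kept.append(int(i))
    up = [i for i in kept if x[i] > 0]
    down = [i for i in kept if x[i] < 0]
    if len(up) < 2:
        raise ValueError("no breathing detected: fewer than 2 inhalation onsets")

    cross_t = np.array([time_ms[i] for i in kept], dtype=float)
    for span, step in ((40.0, 2.0), (8.0, 0.5)):
        cross_t = _refine_crossings(x, time_ms, cross_t, span, step)
    refined = dict(zip(kept, cross_t))

    cycles = []
    for k in range(len(up) - 1):
        on, nxt = up[k], up[k + 1]
        mids = [j for j in down if on < j < nxt]
        if not mids:
            continue
        exh = mids[0]
        ipk = on + int(np.argmax(x[on:exh]))
        epk = exh + int(np.argmin(x[exh:nxt]))
        t_on, t_exh, t_nxt = refined[on], refined[exh], refined[nxt]
        t_ipk = _refine_extremum(x, time_ms, ipk, rate, t_on, t_exh)
        t_epk = _refine_extremum(x, time_ms, epk, rate, t_exh, t_nxt)
        if not t_on < t_ipk < t_exh < t_epk < t_nxt:
            continue  # degenerate segment (e.g. peak on the boundary)
        cycles.append((t_on, t_ipk, t_exh, t_epk, t_nxt))
    if not cycles:
        raise ValueError("no breathing detected: no complete cycles")
    arr = np.array(cycles)
    return BreathLandmarks(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4])


def _refine_crossings(x: np.ndarray, time_ms: np.ndarray, cross_t: np.ndarray,
                      span_ms: float, step_ms: float) -> np.ndarray:
    """Sub-sample crossing times by fitting half-sine templates.

    Smoothed airflow between consecutive zero crossings is close to a
    half-sine of free amplitude.  For each interior crossing the
    candidate time t0 minimizing the residual sum of squares of the two
    flanking half-sine fits (over [previous, t0] and [t0, next]) is
    searched on a grid around the current estimate; the first and last
    crossings keep their coarse times.  One refinement pass uses the
    neighbours' current estimates, so the caller iterates.
    """
    out = cross_t.copy()
    for k in range(1, len(cross_t) - 1):
        tp, tc, tn = cross_t[k - 1], cross_t[k], cross_t[k + 1]
        best_ss, best_t0 = np.inf, tc
        for t0 in np.arange(tc - span_ms, tc + span_ms + step_ms / 2, step_ms):
            ss = 0.0
            for a, b in ((tp, t0), (t0, tn)):
                lo = int(np.searchsorted(time_ms, a))
                hi = int(np.searchsorted(time_ms, b))
                if b - a < 100.0 or hi - lo < 3:
                    ss = np.inf
                    break
                s = np.sin(np.pi * (time_ms[lo:hi] - a) / (b - a))
                y = x[lo:hi]
                amp = float(s @ y) / float(s @ s)
                r = y - amp * s
                ss += float(r @ r)
            if ss < best_ss:
                best_ss, best_t0 = ss, t0
        if np.isfinite(best_ss):
            out[k] = best_t0
    return out


def _refine_extremum(x: np.ndarray, time_ms: np.ndarray, idx: int, rate: float,
                     t_left: float, t_right: float,
                     half_window_ms: float = 400.0) -> float:
    """Sub-sample extremum time by an iterated local quadratic vertex fit.

    The window is recentred on the previous vertex estimate once (a
    symmetric window makes the parabola vertex of a smooth extremum
    unbiased).  The vertex is clipped into the (t_left, t_right)
    segment; a degenerate fit falls back to the coarse sample.
    """
    n = len(x)
    hw = int(round(half_window_ms * rate / 1000.0))
    centre = idx
    vertex = float(time_ms[idx])
    for _ in range(2):
        lo, hi = max(centre - hw, 0), min(centre + hw + 1, n)
        t = time_ms[lo:hi] - time_ms[centre]
        y = x[lo:hi]
        if len(t) < 5:
            return float(time_ms[idx])
        a, b, _ = np.polyfit(t, y, 2)
        if a == 0:
            return float(time_ms[idx])
        vertex = float(time_ms[centre]) - b / (2 * a)
        eps = 1.0  # keep strictly inside the segment (ms)
        vertex = float(np.clip(vertex, t_left + eps, t_right - eps))
        centre = int(np.clip(np.searchsorted(time_ms, vertex), 0, n - 1))
    return vertex


def validate_cycles(landmarks: BreathLandmarks) -> BreathLandmarks:
    """Flag half-breaths outside [500, 6000] ms as invalid."""
    lm = BreathLandmarks(
        landmarks.inhale_onset.copy(), landmarks.inhale_peak.copy(),
        landmarks.exhale_onset.copy(), landmarks.exhale_peak.copy(),
        landmarks.next_onset.copy(),
    )
    di = lm.inhale_duration_ms
    de = lm.exhale_duration_ms
    lm.valid_inhale = (di >= MIN_HALF_BREATH_MS) & (di <= MAX_HALF_BREATH_MS)
    lm.valid_exhale = (de >= MIN_HALF_BREATH_MS) & (de <= MAX_HALF_BREATH_MS)
    return lm


def compute_phase(landmarks: BreathLandmarks, time_ms: np.ndarray) -> PhaseSeries:
    """Piecewise-linear phase angle for every timestamp.

    Within each cycle the four quarter segments map linearly to
    [0, 90], [90, 180], [180, 270] and [270, 360) degrees; 360 wraps to
    0.  Samples outside detected cycles, or inside an invalid
    half-breath, are flagged invalid.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    n = len(time_ms)
    phase = np.full(n, np.nan)
    cycle_id = np.full(n, -1, dtype=int)
    valid = np.zeros(n, dtype=bool)

    for c in range(len(landmarks)):
        knots_t = np.array([
            landmarks.inhale_onset[c], landmarks.inhale_peak[c],
            landmarks.exhale_onset[c], landmarks.exhale_peak[c],
            landmarks.next_onset[c],
        ])
        knots_p = np.array([0.0, 90.0, 180.0, 270.0, 360.0])
        # half-open cycle [onset, next_onset)
        sel = (time_ms >= knots_t[0]) & (time_ms < knots_t[-1])
        if not sel.any():
            continue
        p = np.interp(time_ms[sel], knots_t, knots_p)
        phase[sel] = np.mod(p, 360.0)
        cycle_id[sel] = c
        inhale = p < 180.0
        ok = np.where(inhale, landmarks.valid_inhale[c], landmarks.valid_exhale[c])
        valid[sel] = ok
    return PhaseSeries(phase, cycle_id, valid)


def breathing_rate(landmarks: BreathLandmarks, duration_s: float) -> float:
    """Valid inhalation onsets per minute over the recording."""
    n_valid = int(np.sum(landmarks.valid_inhale))
    if n_valid == 0:
        raise ValueError("no valid breathing cycles")
    return n_valid / duration_s * 60.0
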