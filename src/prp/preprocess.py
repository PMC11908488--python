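"""Staged pupil-trace cleaning.

The cleaning pipeline follows a fixed order, applied separately to each
eye:

1. initial validity rules (short valid runs, isolated valid islands)
2. removal of long invalid stretches (too long to be blinks)
3. buffered piecewise-cubic-spline gap interpolation with range guards
4. rapid-change detection and re-interpolation
5. post-interpolation validity rules (incl. the long-island rule)
6. +/-3 SD outlier masking
7. finalization: every sample ends up exactly valid or removed

All durations are configured in milliseconds and converted to sample
counts through the trace's sampling rate.  Validity is authoritative
throughout: no stage ever changes the numeric value of a sample that is
valid both before and after the stage; interpolation writes only to
invalid samples and to the buffer frames it first marks invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass
class PupilTrace:
    """One eye's pupil time series with validity bookkeeping.

    ``valid`` marks samples that are usable right now; ``removed`` marks
    samples that are permanently missing and must never be interpolated
    (long dropouts, finalized residual gaps).  ``removed`` implies not
    ``valid``.  Values of non-valid samples are ignored downstream.
    """

    values: np.ndarray
    valid: np.ndarray
    sampling_rate: float
    removed: np.ndarray = None  # type: ignore[assignment]
    interpolated: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.removed is None:
            self.removed = np.zeros_like(self.valid)
        if self.interpolated is None:
            self.interpolated = np.zeros_like(self.valid)
        if not (len(self.values) == len(self.valid) == len(self.removed)):
            raise ValueError("values/valid/removed must have equal length")
        if np.any(self.valid & self.removed):
            raise ValueError("a removed sample cannot be valid")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    def copy(self) -> "PupilTrace":
        return PupilTrace(
            self.values.copy(), self.valid.copy(), self.sampling_rate,
            self.removed.copy(), self.interpolated.copy(),
        )

    def ms_to_samples(self, ms: float) -> float:
        return ms * self.sampling_rate / 1000.0

    def samples_to_ms(self, n: int) -> float:
        return n * 1000.0 / self.sampling_rate


@dataclass
class CleaningConfig:
    """Thresholds of the cleaning rules (durations in ms)."""

    min_valid_ms: float = 250.0
    island_valid_ms: float = 500.0
    island_context_ms: float = 2000.0
    long_island_valid_ms: float = 1000.0
    long_island_context_ms: float = 5000.0
    max_blink_ms: float = 500.0
    buffer_frames: int = 2
    spline_range_tolerance: float = 0.30
    recheck_range_tolerance: float = 0.20
    flank_samples: int = 3
    max_anchor_distance_ms: float = 2000.0
    outlier_sd: float = 3.0
    max_invalid_fraction: float = 0.30
    speed_mad_multiplier: float = 16.0

    def __post_init__(self) -> None:
        for name in ("min_valid_ms", "island_valid_ms", "island_context_ms",
                     "long_island_valid_ms", "long_island_context_ms",
                     "max_blink_ms", "max_anchor_distance_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.max_invalid_fraction < 1:
            raise ValueError("max_invalid_fraction must be in (0,1)")
        if min(self.spline_range_tolerance, self.recheck_range_tolerance,
               self.outlier_sd, self.speed_mad_multiplier) <= 0:
            raise ValueError("tolerances must be positive")


def _runs(mask: np.ndarray) -> np.ndarray:
    """Maximal runs of True, as an (n, 2) array of [start, stop)."""
    padded = np.concatenate(([0], mask.astype(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    return edges.reshape(-1, 2)


def mark_unreliable_valid_stretches(
    trace: PupilTrace, cfg: CleaningConfig, stage: str = "initial"
) -> PupilTrace:
    """Invalidate valid runs that are too short or too isolated.

    A maximal valid run shorter than ``min_valid_ms`` is invalidated.
    Valid runs shorter than ``island_valid_ms`` flanked on *both* sides
    by invalid runs longer than ``island_context_ms`` are invalidated.
    In the ``post_interpolation`` stage the analogous long-island rule
    (``long_island_valid_ms`` / ``long_island_context_ms``) applies too.
    """
    if stage not in ("initial", "post_interpolation"):
        raise ValueError(f"unknown stage {stage!r}")
    out = trace.copy()

    # rule 1: short valid runs
    valid_runs = _runs(out.valid)
    for s, e in valid_runs:
        if out.samples_to_ms(e - s) < cfg.min_valid_ms:
            out.valid[s:e] = False

    # rules 2(+3): isolated valid islands, on the updated mask
    island_rules = [(cfg.island_valid_ms, cfg.island_context_ms)]
    if stage == "post_interpolation":
        island_rules.append((cfg.long_island_valid_ms, cfg.long_island_context_ms))
    for max_len_ms, context_ms in island_rules:
        valid_runs = _runs(out.valid)
        n = len(out)
        for i, (s, e) in enumerate(valid_runs):
            if out.samples_to_ms(e - s) >= max_len_ms:
                continue
            left_start = valid_runs[i - 1][1] if i > 0 else 0
            right_stop = valid_runs[i + 1][0] if i + 1 < len(valid_runs) else n
            left_len = s - left_start
            right_len = right_stop - e
            # both flanks must be actual invalid data longer than the context
            if (left_len > 0 and right_len > 0
                    and out.samples_to_ms(left_len) > context_ms
                    and out.samples_to_ms(right_len) > context_ms):
                out.valid[s:e] = False
    return out


def remove_long_invalid(trace: PupilTrace, cfg: CleaningConfig) -> PupilTrace:
    """Permanently remove invalid stretches too long to be blinks."""
    out = trace.copy()
    for s, e in _runs(~out.valid):
        if out.samples_to_ms(e - s) > cfg.max_blink_ms:
            out.removed[s:e] = True
    return out


def _flank_anchors(valid: np.ndarray, gap_start: int, gap_stop: int,
                   n_anchors: int, max_dist: int) -> tuple[np.ndarray, np.ndarray] | None:
    """Nearest valid anchor indices on each side of [gap_start, gap_stop).

    Anchors need not be contiguous; intervening invalid samples are
    skipped.  Returns None when either side lacks ``n_anchors`` valid
    samples within ``max_dist`` samples of the gap edge.
    """
    left = np.flatnonzero(valid[:gap_start])[-n_anchors:]
    right = gap_stop + np.flatnonzero(valid[gap_stop:])[:n_anchors]
    if len(left) < n_anchors or len(right) < n_anchors:
        return None
    if gap_start - left[0] > max_dist or right[-1] - (gap_stop - 1) > max_dist:
        return None
    return left, right


def interpolate_gaps(trace: PupilTrace, cfg: CleaningConfig, mode: str = "first_pass") -> PupilTrace:
    """Fill non-removed invalid runs by buffered cubic-spline interpolation.

    Each gap is extended by ``buffer_frames`` on both sides; a cubic
    spline through the ``flank_samples`` nearest valid samples on each
    side fills the extended gap.  If the range of the filled values
    exceeds the anchor range by more than the stage tolerance (30% on
    the first pass, 20% on rechecks), the fit is retried with 3 and then
    4 buffer frames; if it still fails, the gap proper is filled
    linearly through the two buffer frames and the flank anchors.  Gaps
    touching the trace edge or lacking anchors stay invalid.
    """
    if mode not in ("first_pass", "recheck"):
        raise ValueError(f"unknown mode {mode!r}")
    tol = cfg.spline_range_tolerance if mode == "first_pass" else cfg.recheck_range_tolerance
    out = trace.copy()
    n = len(out)
    max_dist = int(np.ceil(out.ms_to_samples(cfg.max_anchor_distance_ms)))

    for s, e in _runs(~out.valid & ~out.removed):
        if np.all(out.valid[s:e]):  # already filled by a neighbouring extension
            continue
        filled = False
        for nbuf in (cfg.buffer_frames, 3, 4):
            gs, ge = s - nbuf, e + nbuf
            if gs < 0 or ge > n:
                break  # edge gap: unfillable
            anchors = _flank_anchors(out.valid & ~_span_mask(n, gs, ge),
                                     gs, ge, cfg.flank_samples, max_dist)
            if anchors is None:
                break
            left, right = anchors
            x = np.concatenate([left, right])
            y = out.values[x]
            fill_x = np.arange(gs, ge)
            fill_y = CubicSpline(x, y)(fill_x)
            anchor_range = y.max() - y.min()
            if fill_y.max() - fill_y.min() <= anchor_range * (1.0 + tol):
                out.values[gs:ge] = fill_y
                out.valid[gs:ge] = True
                out.interpolated[gs:ge] = True
                filled = True
                break
        else:
            # linear fallback: two buffer frames + flank anchors as knots
            nbuf = cfg.buffer_frames
            gs, ge = s - nbuf, e + nbuf
            anchors = _flank_anchors(out.valid & ~_span_mask(n, gs, ge),
                                     gs, ge, cfg.flank_samples, max_dist)
            left, right = anchors  # existed for the spline attempts
            knots = np.concatenate([left, np.arange(gs, s), np.arange(e, ge), right])
            knots.sort()
            fill_x = np.arange(s, e)
            out.values[s:e] = np.interp(fill_x, knots, out.values[knots])
            out.valid[s:e] = True
            out.interpolated[s:e] = True
            filled = True
        if not filled:
            continue  # stays invalid; promoted to removed at finalization
    return out


def _span_mask(n: int, start: int, stop: int) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    m[max(start, 0):min(stop, n)] = True
    return m


def detect_rapid_changes(trace: PupilTrace, cfg: CleaningConfig) -> np.ndarray:
    """Flag samples in stretches of implausibly fast pupil-size change.

    A sample pair is flagged when the absolute first difference exceeds
    ``speed_mad_multiplier`` times the median absolute deviation of the
    first differences over valid samples; flags are dilated by
    ``buffer_frames``.  An all-constant trace yields an empty mask.
    """
    if int(trace.valid.sum()) < 10:
        raise ValueError("need at least 10 valid samples")
    d = np.diff(trace.values)
    pair_valid = trace.valid[1:] & trace.valid[:-1]
    dv = d[pair_valid]
    mad = np.median(np.abs(dv - np.median(dv)))
    thr = cfg.speed_mad_multiplier * mad
    hit = pair_valid & (np.abs(d) > thr) & (np.abs(d) > 0)
    mask = np.zeros(len(trace), dtype=bool)
    mask[:-1] |= hit
    mask[1:] |= hit
    if mask.any() and cfg.buffer_frames:
        k = cfg.buffer_frames
        idx = np.flatnonzero(mask)
        for i in idx:
            mask[max(0, i - k):i + k + 1] = True
    return mask


def mask_outliers(trace: PupilTrace, cfg: CleaningConfig) -> PupilTrace:
    """Invalidate valid samples outside mean +/- ``outlier_sd`` SD.

    Mean and (population) SD are computed over this trace's valid
    samples.  A zero-variance trace is returned unchanged.
    """
    if int(trace.valid.sum()) < 2:
        raise ValueError("need at least 2 valid samples")
    out = trace.copy()
    v = out.values[out.valid]
    mu, sd = v.mean(), v.std()
    if sd == 0:
        return out
    bad = out.valid & (np.abs(out.values - mu) > cfg.outlier_sd * sd)
    out.valid[bad] = False
    return out


def finalize_trace(trace: PupilTrace) -> PupilTrace:
    """Promote every residual invalid sample to removed."""
    out = trace.copy()
    out.removed[~out.valid] = True
    return out


def validity_fraction(trace: PupilTrace) -> float:
    """Fraction of samples that are invalid or removed."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    return float(np.mean(~trace.valid))


def session_excluded(left: PupilTrace, right: PupilTrace, cfg: CleaningConfig) -> bool:
    """Exclude a session only when BOTH eyes exceed the invalid budget."""
    return (validity_fraction(left) > cfg.max_invalid_fraction
            and validity_fraction(right) > cfg.max_invalid_fraction)


def clean_trace(trace: PupilTrace, cfg: CleaningConfig | None = None) -> PupilTrace:
    """Run the full fixed-order cleaning pipeline on one eye's trace."""
    cfg = cfg or CleaningConfig()
    t = mark_unreliable_valid_stretches(trace, cfg, stage="initial")
    t = remove_long_invalid(t, cfg)
    t = interpolate_gaps(t, cfg, mode="first_pass")
    if int(t.valid.sum()) >= 10:
        rapid = detect_rapid_changes(t, cfg)
        if rapid.any():
            t.valid[rapid & ~t.removed] = False
            t = interpolate_gaps(t, cfg, mode="recheck")
    t = mark_unreliable_valid_stretches(t, cfg, stage="post_interpolation")
    if int(t.valid.sum()) >= 2:
        t = mask_outliers(t, cfg)
    return finalize_trace(t)


def combine_eyes(left: PupilTrace, right: PupilTrace, mode: str = "any_valid") -> PupilTrace:
    """Average the two eyes samplewise.

    Where both eyes are valid the mean is used; where exactly one is
    valid, ``any_valid`` (default) keeps that eye's value while
    ``both_valid`` drops the sample; where neither is valid the sample
    is invalid.
    """
    if len(left) != len(right):
        raise ValueError("eye traces differ in length")
    if left.sampling_rate != right.sampling_rate:
        raise ValueError("eye traces differ in sampling rate")
    n = len(left)
    values = np.full(n, np.nan)
    both = left.valid & right.valid
    values[both] = 0.5 * (left.values[both] + right.values[both])
    valid = both.copy()
    if mode == "any_valid":
        only_l = left.valid & ~right.valid
        only_r = right.valid & ~left.valid
        values[only_l] = left.values[only_l]
        values[only_r] = right.values[only_r]
        valid |= only_l | only_r
    elif mode != "both_valid":
        raise ValueError(f"unknown mode {mode!r}")
    return PupilTrace(values, valid, left.sampling_rate,
                      removed=~valid, interpolated=left.interpolated | right.interpolated)


def zscore_traces(traces: list[PupilTrace]) -> list[PupilTrace]:
    """z-score traces against their pooled valid samples.

    Pass one trace for session scope, or all of a participant's session
    traces for participant scope.  Uses the population SD (divisor n).
    The pooled valid samples of the output have mean 0 and SD 1.
    """
    pooled = np.concatenate([t.values[t.valid] for t in traces])
    if len(pooled) < 2:
        raise ValueError("need at least 2 valid samples to z-score")
    mu, sd = pooled.mean(), pooled.std()
    if sd == 0:
        raise ValueError("zero variance: constant pupil signals an upstream failure")
    out = []
    for t in traces:
        z = t.copy()
        z.values = (z.values - mu) / sd
        out.append(z)
    return out


def zscore_trace(trace: PupilTrace) -> PupilTrace:
    return zscore_traces([trace])[0]


def resample_trace(trace: PupilTrace, target_rate: float) -> PupilTrace:
    """Nearest-neighbour downsampling to ``target_rate``.

    Each target-grid point takes the value and validity flag of the
    nearest source sample.  Upsampling is refused.
    """
    if target_rate > trace.sampling_rate:
        raise ValueError("cannot upsample")
    if target_rate == trace.sampling_rate:
        return trace.copy()
    n_src = len(trace)
    duration = (n_src - 1) / trace.sampling_rate
    n_tgt = int(np.floor(duration * target_rate)) + 1
    src_idx = np.rint(np.arange(n_tgt) * trace.sampling_rate / target_rate).astype(int)
    src_idx = np.clip(src_idx, 0, n_src - 1)
    return PupilTrace(
        trace.values[src_idx], trace.valid[src_idx], target_rate,
        removed=trace.removed[src_idx], interpolated=trace.interpolated[src_idx],
    )
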