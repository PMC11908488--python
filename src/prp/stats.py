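"""Phase-binned pupil statistics and inference.

Covers the analysis layer: 18-bin phase aggregation, the per-bin pupil
derivative, the one-sample sign-flip permutation test with max-statistic
family-wise error control, weighted circular mean directions, the
Rayleigh uniformity test, repeated-measures ANOVA (one- and two-way
within-subject) with Mauchly's sphericity test and Greenhouse-Geisser
correction, and the Friedman fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_N_BINS = 18


# ---------------------------------------------------------------------------
# binning and aggregation
# ---------------------------------------------------------------------------

def bin_centres_deg(n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    width = 360.0 / n_bins
    return width * (np.arange(n_bins) + 0.5)


def assign_bins(phase_deg: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Half-open phase bins: bin k covers [k*w, (k+1)*w) with w = 360/n."""
    width = 360.0 / n_bins
    return np.minimum((np.asarray(phase_deg) // width).astype(int), n_bins - 1)


def bin_means(values: np.ndarray, bins: np.ndarray, joint_valid: np.ndarray,
              n_bins: int = DEFAULT_N_BINS) -> tuple[np.ndarray, np.ndarray]:
    """Mean value and observation count per phase bin.

    Only jointly valid samples (pupil valid AND phase valid) contribute.
    Bins with zero observations come back as NaN means.
    """
    v = values[joint_valid]
    b = bins[joint_valid]
    counts = np.bincount(b, minlength=n_bins).astype(float)
    sums = np.bincount(b, weights=v, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def derivative_by_bin(values: np.ndarray, phase_bins: np.ndarray,
                      cycle_id: np.ndarray, joint_valid: np.ndarray,
                      n_bins: int = DEFAULT_N_BINS, per_cycle: bool = False):
    """Per-bin pupil-size change, averaged over breathing cycles.

    Each consecutive-sample difference x[i] - x[i-1] is attributed to
    the phase bin of sample i; pairs spanning invalid samples or cycle
    boundaries are dropped.  Within a cycle the per-bin sums telescope
    to the cycle's endpoint difference.  Bins visited by no cycle are
    NaN.  With ``per_cycle=True`` the raw (cycle ids, per-cycle per-bin
    sums) are returned instead of the cycle average.
    """
    d = np.diff(values)
    pair_ok = (joint_valid[1:] & joint_valid[:-1]
               & (cycle_id[1:] == cycle_id[:-1]) & (cycle_id[1:] >= 0))
    if not pair_ok.any():
        if per_cycle:
            return np.zeros(0, dtype=int), np.zeros((0, n_bins))
        return np.full(n_bins, np.nan)
    b = phase_bins[1:][pair_ok]
    c = cycle_id[1:][pair_ok]
    dv = d[pair_ok]
    cycles = np.unique(c)
    cyc_index = np.searchsorted(cycles, c)
    flat = cyc_index * n_bins + b
    sums = np.bincount(flat, weights=dv, minlength=len(cycles) * n_bins)
    visited = np.bincount(flat, minlength=len(cycles) * n_bins) > 0
    sums = sums.reshape(len(cycles), n_bins)
    visited = visited.reshape(len(cycles), n_bins)
    if per_cycle:
        return cycles, sums
    n_vis = visited.sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = np.where(n_vis > 0, sums.sum(axis=0) / np.maximum(n_vis, 1), np.nan)
    return out


# ---------------------------------------------------------------------------
# sign-flip max-statistic permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    t_observed: np.ndarray
    p_fwe: np.ndarray
    n_permutations: int
    seed: int
    max_t_null: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def one_sample_t(x: np.ndarray) -> float:
    """t = mean / (SD / sqrt(n)), sample SD; inf when SD = 0, mean != 0."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    m = x.mean()
    s = x.std(ddof=1)
    if s == 0:
        return 0.0 if m == 0 else np.inf * np.sign(m)
    return float(m / (s / np.sqrt(n)))


def signflip_max_t_test(observations: list[np.ndarray], n_permutations: int = 10000,
                        seed: int = 0, chunk: int = 256) -> PermutationResult:
    """One-sample permutation test with max-|t| family-wise correction.

    For each permutation the sign of every observation is independently
    flipped within its bin; the per-bin t statistics are recomputed and
    the maximum |t| across bins recorded.  p_fwe(bin) is the proportion
    of permuted maxima >= |t_obs(bin)| (no smoothing: p = 0 is
    possible).  Sign flips leave the sum of squares invariant, so only
    the flipped means need simulating.  Each bin draws from its own
    Philox stream keyed by (seed, bin), making results independent of
    iteration order.
    """
    k = len(observations)
    obs = [np.asarray(o, dtype=float) for o in observations]
    for o in obs:
        if len(o) < 2:
            raise ValueError("every bin needs at least 2 observations")
    t_obs = np.array([one_sample_t(o) for o in obs])

    max_abs_t = np.zeros(n_permutations)
    for b, x in enumerate(obs):
        n = len(x)
        ssq = float(np.sum(x * x))
        rng = np.random.Generator(np.random.Philox(key=[seed, b]))
        sum_x = float(x.sum())
        t_b = np.empty(n_permutations)
        for start in range(0, n_permutations, chunk):
            stop = min(start + chunk, n_permutations)
            flips = rng.random((stop - start, n)) < 0.5
            # sum of eps*x with eps in {-1,+1}: sum_x - 2 * sum of flipped x
            s_flip = sum_x - 2.0 * (flips @ x)
            m = s_flip / n
            var = (ssq - n * m * m) / (n - 1)
            var = np.maximum(var, 0.0)
            sd = np.sqrt(var)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(sd > 0, m / (sd / np.sqrt(n)),
                             np.where(m == 0, 0.0, np.inf * np.sign(m)))
            t_b[start:stop] = t
        np.maximum(max_abs_t, np.abs(t_b), out=max_abs_t)

    # ties count as >=: tolerate float jitter so sign patterns reproducing
    # |t_obs| exactly (e.g. the identity flip) are never dropped
    p = np.array([np.mean(max_abs_t >= abs(t) * (1 - 1e-9) - 1e-12) for t in t_obs])
    return PermutationResult(t_obs, p, n_permutations, seed, max_abs_t)


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

class UndefinedDirectionError(ValueError):
    """The weighted resultant vector is (numerically) zero."""


def circular_mean_direction(weights: np.ndarray, angles_deg: np.ndarray) -> float:
    """Angle of the weighted circular resultant, in [0, 360).

    Weights are used as-is (bin means may be negative, which flips the
    corresponding unit vector).  A zero resultant has no direction and
    raises rather than silently returning 0.
    """
    w = np.asarray(weights, dtype=float)
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if not np.any(w != 0):
        raise UndefinedDirectionError("all weights are zero")
    s = float(np.sum(w * np.sin(th)))
    c = float(np.sum(w * np.cos(th)))
    r = np.hypot(s, c)
    scale = float(np.sum(np.abs(w)))
    if r < 1e-12 * max(scale, 1e-300):
        raise UndefinedDirectionError("zero resultant vector: direction undefined")
    return float(np.rad2deg(np.arctan2(s, c)) % 360.0)


def rayleigh_test(directions_deg: np.ndarray) -> tuple[float, float]:
    """Rayleigh uniformity test; returns (R, p).

    R is the mean resultant length of the unit vectors; the p-value uses
    the standard series approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)) with Rn = n R.
    """
    th = np.deg2rad(np.asarray(directions_deg, dtype=float))
    n = len(th)
    if n < 3:
        raise ValueError("Rayleigh test needs at least 3 directions")
    rn = np.hypot(np.sum(np.sin(th)), np.sum(np.cos(th)))
    r = rn / n
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n * n - rn * rn)) - (1 + 2 * n))
    return float(r), float(min(p, 1.0))


def proportion_toward_exhalation(directions_deg: np.ndarray) -> float:
    """Fraction of directions in the exhalation half [180, 360) deg."""
    d = np.mod(np.asarray(directions_deg, dtype=float), 360.0)
    if len(d) == 0:
        raise ValueError("no directions")
    return float(np.mean((d >= 180.0) & (d < 360.0)))


@dataclass
class CircularSummary:
    mean_direction_deg: np.ndarray  # per participant
    group_direction_deg: float
    resultant_length: float
    rayleigh_p: float
    proportion_toward_exhalation: float


def summarize_directions(per_participant_bin_means: np.ndarray,
                         angles_deg: np.ndarray) -> CircularSummary:
    """Per-participant weighted mean directions plus group-level summary."""
    dirs = []
    for row in per_participant_bin_means:
        w = np.where(np.isfinite(row), row, 0.0)
        dirs.append(circular_mean_direction(w, angles_deg))
    dirs = np.array(dirs)
    if len(dirs) >= 3:
        r, p = rayleigh_test(dirs)
    else:  # too few participants for a uniformity test
        th_ = np.deg2rad(dirs)
        r = float(np.hypot(np.sin(th_).sum(), np.cos(th_).sum()) / max(len(dirs), 1))
        p = np.nan
    th = np.deg2rad(dirs)
    group = float(np.rad2deg(np.arctan2(np.sin(th).sum(), np.cos(th).sum())) % 360.0)
    return CircularSummary(dirs, group, r, p, proportion_toward_exhalation(dirs))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with sphericity handling
# ---------------------------------------------------------------------------

@dataclass
class EffectResult:
    name: str
    F: float
    df_num: float
    df_den: float
    p: float
    eta_squared: float
    mauchly_W: float | None = None
    mauchly_p: float | None = None
    gg_epsilon: float | None = None
    corrected: bool = False


@dataclass
class AnovaResult:
    effects: list[EffectResult]
    fallback: dict | None = None  # Friedman result when covariance is singular

    def effect(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) orthonormal contrasts of k levels (Helmert, normalized)."""
    c = np.zeros((k, k - 1))
    for j in range(1, k):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
        c[:, j - 1] /= np.linalg.norm(c[:, j - 1])
    return c


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon (Box's formula) for an n x k table."""
    k = data.shape[1]
    c = _orthonormal_contrasts(k)
    s = np.cov(data @ c, rowvar=False, ddof=1)
    s = np.atleast_2d(s)
    tr = np.trace(s)
    eps = tr * tr / ((k - 1) * np.sum(s * s))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mauchly_test(data: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test for an n x k within-subject table.

    Returns (W, p) via the chi-square approximation.  Raises
    LinAlgError-style ValueError when the contrast covariance is
    singular (W would be 0 and the test undefined).
    """
    n, k = data.shape
    if k == 2:
        return 1.0, 1.0
    c = _orthonormal_contrasts(k)
    s = np.cov(data @ c, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(s)
    if np.min(eig) <= 1e-12 * max(np.max(eig), 1e-300):
        raise np.linalg.LinAlgError("singular sums-of-squares matrix: sphericity not assessable")
    d = k - 1
    w = float(np.prod(eig) / (np.mean(eig) ** d))
    return w, _mauchly_p(w, d, n - 1)


def _mauchly_p(w: float, d: int, nstar: int) -> float:
    """Chi-square approximation to Mauchly's W with Box's second-order term.

    ``d`` is the contrast dimension (k - 1), ``nstar`` the error degrees
    of freedom (n - 1 for a single-sample design).
    """
    df = d * (d + 1) / 2 - 1
    rho = 1.0 - (2 * d * d + d + 2) / (6.0 * d * nstar)
    # second-order coefficient as in R's mauchly.test (3*(d+1) term)
    w2 = ((d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d * d + 3 * (d + 1) + 2)
          / (288.0 * d * d * nstar * nstar * rho * rho))
    z = -nstar * rho * np.log(w)
    p = sps.chi2.sf(z, df) + w2 * (sps.chi2.sf(z, df + 4) - sps.chi2.sf(z, df))
    return float(np.clip(p, 0.0, 1.0))


def _one_way_rm(data: np.ndarray, name: str, ss_total_override: float | None = None,
                alpha: float = 0.05) -> EffectResult:
    """One-way within-subject ANOVA on an n x k cell-mean table."""
    n, k = data.shape
    grand = data.mean()
    ss_effect = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subject = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_effect - ss_subject
    df_num = k - 1.0
    df_den = (k - 1.0) * (n - 1.0)
    ms_effect = ss_effect / df_num
    ms_error = ss_error / df_den if df_den > 0 else np.nan
    F = ms_effect / ms_error if ms_error > 0 else (0.0 if ss_effect == 0 else np.inf)
    denom = ss_total_override if ss_total_override is not None else ss_total
    eta2 = ss_effect / denom if denom > 0 else 0.0

    w = p_mauchly = eps = None
    corrected = False
    if ss_effect + ss_error == 0:
        # no within-subject variance at all: F = 0 by convention,
        # sphericity is moot
        return EffectResult(name, 0.0, df_num, df_den, 1.0, 0.0)
    if k > 2:
        try:
            w, p_mauchly = mauchly_test(data)
        except np.linalg.LinAlgError:
            raise
        eps = gg_epsilon(data)
        if p_mauchly < alpha:
            corrected = True
            df_num *= eps
            df_den *= eps
    p = float(sps.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
    if F == 0:
        p = 1.0
    return EffectResult(name, float(F), float(df_num), float(df_den), p,
                        float(eta2), w, p_mauchly, eps, corrected)


def friedman_test(data: np.ndarray) -> dict:
    """Friedman test with ties correction, plus Kendall's W.

    ``data`` is an n-participants x k-levels table.  W = chi2/(n(k-1)).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 3 or k < 3:
        raise ValueError("Friedman test needs >= 3 participants and >= 3 levels")
    if np.all(np.ptp(data, axis=1) == 0):
        chi2, p = 0.0, 1.0
    else:
        chi2, p = sps.friedmanchisquare(*[data[:, j] for j in range(k)])
    w = float(chi2) / (n * (k - 1))
    return {"chi2": float(chi2), "df": k - 1, "p": float(p), "kendalls_W": float(w)}


def rm_anova(cells: pd.DataFrame, dv: str, within: list[str], subject: str,
             alpha: float = 0.05) -> AnovaResult:
    """Repeated-measures ANOVA with 1 or 2 within-subject factors.

    Only complete cases (participants present in every cell) are used;
    fewer than 3 complete participants is an error.  For every effect
    with more than 2 levels Mauchly's test is run and, when violated at
    ``alpha``, Greenhouse-Geisser corrected degrees of freedom are
    reported.  When the contrast covariance matrix is singular the
    Friedman fallback (on the first factor, collapsing the other) is
    returned instead.  eta^2 = SS_effect / SS_total.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("rm_anova supports 1 or 2 within-subject factors")
    levels = {f: sorted(cells[f].unique()) for f in within}
    wide = cells.pivot_table(index=subject, columns=within, values=dv)
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if len(complete) < 3:
        raise ValueError(f"fewer than 3 complete participants (dropped: {dropped})")

    if len(within) == 1:
        data = complete.to_numpy()
        try:
            eff = _one_way_rm(data, within[0], alpha=alpha)
        except np.linalg.LinAlgError:
            return AnovaResult([], fallback=friedman_test(complete.to_numpy()))
        res = AnovaResult([eff])
        res.dropped = dropped  # type: ignore[attr-defined]
        return res

    fa, fb = within
    a, b = len(levels[fa]), len(levels[fb])
    n = len(complete)
    # cells as n x a x b
    cube = complete.to_numpy().reshape(n, a, b)
    grand = cube.mean()
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_ab = cube.mean(axis=0)
    m_s = cube.mean(axis=(1, 2))
    m_as = cube.mean(axis=2)
    m_bs = cube.mean(axis=1)

    ss_total = np.sum((cube - grand) ** 2)
    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2)
    ss_abs = ss_total - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs

    effects = []
    try:
        for name, ss_eff, ss_err, df1, df2, collapsed in [
            (fa, ss_a, ss_as, a - 1, (a - 1) * (n - 1), m_as),
            (fb, ss_b, ss_bs, b - 1, (b - 1) * (n - 1), m_bs),
            (f"{fa}*{fb}", ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1), None),
        ]:
            F = (ss_eff / df1) / (ss_err / df2) if ss_err > 0 else (0.0 if ss_eff == 0 else np.inf)
            eta2 = ss_eff / ss_total if ss_total > 0 else 0.0
            k_eff = df1 + 1
            w = p_m = eps = None
            corrected = False
            dfn, dfd = float(df1), float(df2)
            if name == f"{fa}*{fb}":
                # sphericity on the (a-1)(b-1) interaction contrasts
                ca, cb = _orthonormal_contrasts(a), _orthonormal_contrasts(b)
                cc = np.einsum("ai,bj->abij", ca, cb).reshape(a * b, (a - 1) * (b - 1))
                proj = cube.reshape(n, a * b) @ cc
                if (a - 1) * (b - 1) > 1:
                    s = np.cov(proj, rowvar=False, ddof=1)
                    eig = np.linalg.eigvalsh(np.atleast_2d(s))
                    if np.min(eig) <= 1e-12 * max(np.max(eig), 1e-300):
                        raise np.linalg.LinAlgError("singular interaction covariance")
                    d = (a - 1) * (b - 1)
                    w = float(np.prod(eig) / (np.mean(eig) ** d))
                    p_m = _mauchly_p(w, d, n - 1)
                    tr = np.trace(np.atleast_2d(s))
                    eps = float(np.clip(tr * tr / (d * np.sum(s * s)), 1.0 / d, 1.0))
            elif k_eff > 2:
                w, p_m = mauchly_test(collapsed)
                eps = gg_epsilon(collapsed)
            if p_m is not None and p_m < alpha:
                corrected = True
                dfn *= eps
                dfd *= eps
            if F == 0:
                p = 1.0
            elif np.isfinite(F):
                p = float(sps.f.sf(F, dfn, dfd))
            else:
                p = 0.0
            effects.append(EffectResult(name, float(F), dfn, dfd, p, float(eta2),
                                        w, p_m, eps, corrected))
    except np.linalg.LinAlgError:
        collapsed_first = cube.mean(axis=2)
        return AnovaResult([], fallback=friedman_test(collapsed_first))
    res = AnovaResult(effects)
    res.dropped = dropped  # type: ignore[attr-defined]
    return res


def time_bin_means(values: np.ndarray, valid: np.ndarray,
                   n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Mean pupil size per equal-duration time bin of the recording."""
    n = len(values)
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    out = np.full(n_bins, np.nan)
    for k in range(n_bins):
        seg_valid = valid[edges[k]:edges[k + 1]]
        seg = values[edges[k]:edges[k + 1]][seg_valid]
        if len(seg):
            out[k] = seg.mean()
    return out
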