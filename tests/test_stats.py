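import itertools

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st

from prp import stats as ps
from prp.stats import (UndefinedDirectionError, assign_bins, bin_centres_deg,
                       bin_means, circular_mean_direction, derivative_by_bin,
                       friedman_test, gg_epsilon, mauchly_test, one_sample_t,
                       proportion_toward_exhalation, rayleigh_test, rm_anova,
                       signflip_max_t_test, time_bin_means)


class TestAssignBins:
    @pytest.mark.parametrize("phase,expected", [
        (0.0, 0), (19.999, 0), (20.0, 1), (350.0, 17), (359.999, 17),
    ])
    def test_half_open_edges(self, phase, expected):
        assert assign_bins(np.array([phase]))[0] == expected

    def test_uniform_phases_fill_bins_evenly(self, rng):
        n = 1_000_000
        b = assign_bins(rng.uniform(0, 360, n))
        counts = np.bincount(b, minlength=18)
        expect = n / 18
        sd = np.sqrt(n * (1 / 18) * (17 / 18))
        assert np.all(np.abs(counts - expect) < 4 * sd)


class TestBinMeans:
    def test_cosine_recovered_per_bin(self, rng):
        theta = rng.uniform(0, 360, 400_000)
        z = np.cos(np.deg2rad(theta - 180.0))
        bins = assign_bins(theta)
        means, counts = bin_means(z, bins, np.ones(len(z), dtype=bool))
        # numeric-integration oracle: mean of cos over each 20 deg sector
        edges = np.deg2rad(np.arange(19) * 20.0)
        for k in range(18):
            lo, hi = edges[k], edges[k + 1]
            oracle = (np.sin(hi - np.pi) - np.sin(lo - np.pi)) / (hi - lo)
            assert means[k] == pytest.approx(oracle, abs=0.01)
        assert counts.sum() == len(z)

    def test_all_zero_trace_gives_zero_means(self):
        means, _ = bin_means(np.zeros(100), np.zeros(100, dtype=int),
                             np.ones(100, dtype=bool))
        assert means[0] == 0.0

    def test_samples_in_single_bin(self):
        v = np.array([1.0, 2.0, 3.0])
        means, counts = bin_means(v, np.full(3, 3), np.ones(3, dtype=bool))
        assert means[3] == pytest.approx(2.0)
        assert np.isnan(np.delete(means, 3)).all()
        assert counts[3] == 3


class TestDerivativeByBin:
    def _sine_fixture(self, n_cycles=20, samples_per_cycle=360):
        phase = np.tile(np.arange(samples_per_cycle) * (360.0 / samples_per_cycle),
                        n_cycles)
        cycle = np.repeat(np.arange(n_cycles), samples_per_cycle)
        pupil = np.sin(np.deg2rad(phase))
        return pupil, phase, cycle

    def test_sine_telescoping_oracle(self):
        pupil, phase, cycle = self._sine_fixture()
        bins = assign_bins(phase)
        d = derivative_by_bin(pupil, bins, cycle, np.ones(len(pupil), dtype=bool))
        edges = np.deg2rad(np.arange(19) * 20.0)
        for k in range(18):
            oracle = np.sin(edges[k + 1]) - np.sin(edges[k])
            assert d[k] == pytest.approx(oracle, abs=0.02)

    def test_constant_pupil_all_zero(self):
        _, phase, cycle = self._sine_fixture()
        bins = assign_bins(phase)
        d = derivative_by_bin(np.full(len(phase), 2.0), bins, cycle,
                              np.ones(len(phase), dtype=bool))
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_per_cycle_sums_telescope_to_endpoint_difference(self, rng):
        n = 720
        phase = np.concatenate([np.sort(rng.uniform(0, 360, n // 2)),
                                np.sort(rng.uniform(0, 360, n // 2))])
        cycle = np.repeat([0, 1], n // 2)
        pupil = rng.normal(0, 1, n)
        bins = assign_bins(phase)
        joint = np.ones(n, dtype=bool)
        d = np.diff(pupil)
        ok = cycle[1:] == cycle[:-1]
        for c in (0, 1):
            sel = ok & (cycle[1:] == c)
            per_bin = np.bincount(bins[1:][sel], weights=d[sel], minlength=18)
            endpoints = pupil[cycle == c]
            assert per_bin.sum() == pytest.approx(endpoints[-1] - endpoints[0], abs=1e-9)


class TestOneSampleT:
    def test_matches_scipy(self, rng):
        from scipy.stats import ttest_1samp
        x = rng.normal(0.3, 1.2, 40)
        assert one_sample_t(x) == pytest.approx(ttest_1samp(x, 0.0).statistic)

    def test_degenerate_zero_variance(self):
        assert one_sample_t(np.zeros(5)) == 0.0
        assert one_sample_t(np.full(5, 2.0)) == np.inf
        assert one_sample_t(np.full(5, -2.0)) == -np.inf


def exhaustive_signflip(observations):
    """Enumeration oracle: exact max-|t| null over every sign pattern."""
    sizes = [len(o) for o in observations]
    t_obs = np.array([one_sample_t(o) for o in observations])
    all_max = []
    per_bin_null = [[] for _ in observations]
    for pattern in itertools.product(*[[-1, 1]] * sum(sizes)):
        pos = 0
        ts = []
        for b, o in enumerate(observations):
            eps = np.array(pattern[pos:pos + sizes[b]])
            pos += sizes[b]
            tb = one_sample_t(eps * o)
            ts.append(abs(tb))
            per_bin_null[b].append(abs(tb))
        all_max.append(max(ts))
    all_max = np.array(all_max)
    p_fwe = np.array([np.mean(all_max >= abs(t)) for t in t_obs])
    p_unc = np.array([np.mean(np.array(per_bin_null[b]) >= abs(t_obs[b]))
                      for b in range(len(observations))])
    return t_obs, p_fwe, p_unc


class TestSignflipPermutation:
    def test_all_zero_observations(self):
        res = signflip_max_t_test([np.zeros(5), np.zeros(5)], 100, seed=1)
        np.testing.assert_array_equal(res.t_observed, [0.0, 0.0])
        np.testing.assert_array_equal(res.p_fwe, [1.0, 1.0])

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        obs = [rng.normal(0.8, 1, 4), rng.normal(0.0, 1, 4)]
        _, p_exact, p_unc = exhaustive_signflip(obs)
        res = signflip_max_t_test(obs, n_permutations=10_000, seed=3)
        for b in range(2):
            se = np.sqrt(max(p_exact[b] * (1 - p_exact[b]), 1e-6) / 10_000)
            assert abs(res.p_fwe[b] - p_exact[b]) <= 3 * se + 1e-12
        # family-wise p dominates the per-bin uncorrected p
        assert np.all(p_exact >= p_unc - 1e-12)

    def test_deterministic_given_seed(self, rng):
        obs = [rng.normal(0, 1, 30) for _ in range(4)]
        r1 = signflip_max_t_test(obs, 500, seed=9)
        r2 = signflip_max_t_test(obs, 500, seed=9)
        np.testing.assert_array_equal(r1.p_fwe, r2.p_fwe)
        np.testing.assert_array_equal(r1.max_t_null, r2.max_t_null)

    def test_p_monotone_in_observed_t(self, rng):
        obs = [rng.normal(m, 1, 50) for m in (0.0, 0.2, 0.5, 1.0)]
        res = signflip_max_t_test(obs, 2000, seed=2)
        order = np.argsort(np.abs(res.t_observed))
        assert np.all(np.diff(res.p_fwe[order]) <= 1e-12)

    def test_bin_relabelling_permutes_p_values(self, rng):
        obs = [rng.normal(0.3, 1, 20) for _ in range(3)]
        res = signflip_max_t_test(obs, 1000, seed=5)
        perm = [2, 0, 1]
        res_p = signflip_max_t_test([obs[i] for i in perm], 1000, seed=5)
        # identical values end up with identical FWE p regardless of position:
        # the max-t null only depends on the collection of bins
        for orig, new in enumerate(perm):
            matching = np.flatnonzero(np.isclose(res.t_observed, res_p.t_observed[orig]))
            assert np.isclose(res.p_fwe[matching[0]], res_p.p_fwe[orig], atol=0.05)

    def test_small_bin_errors(self):
        with pytest.raises(ValueError):
            signflip_max_t_test([np.array([1.0])], 10, seed=0)


class TestCircularMean:
    def test_single_nonzero_weight(self):
        w = np.zeros(18)
        w[9] = 1.0  # bin centre 190 deg
        assert circular_mean_direction(w, bin_centres_deg()) == pytest.approx(190.0)

    def test_cosine_weights_recover_peak(self):
        ang = bin_centres_deg()
        w = np.cos(np.deg2rad(ang - 200.0))
        assert circular_mean_direction(w, ang) == pytest.approx(200.0, abs=1e-6)

    def test_equal_weights_undefined(self):
        with pytest.raises(UndefinedDirectionError):
            circular_mean_direction(np.ones(18), bin_centres_deg())

    def test_all_zero_weights_undefined(self):
        with pytest.raises(UndefinedDirectionError):
            circular_mean_direction(np.zeros(18), bin_centres_deg())

    @settings(max_examples=40, deadline=None)
    @given(delta=st.floats(0, 360, allow_nan=False))
    def test_rotation_equivariance(self, delta):
        ang = bin_centres_deg()
        w = np.cos(np.deg2rad(ang - 200.0))
        base = circular_mean_direction(w, ang)
        rotated = circular_mean_direction(w, (ang + delta) % 360.0)
        assert rotated == pytest.approx((base + delta) % 360.0, abs=1e-6) or \
            abs(rotated - (base + delta) % 360.0) > 359.99

    def test_negative_weights_flip_direction(self):
        ang = bin_centres_deg()
        w = -np.cos(np.deg2rad(ang - 200.0))
        assert circular_mean_direction(w, ang) == pytest.approx(20.0, abs=1e-6)


class TestRayleigh:
    def test_uniform_grid_not_rejected(self):
        r, p = rayleigh_test(bin_centres_deg())
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_identical_directions_degenerate(self):
        r, p = rayleigh_test(np.full(20, 137.0))
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_matches_pingouin_oracle(self, rng):
        for n in (5, 12, 50):
            d = rng.uniform(0, 360, n)
            _, p = rayleigh_test(d)
            _, p_pg = pg.circ_rayleigh(np.deg2rad(d))
            assert p == pytest.approx(p_pg, abs=1e-8)

    def test_von_mises_sample_rejected(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            d = np.rad2deg(rng.vonmises(np.deg2rad(200), 2.0, 50)) % 360
            _, p = rayleigh_test(d)
            hits += p < 0.001
        assert hits >= 99

    def test_too_few_directions_error(self):
        with pytest.raises(ValueError):
            rayleigh_test(np.array([10.0, 20.0]))


class TestProportionTowardExhalation:
    def test_examples(self):
        assert proportion_toward_exhalation(np.array([190.0, 200.0, 10.0])) == pytest.approx(2 / 3)
        assert proportion_toward_exhalation(np.full(5, 90.0)) == 0.0


class TestSphericityMachinery:
    def test_gg_epsilon_matches_pingouin(self, rng):
        for _ in range(5):
            data = rng.normal(size=(10, 5))
            assert gg_epsilon(data) == pytest.approx(
                pg.epsilon(pd.DataFrame(data), correction="gg"), abs=1e-8)

    def test_mauchly_matches_pingouin(self, rng):
        for k in (3, 4, 5):
            data = rng.normal(size=(12, k))
            w, p = mauchly_test(data)
            sph = pg.sphericity(pd.DataFrame(data))
            assert w == pytest.approx(sph.W, abs=1e-8)
            assert p == pytest.approx(sph.pval, abs=1e-8)

    def test_epsilon_bounds(self, rng):
        for k in (3, 6):
            data = rng.normal(size=(20, k))
            eps = gg_epsilon(data)
            assert 1.0 / (k - 1) <= eps <= 1.0

    def test_two_levels_trivially_spherical(self):
        w, p = mauchly_test(np.random.default_rng(0).normal(size=(10, 2)))
        assert (w, p) == (1.0, 1.0)


class TestRmAnova:
    def _df(self, data):
        n, k = data.shape
        return pd.DataFrame([{"s": s, "lvl": l, "y": data[s, l]}
                             for s in range(n) for l in range(k)])

    def test_identical_cells_give_f_zero_p_one(self):
        data = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = rm_anova(self._df(data), dv="y", within=["lvl"], subject="s")
        e = res.effect("lvl")
        assert e.F == 0.0
        assert e.p == 1.0

    def test_one_way_matches_sums_of_squares_oracle(self, rng):
        data = rng.normal(size=(5, 3))
        res = rm_anova(self._df(data), dv="y", within=["lvl"], subject="s")
        e = res.effect("lvl")
        # direct sums-of-squares oracle
        n, k = data.shape
        grand = data.mean()
        ss_eff = n * np.sum((data.mean(0) - grand) ** 2)
        ss_sub = k * np.sum((data.mean(1) - grand) ** 2)
        ss_tot = np.sum((data - grand) ** 2)
        ss_err = ss_tot - ss_eff - ss_sub
        f_oracle = (ss_eff / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        assert e.F == pytest.approx(f_oracle, abs=1e-10)
        assert e.eta_squared == pytest.approx(ss_eff / ss_tot, abs=1e-10)
        assert e.gg_epsilon == pytest.approx(gg_epsilon(data), abs=1e-12)

    def test_one_way_matches_pingouin(self, rng):
        data = rng.normal(size=(12, 6))
        res = rm_anova(self._df(data), dv="y", within=["lvl"], subject="s")
        e = res.effect("lvl")
        pgres = pg.rm_anova(data=self._df(data), dv="y", within="lvl",
                            subject="s", correction=True)
        assert e.F == pytest.approx(pgres["F"][0], abs=1e-8)
        assert e.gg_epsilon == pytest.approx(pgres["eps"][0], abs=1e-8)

    def test_two_way_matches_pingouin(self, rng):
        d2 = rng.normal(size=(10, 4, 3))
        df = pd.DataFrame([{"s": s, "a": a, "b": b, "y": d2[s, a, b]}
                           for s in range(10) for a in range(4) for b in range(3)])
        res = rm_anova(df, dv="y", within=["a", "b"], subject="s")
        pg2 = pg.rm_anova(data=df, dv="y", within=["a", "b"], subject="s")
        for name, row in zip(["a", "b", "a*b"], range(3)):
            assert res.effect(name).F == pytest.approx(pg2["F"][row], abs=1e-8)

    def test_two_level_factor_needs_no_correction(self, rng):
        data = rng.normal(size=(8, 2))
        res = rm_anova(self._df(data), dv="y", within=["lvl"], subject="s")
        e = res.effect("lvl")
        assert e.gg_epsilon is None
        assert not e.corrected

    def test_singular_covariance_falls_back_to_friedman(self, rng):
        # more levels than subjects makes the contrast covariance singular
        data = rng.normal(size=(4, 8))
        res = rm_anova(self._df(data), dv="y", within=["lvl"], subject="s")
        assert res.fallback is not None
        assert "chi2" in res.fallback

    def test_incomplete_participants_dropped(self, rng):
        data = rng.normal(size=(6, 3))
        df = self._df(data)
        df = df[~((df.s == 5) & (df.lvl == 2))]  # subject 5 misses a cell
        res = rm_anova(df, dv="y", within=["lvl"], subject="s")
        assert res.dropped == [5]

    def test_fewer_than_three_complete_errors(self, rng):
        data = rng.normal(size=(2, 3))
        with pytest.raises(ValueError, match="fewer than 3"):
            rm_anova(self._df(data), dv="y", within=["lvl"], subject="s")


class TestFriedman:
    def test_identical_rows_chi2_zero(self):
        data = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (5, 1)) * 0 + 7.0
        res = friedman_test(data)
        assert res["chi2"] == 0.0
        assert res["kendalls_W"] == 0.0

    def test_perfectly_consistent_ordering_w_one(self):
        data = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (6, 1))
        data += np.arange(6)[:, None]  # subject offsets do not matter
        res = friedman_test(data)
        assert res["kendalls_W"] == pytest.approx(1.0)

    def test_matches_textbook_rank_formula(self, rng):
        data = rng.normal(size=(6, 4))
        res = friedman_test(data)
        # direct rank-sum oracle (no ties in continuous data)
        n, k = data.shape
        ranks = np.argsort(np.argsort(data, axis=1), axis=1) + 1
        rj = ranks.sum(axis=0)
        chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rj ** 2) - 3 * n * (k + 1)
        assert res["chi2"] == pytest.approx(chi2, abs=1e-8)
        assert res["kendalls_W"] == pytest.approx(chi2 / (n * (k - 1)), abs=1e-8)


class TestTimeBinMeans:
    def test_linear_trace_strictly_decreasing(self):
        v = np.linspace(10, 0, 18000)
        m = time_bin_means(v, np.ones(18000, dtype=bool))
        assert np.all(np.diff(m) < 0)

    def test_constant_trace(self):
        m = time_bin_means(np.full(18000, 4.5), np.ones(18000, dtype=bool))
        np.testing.assert_allclose(m, 4.5)

    def test_empty_bin_is_missing(self):
        v = np.arange(36.0)
        valid = np.ones(36, dtype=bool)
        valid[0:2] = False  # first of 18 bins fully invalid
        m = time_bin_means(v, valid)
        assert np.isnan(m[0])
        assert np.isfinite(m[1:]).all()
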