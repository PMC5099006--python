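"""Bivariate Ripley's K: estimator, envelopes, classification."""

import numpy as np
import pytest

from _oracles import k_brute, random_event_sets
from firesync import (
    BivariateEventAnalysis,
    classify_synchrony,
    k_bivariate_1d,
    mc_envelopes,
    randomization_sanity,
)


class TestEstimator:
    def test_single_pair_at_lag_two(self):
        k = k_bivariate_1d([50], [48], (1, 100), t_max=5)
        assert list(k[:2]) == [0.0, 0.0]
        assert np.allclose(k[2:], 100.0)

    def test_climate_in_fire_year_counts_at_lag_zero(self):
        k = k_bivariate_1d([50], [50], (1, 100), t_max=3)
        assert k[0] == 100.0

    def test_identical_sets_lag_zero_is_T_over_n(self):
        years = [10, 30, 50, 70, 90]
        k = k_bivariate_1d(years, years, (1, 100), t_max=0)
        assert k[0] == pytest.approx(100 / 5)

    def test_forward_pairs_do_not_count(self):
        # climate after the fire must never contribute
        k = k_bivariate_1d([50], [55], (1, 100), t_max=10)
        assert np.all(k == 0.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        fires, climate, domain, t_max = random_event_sets(rng)
        for edge in ("ripley", "none"):
            got = k_bivariate_1d(fires, climate, domain, t_max, edge)
            want = k_brute(fires, climate, domain, t_max, edge == "ripley")
            assert np.allclose(got, want, rtol=1e-12, atol=1e-9)

    def test_doubling_domain_doubles_interior_k(self):
        fires, climate = [200, 240, 280], [195, 230]
        k1 = k_bivariate_1d(fires, climate, (100, 399), t_max=20)
        k2 = k_bivariate_1d(fires, climate, (100, 699), t_max=20)
        assert np.allclose(k2, 2 * k1)

    def test_edge_corrected_fire_at_domain_start_upweighted(self):
        # fire at the first domain year: window fraction is 1/(t+1)
        k = k_bivariate_1d([1], [1], (1, 100), t_max=4)
        assert np.allclose(k, [100, 200, 300, 400, 500])

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            k_bivariate_1d([], [5], (1, 100), 5)
        with pytest.raises(ValueError, match="t_max"):
            k_bivariate_1d([5], [5], (1, 100), 100)
        with pytest.raises(ValueError, match="outside domain"):
            k_bivariate_1d([500], [5], (1, 100), 5)


class TestEnvelopes:
    def test_same_seed_identical_results(self):
        args = ([100, 200, 300], [95, 190, 280], (1, 600))
        a = mc_envelopes(*args, t_max=10, n_reps=200, seed=42)
        b = mc_envelopes(*args, t_max=10, n_reps=200, seed=42)
        assert np.array_equal(a.khat, b.khat)
        for lev in a.envelopes:
            assert np.array_equal(a.envelopes[lev][0], b.envelopes[lev][0])
            assert np.array_equal(a.envelopes[lev][1], b.envelopes[lev][1])

    def test_envelope_nesting_95_in_99(self, rng):
        fires = rng.choice(np.arange(1, 601), 16, replace=False)
        climate = rng.choice(np.arange(1, 601), 50, replace=False)
        res = mc_envelopes(fires, climate, (1, 600), t_max=10,
                           n_reps=500, seed=1)
        lo95, hi95 = res.envelope(0.95)
        lo99, hi99 = res.envelope(0.99)
        assert np.all(lo99 <= lo95) and np.all(hi95 <= hi99)

    def test_null_expectation_matches_mc_mean(self, rng):
        fires = rng.choice(np.arange(1, 601), 20, replace=False)
        climate = rng.choice(np.arange(1, 601), 50, replace=False)
        res = mc_envelopes(fires, climate, (1, 600), t_max=10,
                           n_reps=2000, seed=2)
        # E[Khat(t)] = t + 1 under the uniform null
        assert np.allclose(res.null_mean, res.null_expectation, rtol=0.05)

    def test_planted_lag_three_detected(self):
        rng = np.random.default_rng(11)
        climate = np.sort(rng.choice(np.arange(1, 598), 50, replace=False))
        fires = climate + 3
        res = mc_envelopes(fires, climate, (1, 600), t_max=10,
                           n_reps=1000, seed=5)
        labels = res.classification(0.95)
        assert all(labels[3:] == "synchronous")

    def test_reps_and_levels_validation(self):
        model = BivariateEventAnalysis([50], [40], (1, 100), t_max=5)
        with pytest.raises(ValueError, match="n_reps"):
            model.fit(n_reps=10)
        with pytest.raises(ValueError, match="levels"):
            model.fit(n_reps=200, levels=(1.5,))

    def test_circular_null_preserves_spacing(self, rng):
        from firesync.bea import _null_replicates

        climate = np.sort(rng.choice(np.arange(1, 601), 30, replace=False))
        reps = _null_replicates(rng, "circular", climate, (1, 600), 50)
        T = 600

        def circular_gaps(years):
            ys = np.sort(years)
            return sorted(np.diff(np.append(ys, ys[0] + T)))

        want = circular_gaps(climate)
        for r in reps:
            assert circular_gaps(r) == want


class TestClassification:
    def make_result(self, rng):
        fires = rng.choice(np.arange(1, 601), 16, replace=False)
        climate = rng.choice(np.arange(1, 601), 50, replace=False)
        return mc_envelopes(fires, climate, (1, 600), t_max=20,
                            n_reps=300, seed=7)

    def test_window_formatting_contiguous_runs(self, rng):
        res = self.make_result(rng)
        # force a known label pattern
        res.khat = res.null_expectation.copy()
        lo, hi = res.envelopes[0.95]
        for lag in (6, 7, 8, 9, 13, 14, 15, 16, 17):
            res.khat[lag] = hi[lag] + 1
        wins = res.synchrony_windows(0.95)
        assert wins["synchronous"] == [(6, 9), (13, 17)]

    def test_all_inside_is_single_independent_window(self, rng):
        res = self.make_result(rng)
        res.khat = res.null_expectation.copy()
        wins = res.synchrony_windows(0.95)
        assert wins["synchronous"] == [] and wins["asynchronous"] == []
        assert wins["independent"] == [(0, 20)]

    def test_all_below_is_asynchronous_everywhere(self, rng):
        res = self.make_result(rng)
        res.khat = res.envelopes[0.95][0] - 1
        wins = classify_synchrony(res, 0.95)["windows"]
        assert wins["asynchronous"] == [(0, 20)]

    def test_to_frame_columns(self, rng):
        df = self.make_result(rng).to_frame()
        for col in ("lag", "khat", "expectation", "env95_lo", "env95_hi",
                    "env99_lo", "env99_hi", "class"):
            assert col in df.columns


def test_randomization_sanity_null_rate(rng):
    climate_sets = {
        f"set{i}": rng.choice(np.arange(1, 601), 50, replace=False)
        for i in range(3)
    }
    out = randomization_sanity(climate_sets, (1, 600), n_events=16,
                               t_max=10, n_reps=300, seed=21)
    for frac in out["per_set"].values():
        assert frac <= 0.5  # pointwise false positives only, never wholesale
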