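"""Spatial similarity: series, windows, tests, cross-temporal matrices."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import pearsonr

import pairrsa as p
from pairrsa.preprocess import SmoothSpec
from pairrsa.spatial import average_condition_series, cross_temporal_matrix
from pairrsa.stats import PermutationPlan


def brute_force_series(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Independent oracle: scipy pearsonr per time sample."""
    out = np.empty(a.shape[1])
    for t in range(a.shape[1]):
        if a[:, t].std() == 0 or b[:, t].std() == 0:
            out[t] = np.nan
        else:
            out[t] = pearsonr(a[:, t], b[:, t]).statistic
    return out


class TestSimilaritySeries:
    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(6, 10))
        times = np.arange(10) / 300.0
        s = p.spatial_similarity_series(a, a, times)
        np.testing.assert_allclose(s.r, 1.0, atol=1e-12)
        s_neg = p.spatial_similarity_series(a, -a, times)
        np.testing.assert_allclose(s_neg.r, -1.0, atol=1e-12)

    def test_affine_invariance_and_hand_value(self):
        times = np.array([0.0])
        a = np.array([[1.0], [2.0], [3.0]])
        b = 2 * a + 1  # positive affine transform -> r = 1
        assert p.spatial_similarity_series(a, b, times).r[0] == pytest.approx(1.0)
        c = np.array([[1.0], [0.0], [2.0]])
        expect = pearsonr(a[:, 0], c[:, 0]).statistic
        assert p.spatial_similarity_series(a, c, times).r[0] == pytest.approx(
            expect, abs=1e-12
        )

    def test_oracle_equivalence_small_instances(self):
        """<= 4 sensors, <= 6 samples: match brute-force Pearson to 1e-12."""
        rng = np.random.default_rng(42)
        for n_sens in (3, 4):
            for n_t in (2, 6):
                a = rng.normal(size=(n_sens, n_t))
                b = rng.normal(size=(n_sens, n_t))
                times = np.arange(n_t) / 300.0
                s = p.spatial_similarity_series(a, b, times)
                np.testing.assert_allclose(s.r, brute_force_series(a, b), atol=1e-12)

    def test_zero_variance_flagged_undefined(self):
        times = np.arange(3) / 300.0
        a = np.ones((4, 3))  # constant patterns: undefined everywhere
        b = np.random.default_rng(1).normal(size=(4, 3))
        s = p.spatial_similarity_series(a, b, times)
        assert np.all(np.isnan(s.r))

    def test_mismatched_axes_rejected(self):
        with pytest.raises(ValueError):
            p.spatial_similarity_series(np.zeros((3, 4)), np.zeros((3, 5)),
                                        np.arange(4) / 300.0)


class TestConditionAverages:
    def test_matches_brute_force_loop(self, tiny_dataset):
        """Condition average equals an explicit loop over comparisons."""
        epoch_sets, truth = tiny_dataset
        within = p.enumerate_within(truth.design)
        per_part, group = average_condition_series(epoch_sets, within)
        for es, series in zip(epoch_sets, per_part):
            index = es.trial_index()
            stack = np.array([
                brute_force_series(es.data[index[a]], es.data[index[b]])
                for a, b in within
            ])
            np.testing.assert_allclose(series.r, np.nanmean(stack, axis=0),
                                       atol=1e-10)
        np.testing.assert_allclose(
            group.r, np.nanmean([s.r for s in per_part], axis=0), atol=1e-12
        )

    def test_window_means_match_series_average(self, tiny_dataset):
        epoch_sets, truth = tiny_dataset
        within = p.enumerate_within(truth.design)
        per_part, _ = average_condition_series(epoch_sets, within)
        interval = (-0.88, -0.485)
        means = p.condition_window_means(epoch_sets, within, interval)
        mask = (epoch_sets[0].times >= interval[0]) & (epoch_sets[0].times < interval[1])
        for m, s in zip(means, per_part):
            assert m == pytest.approx(np.nanmean(s.r[mask]), abs=1e-12)


class TestDetectWindow:
    TIMES = np.arange(-600, 300) / 300.0  # -2.0 .. 1.0 s

    def series(self, r):
        return p.SimilarityTimeSeries(r=r, times=self.TIMES)

    def test_all_zero_gives_empty(self):
        assert p.detect_window(self.series(np.zeros(900)), 0.04) is None

    def test_boxcar_recovered(self):
        r = np.where((self.TIMES >= -0.9) & (self.TIMES <= -0.5), 0.08, 0.0)
        lo, hi = p.detect_window(self.series(r), 0.04)
        dt = 1 / 300.0
        assert lo == pytest.approx(-0.9, abs=1.5 * dt)
        assert hi == pytest.approx(-0.5, abs=1.5 * dt)

    def test_longest_run_wins(self):
        r = np.zeros(900)
        r[(self.TIMES >= -1.5) & (self.TIMES < -1.4)] = 0.1  # 0.1 s run
        r[(self.TIMES >= -0.9) & (self.TIMES < -0.6)] = 0.1  # 0.3 s run
        lo, hi = p.detect_window(self.series(r), 0.04)
        assert -0.95 < lo < -0.85 and -0.65 < hi < -0.55

    def test_search_interval_restricts(self):
        r = np.zeros(900)
        r[(self.TIMES >= -1.5) & (self.TIMES < -1.1)] = 0.1  # outside search
        r[(self.TIMES >= -0.8) & (self.TIMES < -0.7)] = 0.1
        lo, hi = p.detect_window(self.series(r), 0.04, search_interval=(-1.0, 0.0))
        assert lo >= -1.0 and hi <= 0.0


class TestWindowTest:
    def test_identical_conditions(self):
        x = np.array([0.1, 0.2, 0.3])
        res = p.window_test(x, x, (-0.88, -0.485))
        assert res.t_statistic == 0.0 and res.p_value == 1.0
        assert res.df == 2

    def test_degenerate_constant_difference(self):
        res = p.window_test(np.ones(4) * 0.2, np.ones(4) * 0.1, (-1, 0))
        assert res.degenerate and np.isinf(res.t_statistic)

    def test_hand_table(self):
        w = np.array([0.08, 0.09, 0.07, 0.10])
        b = np.array([0.06, 0.08, 0.07, 0.07])
        d = w - b
        t_hand = d.mean() / (d.std(ddof=1) / 2.0)
        res = p.window_test(w, b, (-1, 0))
        assert res.t_statistic == pytest.approx(t_hand, abs=1e-12)
        assert res.df == 3


class TestOrderAnova:
    def test_no_order_effect_on_symmetric_data(self, tiny_dataset):
        epoch_sets, truth = tiny_dataset
        res = p.order_anova(epoch_sets, truth.design, (-0.88, -0.485))
        for effect in ("Order", "Pairs", "OrderxPairs"):
            assert np.isfinite(res[effect]["F"]) and res[effect]["F"] >= 0
            assert res[effect]["df1"] == 1 and res[effect]["df2"] == len(epoch_sets) - 1
        # the generator embeds no order dependence; Pairs is the real effect
        assert res["Pairs"]["F"] > res["Order"]["F"]


class TestCrossTemporal:
    def test_self_matrix_static_pattern(self):
        # one fixed spatial pattern modulated in time: all defined cells = 1
        pattern = np.array([1.0, -0.5, 0.2, 0.8])
        wave = np.sin(np.linspace(0.5, 3.0, 30)) + 1.5
        a = np.outer(pattern, wave)
        times = np.arange(30) / 300.0
        m = cross_temporal_matrix(a, a, times, 300.0, smooth=None)
        np.testing.assert_allclose(m.r, 1.0, atol=1e-10)

    def test_diagonal_equals_series(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 6, 40))
        times = np.arange(40) / 300.0
        m = cross_temporal_matrix(a, b, times, 300.0, smooth=None)
        s = p.spatial_similarity_series(a, b, times)
        np.testing.assert_allclose(np.diag(m.r), s.r, atol=1e-10)

    def test_dynamic_pattern_lag_decay(self):
        """Noiseless dynamic-identity pair: within-pair cross-temporal
        similarity at 200 ms lag falls below the lag-0 similarity."""
        cfg = p.SimulationConfig(
            n_participants=1, n_pairs=2, n_sensors=24,
            epoch_window=(-1.2, 0.2), word_onsets=(-1.0,),
            identity_mode="dynamic", identity_tau=0.05,
            evoked_amplitude=0.0, identity_amplitude=1.0, noise_sd=0.0, seed=2,
        )
        epoch_sets, truth = p.simulate_dataset(cfg)
        es = epoch_sets[0]
        a_id, b_id = truth.design.sentences_of_pair(truth.design.pair_ids[0])
        idx = es.trial_index()
        m = cross_temporal_matrix(
            es.data[idx[a_id]], es.data[idx[b_id]], es.times, 300.0,
            smooth=None, interval=(-0.88, -0.485),
        )
        lag = int(round(0.2 * 300))
        diag0 = np.nanmean(np.diag(m.r))
        diag_lag = np.nanmean(np.diag(m.r, k=lag))
        assert diag0 > diag_lag + 0.3


class TestMatrixClusterTest:
    def test_identical_conditions_no_clusters(self):
        rng = np.random.default_rng(0)
        mats = rng.normal(size=(6, 10, 10))
        res = p.matrix_cluster_test(mats, mats.copy(),
                                    plan=PermutationPlan(n_perm=50, seed=1))
        assert res.clusters == []

    def test_embedded_diagonal_effect_detected(self):
        """A strong diagonal within > between difference yields a
        significant cluster overlapping the diagonal."""
        rng = np.random.default_rng(4)
        n, t = 10, 20
        between = rng.normal(0, 0.05, size=(n, t, t))
        within = between + rng.normal(0, 0.02, size=(n, t, t))
        diag = np.eye(t, dtype=bool) | np.eye(t, k=1, dtype=bool) | np.eye(t, k=-1, dtype=bool)
        within[:, diag] += 0.2
        res = p.matrix_cluster_test(within, between,
                                    plan=PermutationPlan(n_perm=200, seed=2))
        sig = [c for c in res.clusters if c.significant and c.tail == "positive"]
        assert sig
        cells = np.concatenate([c.members for c in sig])
        i, j = np.unravel_index(cells, (t, t))
        assert np.mean(np.abs(i - j)) < 2.5

    def test_p_convention_when_null_ties_observed(self):
        # all-equal masses: observed never exceeds null -> p = 1
        within = np.tile(np.linspace(0, 1, 25).reshape(5, 5), (4, 1, 1))
        res = p.matrix_cluster_test(within, within.copy(),
                                    plan=PermutationPlan(n_perm=20, seed=0))
        assert all(c.p_value == 1.0 for c in res.clusters) or res.clusters == []


class TestFisherZOption:
    def test_off_by_default_and_monotone_effect(self, tiny_dataset):
        """Fisher-z averaging is optional; it agrees with raw averaging
        for a single comparison and differs for heterogeneous r values."""
        epoch_sets, truth = tiny_dataset
        within = p.enumerate_within(truth.design)
        single = p.ComparisonSet(label="w1", comparisons=within.comparisons[:1])
        _, raw = average_condition_series(epoch_sets[:1], single)
        _, fz = average_condition_series(epoch_sets[:1], single, fisher_z=True)
        np.testing.assert_allclose(fz.r, raw.r, atol=1e-10)
        _, raw_all = average_condition_series(epoch_sets[:1], within)
        _, fz_all = average_condition_series(epoch_sets[:1], within,
                                             fisher_z=True)
        assert not np.allclose(np.nan_to_num(fz_all.r),
                               np.nan_to_num(raw_all.r), atol=1e-12)
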