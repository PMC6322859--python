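"""LCMV beamforming, orientation selection and source-level RSA."""

from __future__ import annotations

import numpy as np
import pytest

import pairrsa as p
from pairrsa.containers import BeamformerFilters, CovarianceEstimate, EpochSet, TrialInfo
from pairrsa.source import (
    estimate_covariance,
    grid_adjacency,
    grid_cluster_test,
    lcmv_filters,
    peak_region,
    project_orientation,
)
from pairrsa.stats import PermutationPlan
from pairrsa.temporal import average_condition_maps


def make_epochs(data: np.ndarray, rate: float = 300.0) -> EpochSet:
    n_trials, n_sensors, n_times = data.shape
    trials = [
        TrialInfo(i, i // 2, i % 2 + 1,
                  "expected" if i % 2 == 0 else "unexpected", "noun")
        for i in range(n_trials)
    ]
    return EpochSet(data=data, times=np.arange(n_times) / rate,
                    sensor_ids=[f"S{i}" for i in range(n_sensors)], trials=trials)


class TestCovariance:
    def test_white_noise_near_identity(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(20, 8, 500))
        cov = estimate_covariance(make_epochs(data), (0.0, 500 / 300.0))
        err = np.linalg.norm(cov.matrix - np.eye(8)) / np.linalg.norm(np.eye(8))
        assert err < 0.10
        assert not cov.ill_conditioned

    def test_constant_signal_zero_matrix(self):
        cov = estimate_covariance(make_epochs(np.ones((3, 4, 100))), (0.0, 0.3))
        np.testing.assert_allclose(cov.matrix, 0.0, atol=1e-15)

    def test_rank_one_structure(self):
        t = np.arange(200) / 300.0
        wave = np.sin(2 * np.pi * 7 * t)
        data = np.zeros((2, 5, 200))
        data[:, 2, :] = wave
        cov = estimate_covariance(make_epochs(data), (0.0, 0.6))
        ev = np.sort(np.linalg.eigvalsh(cov.matrix))[::-1]
        assert ev[1] < 1e-6 * ev[0]

    def test_ill_conditioned_flag(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(3, 50, 30))
        cov = estimate_covariance(make_epochs(data), (0.0, 0.1))
        assert cov.ill_conditioned

    def test_psd(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(5, 6, 100))
        cov = estimate_covariance(make_epochs(data), (0.0, 0.3))
        ev = np.linalg.eigvalsh(cov.matrix)
        assert ev.min() >= -1e-10 * np.trace(cov.matrix)


class TestLcmvFilters:
    def setup_method(self):
        pos = p.make_sensor_layout(16, seed=1)
        self.fm = p.make_forward_model(6, pos, seed=2)

    def test_unit_gain_any_invertible_cov(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(16, 16))
        cov = CovarianceEstimate(matrix=a @ a.T + 16 * np.eye(16),
                                 window=(0, 1), n_trials=10)
        filt = lcmv_filters(self.fm, cov, lam=0.0, auto_regularize=False)
        for g in range(self.fm.n_grid):
            np.testing.assert_allclose(
                filt.filters[g] @ self.fm.leadfield(g), np.eye(3), atol=1e-8
            )

    def test_identity_cov_orthonormal_leadfield(self):
        # orthonormal L with C = I gives W = L^T
        q, _ = np.linalg.qr(np.random.default_rng(4).normal(size=(16, 3)))
        fm = p.ForwardModel(grid_positions=np.zeros((1, 3)), gain=q,
                            grid_spacing=10.0)
        cov = CovarianceEstimate(matrix=np.eye(16), window=(0, 1), n_trials=5)
        filt = lcmv_filters(fm, cov, lam=0.0, auto_regularize=False)
        np.testing.assert_allclose(filt.filters[0], q.T, atol=1e-10)

    def test_unregularized_filter_minimizes_variance(self):
        """lam = 0 is the minimum-variance solution: any diagonal loading
        can only raise the source output variance, and the output grows
        monotonically along a loading ladder for this data."""
        rng = np.random.default_rng(5)
        data = rng.normal(size=(10, 16, 300))
        es = make_epochs(data)
        cov = estimate_covariance(es, (0.0, 1.0))
        variances = []
        for lam in (0.0, 0.05, 0.2, 1.0):
            filt = lcmv_filters(self.fm, cov, lam=lam, auto_regularize=False)
            proj = project_orientation(filt, es)
            variances.append(proj.data.var())
        assert variances[0] == min(variances)
        assert all(b >= a * (1 - 1e-9) for a, b in zip(variances, variances[1:]))


class TestProjectOrientation:
    def test_single_orientation_source(self):
        """A source confined to one orientation is returned up to sign."""
        w = np.zeros((1, 3, 4))
        w[0] = np.eye(3, 4)
        filt = BeamformerFilters(filters=w, lam=0.0)
        t = np.arange(50) / 300.0
        wave = np.sin(2 * np.pi * 5 * t)
        data = np.zeros((2, 4, 50))
        data[:, 1, :] = wave  # maps onto orientation 2 only
        proj = project_orientation(filt, make_epochs(data))
        r = np.corrcoef(proj.data[0, 0], wave)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_isotropic_noise_variance(self):
        """Output variance approximates the top eigenvalue of the 3x3
        source covariance."""
        rng = np.random.default_rng(6)
        w = np.zeros((1, 3, 3))
        w[0] = np.diag([2.0, 1.0, 0.5])
        filt = BeamformerFilters(filters=w, lam=0.0)
        data = rng.normal(size=(20, 3, 400))
        proj = project_orientation(filt, make_epochs(data))
        src3 = np.einsum("os,nst->not", w[0], data)
        c3 = np.cov(src3.transpose(1, 0, 2).reshape(3, -1))
        top = np.linalg.eigvalsh(c3)[-1]
        assert proj.data.var() == pytest.approx(top, rel=0.05)

    def test_noiseless_end_to_end_recovery(self):
        """LCMV reconstruction at the true grid point recovers the injected
        waveform (|r| > 0.99) and localizes by output variance."""
        pos = p.make_sensor_layout(24, seed=2)
        fm = p.make_forward_model(12, pos, seed=3)
        cfg = p.SimulationConfig(n_participants=1, n_pairs=2, n_sensors=24,
                                 epoch_window=(-1.2, 0.2), word_onsets=(-1.0,),
                                 evoked_amplitude=0.0, identity_amplitude=1.0,
                                 noise_sd=0.0, seed=7)
        assign = {0: (5, (0.3, 1.0, -0.2)), 1: (5, (0.3, 1.0, -0.2))}
        es, truth = p.simulate_from_sources(fm, assign, cfg)
        cov = estimate_covariance(es[0], (-1.0, 0.2))
        filt = lcmv_filters(fm, cov)
        proj = project_orientation(filt, es[0])
        eff = truth.effect_samples
        wave = truth.participants[0]["identity_waveforms"][0]
        r = np.corrcoef(proj.data[0, 5, eff], wave)[0, 1]
        assert abs(r) > 0.99
        var = proj.data[:, :, eff].var(axis=(0, 2))
        assert var.argmax() == 5


class TestSourceRsaAndClusters:
    def test_identity_filters_match_sensor_level(self, tiny_dataset):
        """With filters that pass each sensor through unchanged, source-level
        temporal RSA equals the sensor-level maps."""
        epoch_sets, truth = tiny_dataset
        es = epoch_sets[0]
        s = es.n_sensors
        w = np.zeros((s, 3, s))
        for g in range(s):
            w[g, 0, g] = 1.0
        filt = BeamformerFilters(filters=w, lam=0.0)
        proj = project_orientation(filt, es)
        np.testing.assert_allclose(np.abs(proj.data[:, :, :]),
                                   np.abs(es.data), atol=1e-10)
        within = p.enumerate_within(truth.design)
        window = (-0.88, -0.485)
        maps_src, _ = average_condition_maps([proj], within, window)
        maps_sens, _ = average_condition_maps([es], within, window)
        np.testing.assert_allclose(maps_src, maps_sens, atol=1e-10)

    def test_zero_difference_map(self, tiny_dataset):
        epoch_sets, truth = tiny_dataset
        within = p.enumerate_within(truth.design)
        maps, _ = average_condition_maps(epoch_sets, within, (-0.88, -0.485))
        from pairrsa.source import source_temporal_rsa

        res = source_temporal_rsa(epoch_sets, within, within, (-0.88, -0.485),
                                  np.zeros((epoch_sets[0].n_sensors, 3)))
        np.testing.assert_allclose(res["difference"].values, 0.0, atol=1e-12)
        assert np.all(np.abs(res["within"].values) <= 1.0 + 1e-9)

    def test_grid_adjacency_lattice(self):
        pos = p.make_sensor_layout(27, seed=1)
        fm = p.make_forward_model(27, pos, seed=2, grid_spacing=10.0)
        adj = grid_adjacency(fm.grid_positions, fm.grid_spacing)
        assert np.array_equal(adj, adj.T)
        assert not np.any(np.diag(adj))
        # interior lattice points have up to 6 face neighbors
        assert adj.sum(axis=1).max() <= 6

    def test_single_point_grid_cluster(self):
        fm = p.ForwardModel(
            grid_positions=np.zeros((1, 3)),
            gain=np.random.default_rng(0).normal(size=(8, 3)),
            grid_spacing=10.0,
        )
        rng = np.random.default_rng(1)
        w = rng.normal(size=(6, 1)) + 1.0
        b = rng.normal(size=(6, 1))
        res = grid_cluster_test(w, b, fm, plan=PermutationPlan(n_perm=100, seed=2))
        assert all(len(c.members) == 1 and c.members[0] == 0 for c in res.clusters)


class TestPeakRegion:
    def test_uniform_cluster_returned_whole(self):
        vals = np.full(10, 0.5)
        members = np.arange(4, 9)
        np.testing.assert_array_equal(peak_region(vals, members), members)

    def test_single_dominant_peak(self):
        vals = np.zeros(10)
        vals[6] = 1.0
        vals[5] = 0.5
        out = peak_region(vals, np.array([4, 5, 6, 7]))
        np.testing.assert_array_equal(out, [6])

    def test_linear_gradient_fraction(self):
        # values 0 .. 1 over 11 points; fraction 0.85 keeps the top two
        vals = np.linspace(0.0, 1.0, 11)
        out = peak_region(vals, np.arange(11), fraction=0.85)
        np.testing.assert_array_equal(out, [9, 10])

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            peak_region(np.zeros(5), np.array([], dtype=int))


class TestOrientationScope:
    def test_per_trial_scope_matches_for_fixed_orientation_source(self):
        """When the source direction is constant, per-trial and
        per-participant orientation estimates agree up to sign."""
        w = np.zeros((1, 3, 4))
        w[0] = np.eye(3, 4)
        filt = BeamformerFilters(filters=w, lam=0.0)
        rng = np.random.default_rng(3)
        orient = np.array([0.6, 0.8, 0.0])
        data = np.einsum("o,nt->not", np.array([0.6, 0.8, 0.0, 0.0]),
                         rng.normal(size=(4, 80)))
        es = make_epochs(data)
        a = project_orientation(filt, es, scope="participant")
        b = project_orientation(filt, es, scope="trial")
        np.testing.assert_allclose(np.abs(a.data), np.abs(b.data), atol=1e-10)
        with pytest.raises(ValueError, match="scope"):
            project_orientation(filt, es, scope="bogus")
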