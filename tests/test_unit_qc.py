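"""Cluster-separation statistics against hand computations and nulls,
refractory/stability/duplicate identity checks."""

import math

import numpy as np
import pytest
from sklearn.metrics import davies_bouldin_score

from ceaphys.core import SpikeTrain
from ceaphys.synthetic import simulate_waveforms
from ceaphys.unit_qc import (ClusterFeatures, artificial_cluster_null,
                             correlogram, davies_bouldin, duplicate_units,
                             j3_statistic, refractory_check,
                             waveform_features, waveform_stability)

TOY = ClusterFeatures(np.array([[0., 0.], [2., 0.], [10., 0.], [12., 0.]]),
                      np.array([0, 0, 1, 1]))


class TestScatterStatistics:
    def test_j3_hand_example(self):
        # within scatter 4, between scatter 100
        assert j3_statistic(TOY) == pytest.approx(25.0)

    def test_db_hand_example(self):
        # spreads 1 and 1, centroid separation 10
        assert davies_bouldin(TOY) == pytest.approx(0.2)

    def test_point_mass_clusters_give_inf_j3(self):
        f = ClusterFeatures(np.array([[0., 0.], [0., 0.], [5., 5.]]),
                            np.array([0, 0, 1]))
        assert math.isinf(j3_statistic(f))

    def test_coincident_centroids_give_inf_db(self):
        f = ClusterFeatures(np.array([[0., 1.], [0., -1.], [1., 0.],
                                      [-1., 0.]]), np.array([0, 0, 1, 1]))
        assert math.isinf(davies_bouldin(f))

    def test_single_cluster_rejected(self):
        f = ClusterFeatures(np.array([[0., 0.], [1., 1.]]), np.array([0, 0]))
        with pytest.raises(ValueError):
            j3_statistic(f)
        with pytest.raises(ValueError):
            davies_bouldin(f)

    def test_db_matches_sklearn(self, rng):
        pts = np.vstack([rng.normal(0, 1, (40, 3)),
                         rng.normal(2.5, 1.3, (60, 3))])
        labels = np.repeat([0, 1], [40, 60])
        f = ClusterFeatures(pts, labels)
        assert davies_bouldin(f) == pytest.approx(
            davies_bouldin_score(pts, labels), rel=1e-9)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(0, 1, (60, 3))
        labels = rng.integers(0, 2, 60)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ q.T + np.array([5.0, -3.0, 2.0])
        f0, f1 = ClusterFeatures(pts, labels), ClusterFeatures(moved, labels)
        assert j3_statistic(f1) == pytest.approx(j3_statistic(f0))
        assert davies_bouldin(f1) == pytest.approx(davies_bouldin(f0))

    def test_db_scale_invariance(self):
        scaled = ClusterFeatures(TOY.points * 2, TOY.labels)
        assert davies_bouldin(scaled) == pytest.approx(davies_bouldin(TOY))

    def test_separation_sweep_monotone(self, rng):
        """J3 rises and DB falls as two fixed-spread Gaussian clusters
        move apart."""
        base = rng.normal(0, 1, (80, 2))
        labels = np.repeat([0, 1], 40)
        j3s, dbs = [], []
        for sep in (2.0, 4.0, 8.0, 16.0):
            pts = base.copy()
            pts[40:, 0] += sep
            f = ClusterFeatures(pts, labels)
            j3s.append(j3_statistic(f))
            dbs.append(davies_bouldin(f))
        assert np.all(np.diff(j3s) > 0)
        assert np.all(np.diff(dbs) < 0)


class TestFeatures:
    def test_identical_spikes_project_to_zero(self):
        ws = simulate_waveforms([np.sin(np.arange(24))], 10, 0.0, seed=0)[0]
        f = waveform_features(ws, n_components=2)
        assert np.allclose(f.points, 0.0)

    def test_projection_variances_equal_eigenvalues(self, rng):
        spikes = rng.normal(size=(500, 12)) @ rng.normal(size=(12, 12))
        from ceaphys.core import WaveformSet
        f = waveform_features(WaveformSet("u", 4e4, spikes), n_components=4)
        cov = np.cov(spikes, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1][:4]
        assert np.allclose(np.var(f.points, axis=0, ddof=1), eig, rtol=1e-6)

    def test_first_component_separates_two_templates(self):
        t1 = np.sin(np.linspace(0, 2 * np.pi, 32))
        t2 = -t1
        sets = simulate_waveforms([t1, t2], 200, 0.2, seed=3)
        f = waveform_features(sets, n_components=2)
        score = f.points[:, 0]
        side = score > 0
        frac = max(np.mean(side[:200]) + np.mean(~side[200:]),
                   np.mean(~side[:200]) + np.mean(side[200:])) / 2
        assert frac >= 0.99


class TestArtificialClusterNull:
    def test_single_split_gives_single_values(self, rng):
        cloud = rng.normal(size=(50, 2))
        null = artificial_cluster_null(cloud, n_splits=1, seed=0)
        assert null.j3.shape == (1,) and null.db.shape == (1,)

    def test_separated_clusters_beat_null(self, rng):
        cloud = rng.normal(size=(200, 2))
        null = artificial_cluster_null(cloud, n_splits=500, seed=1)
        sets = simulate_waveforms([np.sin(np.arange(16)),
                                   np.cos(np.arange(16)) * 2], 100, 0.1,
                                  seed=2)
        f = waveform_features(sets, n_components=2)
        j3_obs = j3_statistic(f)
        assert j3_obs > np.quantile(null.j3, 0.99)
        assert null.quantile_of("j3", j3_obs) == 1.0

    def test_null_median_stable_across_seeds(self, rng):
        cloud = rng.normal(size=(300, 2))
        m = [np.median(artificial_cluster_null(cloud, 400, seed=s).j3)
             for s in (0, 1)]
        assert m[0] == pytest.approx(m[1], rel=0.15)

    def test_random_split_of_single_cloud_within_null_iqr(self, rng):
        cloud = rng.normal(size=(200, 3))
        null = artificial_cluster_null(cloud, n_splits=800, seed=5)
        w = rng.normal(size=3)
        labels = ((cloud - cloud.mean(0)) @ w > 0).astype(int)
        j3 = j3_statistic(ClusterFeatures(cloud - cloud.mean(0), labels))
        lo, hi = np.quantile(null.j3, [0.005, 0.995])
        assert lo <= j3 <= hi

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            artificial_cluster_null(rng.normal(size=(3, 2)), 10)
        with pytest.raises(ValueError):
            artificial_cluster_null(rng.normal(size=(10, 2)), 0)


class TestRefractory:
    def test_single_spike_undefined(self):
        frac, _ = refractory_check(SpikeTrain("u", "s", np.array([1.0])))
        assert frac is None

    def test_poisson_violation_fraction_closed_form(self, rng):
        """For exponential ISIs at 20 Hz, P(ISI < 1 ms) = 1 - e^-0.02."""
        times = np.cumsum(rng.exponential(1 / 20.0, size=150_000))
        frac, _ = refractory_check(SpikeTrain("u", "s", times))
        p = 1 - math.exp(-0.02)
        se = math.sqrt(p * (1 - p) / 150_000)
        assert abs(frac - p) < 3 * se

    def test_dead_time_empties_central_autocorrelogram(self):
        times = np.arange(0.0, 10.0, 0.004)  # 4-ms spacing
        frac, acg = refractory_check(SpikeTrain("u", "s", times))
        assert frac == 0.0
        central = np.abs(acg.lag_centers) < 0.001
        assert acg.counts[central].sum() == 0


class TestStability:
    def test_identical_and_negated_waveforms(self):
        w = np.sin(np.linspace(0, 3, 40))
        assert waveform_stability(w, w) == pytest.approx(1.0)
        assert waveform_stability(w, -w) == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            waveform_stability(np.ones(10), np.arange(10.0))

    def test_snr_attenuation_matches_closed_form(self, rng):
        """Two independently-noised copies of a template correlate at
        s^2/(s^2+1) on average, s the per-sample SNR."""
        tpl = rng.normal(size=200)
        tpl = (tpl - tpl.mean()) / tpl.std()
        s = 1.5
        rs = []
        for _ in range(300):
            a = tpl + rng.normal(0, 1 / s, 200)
            b = tpl + rng.normal(0, 1 / s, 200)
            rs.append(waveform_stability(a, b))
        expected = s ** 2 / (s ** 2 + 1)
        se = np.std(rs, ddof=1) / math.sqrt(len(rs))
        assert abs(np.mean(rs) - expected) < 3 * se


class TestDuplicates:
    def poisson_train(self, rng, uid, rate=10.0, dur=600.0):
        n = rng.poisson(rate * dur)
        return SpikeTrain(uid, "s", np.sort(rng.uniform(0, dur, n)))

    def test_clone_flagged(self, rng):
        a = self.poisson_train(rng, "a")
        b = SpikeTrain("b", "s", a.spike_times.copy())
        flag, _ = duplicate_units(a, b)
        assert flag is True

    def test_jittered_clone_flagged(self, rng):
        a = self.poisson_train(rng, "a")
        jit = np.sort(a.spike_times + rng.uniform(-5e-4, 5e-4,
                                                  a.n_spikes))
        flag, _ = duplicate_units(a, SpikeTrain("b", "s", jit))
        assert flag is True

    def test_independent_trains_not_flagged(self, rng):
        a = self.poisson_train(rng, "a")
        b = self.poisson_train(rng, "b")
        flag, _ = duplicate_units(a, b)
        assert flag is False

    def test_symmetry(self, rng):
        a = self.poisson_train(rng, "a")
        b = self.poisson_train(rng, "b")
        assert duplicate_units(a, b)[0] == duplicate_units(b, a)[0]

    def test_too_few_spikes_indeterminate(self):
        a = SpikeTrain("a", "s", np.arange(10.0))
        b = SpikeTrain("b", "s", np.arange(10.0) + 0.5)
        flag, _ = duplicate_units(a, b)
        assert flag is None


def test_correlogram_counts_match_naive(rng):
    a = np.sort(rng.uniform(0, 20, 80))
    b = np.sort(rng.uniform(0, 20, 90))
    ccg = correlogram(SpikeTrain("a", "s", a), SpikeTrain("b", "s", b))
    lags = (b[None, :] - a[:, None]).ravel()
    expected = np.histogram(lags, bins=ccg.lag_edges)[0]
    assert np.array_equal(ccg.counts, expected)
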