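import numpy as np
import pytest
from scipy import stats

from molconn.atlas import SUBCORTICAL_NETWORK, load_region_table
from molconn.connectivity import (Connectome, edge_similarity, group_connectome,
                                  network_strength, network_strength_timecourse,
                                  sliding_window_connectomes, subject_connectome)
from molconn.kinetics import RegionalTimeSeries


def _random_connectome(rng, n=10, subject_id=""):
    return subject_connectome(rng.normal(size=(n, 40)), subject_id=subject_id)


class TestSubjectConnectome:
    def test_fisher_z_closed_form(self):
        # two series engineered to correlate at exactly r = 0.5
        n = 8
        x = np.concatenate([np.ones(n), -np.ones(n)])
        y = np.concatenate([np.ones(n // 2), -np.ones(n // 2)] * 2)
        a = x
        b = 0.5 * x + np.sqrt(1 - 0.25) * y  # corr(a, b) = 0.5 exactly
        conn = subject_connectome(np.vstack([a, b]))
        assert conn.z[0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert conn.z[0, 1] == pytest.approx(0.5493, abs=1e-4)

    def test_diagonal_zero_and_symmetric(self, rng):
        conn = _random_connectome(rng)
        assert np.all(np.diag(conn.z) == 0)
        assert np.array_equal(conn.z, conn.z.T)

    def test_matches_pairwise_pearson_oracle(self, rng):
        values = rng.normal(size=(48, 60))
        conn = subject_connectome(values)
        for i in range(0, 48, 7):
            for j in range(i + 1, 48, 5):
                r = stats.pearsonr(values[i], values[j])[0]
                assert conn.z[i, j] == pytest.approx(np.arctanh(r), abs=1e-12)

    def test_perfect_correlation_is_clipped_finite(self):
        x = np.linspace(0, 1, 10)
        conn = subject_connectome(np.vstack([x, 2 * x + 1]))
        assert np.isfinite(conn.z[0, 1])
        assert conn.z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_zero_variance_region_warns_and_zeroes_edges(self, rng):
        values = rng.normal(size=(3, 20))
        values[1] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            conn = subject_connectome(values)
        assert np.all(conn.z[1] == 0) and np.all(conn.z[:, 1] == 0)
        assert conn.z[0, 2] != 0

    def test_too_few_samples_errors(self, rng):
        with pytest.raises(ValueError, match="at least 3 samples"):
            subject_connectome(rng.normal(size=(4, 2)))

    def test_arctanh_tanh_identity_on_clipped_domain(self, rng):
        z = rng.uniform(-3, 3, size=100)
        assert np.allclose(np.arctanh(np.tanh(z)), z, atol=1e-10)


class TestGroupConnectome:
    def test_mean_is_elementwise_average(self, rng):
        conns = [_random_connectome(rng, 6) for _ in range(5)]
        g = group_connectome(conns)
        assert np.allclose(g.mean_z, np.mean([c.z for c in conns], axis=0))

    def test_consistent_positive_edges_all_survive_fwe(self, rng):
        base = np.abs(rng.normal(1.0, 0.1, size=(6, 6)))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 0)
        conns = []
        for _ in range(10):
            jitter = rng.normal(0, 1e-3, size=(6, 6))
            jitter = (jitter + jitter.T) / 2
            z = base + jitter
            np.fill_diagonal(z, 0)
            conns.append(Connectome(z=z, region_ids=[f"r{i}" for i in range(6)]))
        g = group_connectome(conns)
        iu = np.triu_indices(6, k=1)
        assert g.fwe_mask[iu].all()
        assert np.all(g.thresholded_mean_z()[iu] != 0)

    def test_thresholded_matrix_zeroes_failing_edges(self, rng):
        conns = [_random_connectome(rng, 8, subject_id=str(i)) for i in range(5)]
        g = group_connectome(conns)
        masked = g.thresholded_mean_z()
        assert np.all(masked[~g.fwe_mask] == 0)

    def test_permutation_equivariance(self, rng):
        conns = [_random_connectome(rng, 7) for _ in range(6)]
        g = group_connectome(conns)
        perm = rng.permutation(7)
        conns_p = [Connectome(z=c.z[np.ix_(perm, perm)],
                              region_ids=[c.region_ids[k] for k in perm])
                   for c in conns]
        gp = group_connectome(conns_p)
        assert np.allclose(gp.mean_z, g.mean_z[np.ix_(perm, perm)])
        assert np.array_equal(gp.fwe_mask, g.fwe_mask[np.ix_(perm, perm)])

    def test_mismatching_regions_error(self, rng):
        a = _random_connectome(rng, 5)
        b = _random_connectome(rng, 6)
        with pytest.raises(ValueError, match="mismatch"):
            group_connectome([a, b])


class TestEdgeSimilarity:
    def test_self_similarity_is_one(self, rng):
        a = _random_connectome(rng)
        assert edge_similarity(a, a) == pytest.approx(1.0)

    def test_negated_matrix_gives_minus_one(self, rng):
        a = _random_connectome(rng)
        b = Connectome(z=-a.z, region_ids=a.region_ids)
        assert edge_similarity(a, b) == pytest.approx(-1.0)

    def test_matches_lower_triangle_vector_oracle(self, rng):
        a, b = _random_connectome(rng), _random_connectome(rng)
        il = np.tril_indices(a.n_regions, k=-1)
        oracle = stats.pearsonr(a.z[il], b.z[il])[0]
        assert edge_similarity(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_and_affine_invariant(self, rng):
        a, b = _random_connectome(rng), _random_connectome(rng)
        r = edge_similarity(a, b)
        assert edge_similarity(b, a) == pytest.approx(r, abs=1e-12)
        a2 = Connectome(z=3.0 * a.z, region_ids=a.region_ids)
        assert edge_similarity(a2, b) == pytest.approx(r, abs=1e-10)


class TestSlidingWindows:
    def _ts(self, rng, n_regions=6, n_frames=80):
        return RegionalTimeSeries(values=rng.normal(size=(n_regions, n_frames)),
                                  region_ids=[f"r{i}" for i in range(n_regions)],
                                  frame_mid_min=np.arange(n_frames) + 0.5)

    def test_default_windows_start_20_to_60(self, rng):
        wins = sliding_window_connectomes(self._ts(rng))
        starts = [w.window_min[0] for w in wins]
        assert starts == [20, 25, 30, 35, 40, 45, 50, 55, 60]

    def test_each_window_equals_direct_connectome(self, rng):
        ts = self._ts(rng)
        wins = sliding_window_connectomes(ts)
        direct = subject_connectome(ts, window_min=(35.0, 55.0))
        assert np.allclose(wins[3].z, direct.z, atol=1e-14)

    def test_window_longer_than_series_errors(self, rng):
        short = self._ts(rng, n_frames=30)
        with pytest.raises(ValueError, match="longer than"):
            sliding_window_connectomes(short, window_len_min=40, start_min=0,
                                       end_min=30)

    def test_stationary_cohort_windows_are_similar(self, rng):
        """With a planted stable covariance, consecutive windows agree."""
        from molconn.connectivity import edge_similarity
        n, t = 12, 80
        shared = rng.normal(size=t)
        values = 1.2 * shared[None, :] + 0.6 * rng.normal(size=(n, t))
        ts = RegionalTimeSeries(values=values, region_ids=[f"r{i}" for i in range(n)],
                                frame_mid_min=np.arange(t) + 0.5)
        wins = sliding_window_connectomes(ts)
        sims = [edge_similarity(wins[k], wins[k + 1]) for k in range(len(wins) - 1)]
        assert np.mean(sims) > 0.7


class TestNetworkStrength:
    def test_constant_edges_give_constant_strength(self, region_table):
        ids = region_table.region_ids
        z = np.full((48, 48), 0.37)
        np.fill_diagonal(z, 0)
        conn = Connectome(z=z, region_ids=ids)
        s, node = network_strength(conn, SUBCORTICAL_NETWORK, region_table)
        assert s == pytest.approx(0.37)
        assert all(v == pytest.approx(0.37) for v in node.values())

    def test_identical_windows_give_p_one(self, region_table, rng):
        ids = region_table.region_ids
        z = rng.normal(size=(48, 48))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        conn = Connectome(z=z, region_ids=ids)
        windows = [[conn, conn, conn] for _ in range(5)]
        results, p_fdr, (t, p) = network_strength_timecourse(
            windows, SUBCORTICAL_NETWORK, region_table)
        assert t == 0.0 and p == 1.0
        assert np.all(p_fdr == 1.0)

    def test_missing_windows_error(self, region_table, rng):
        conn = _random_connectome(rng, 48)
        conn = Connectome(z=conn.z, region_ids=region_table.region_ids)
        with pytest.raises(ValueError, match="differing numbers"):
            network_strength_timecourse([[conn, conn], [conn]],
                                        SUBCORTICAL_NETWORK, region_table)
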