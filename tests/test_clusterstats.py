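"""Cluster permutation machinery: paired t maps against direct formulas,
connected components against a brute-force oracle, permutation determinism
and symmetry, and percentage summaries against counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from eegbench import clusterstats as cs
from eegbench import montage as mont
from eegbench import synth


@pytest.fixture(scope="module")
def adjacency():
    pos = mont.positions(mont.STANDARD_1020)
    return cs.sensor_adjacency(pos, list(mont.STANDARD_1020))


def random_statmap(rng, n_ch=4, n_f=5, n_t=6, scale=1.0):
    t = scale * rng.standard_normal((n_ch, n_f, n_t))
    return cs.StatMap(t=t, dof=19, channels=list(mont.STANDARD_1020[:n_ch]),
                      freqs=np.arange(n_f, dtype=float),
                      times=np.arange(n_t, dtype=float))


def small_adjacency(n_ch):
    # chain adjacency: i ~ i+1
    m = np.zeros((n_ch, n_ch), dtype=bool)
    for i in range(n_ch - 1):
        m[i, i + 1] = m[i + 1, i] = True
    return cs.Adjacency(m, list(mont.STANDARD_1020[:n_ch]))


def brute_force_clusters(t, adj_matrix, threshold):
    """Breadth-first connected components over supra-threshold bins."""
    n_ch, n_f, n_t = t.shape
    seen = np.zeros(t.shape, dtype=bool)
    out = []
    for sign in (1, -1):
        supra = sign * t > threshold
        for start in zip(*np.nonzero(supra)):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                c, f, ti = stack.pop()
                comp.append((c, f, ti))
                neigh = [(c, f, ti - 1), (c, f, ti + 1),
                         (c, f - 1, ti), (c, f + 1, ti)]
                neigh += [(c2, f, ti) for c2 in range(n_ch) if adj_matrix[c, c2]]
                for (c2, f2, t2) in neigh:
                    if (0 <= c2 < n_ch and 0 <= f2 < n_f and 0 <= t2 < n_t
                            and supra[c2, f2, t2] and not seen[c2, f2, t2]):
                        seen[c2, f2, t2] = True
                        stack.append((c2, f2, t2))
            out.append((sign, frozenset(comp)))
    return out


class TestThreshold:
    def test_default_is_90th_normal_percentile(self):
        assert round(stats.norm.ppf(0.90), 2) == cs.CLUSTER_THRESHOLD == 1.28


class TestAdjacency:
    def test_montage_graph_properties(self, adjacency):
        m = adjacency.matrix
        assert (m == m.T).all()
        assert not m.diagonal().any()
        assert m.any(axis=1).all()

    def test_neighbors_are_physically_close(self, adjacency):
        assert adjacency.matrix[mont.STANDARD_1020.index("O1"),
                                mont.STANDARD_1020.index("O2")]
        assert not adjacency.matrix[mont.STANDARD_1020.index("Fp1"),
                                    mont.STANDARD_1020.index("O2")]

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            cs.Adjacency(np.array([[0, 1], [0, 0]], dtype=bool), ["Cz", "Pz"])
        with pytest.raises(ValueError):
            cs.Adjacency(np.eye(2, dtype=bool), ["Cz", "Pz"])


class TestPairedTMap:
    def test_symmetric_trials_give_small_t(self):
        """Antithetic trial pairs cancel exactly: mean |t| below 0.2."""
        rng = np.random.default_rng(0)
        half = rng.standard_normal((100, 3, 4, 30))
        data = np.concatenate([half, -half])
        times = np.arange(-0.5, 1.0, 0.05)
        m = cs.paired_t_map(data, times, list(mont.STANDARD_1020[:3]),
                            np.arange(4.0))
        assert np.abs(m.t).mean() < 0.2

    def test_sign_convention_post_minus_baseline(self):
        rng = np.random.default_rng(1)
        times = np.arange(-0.5, 1.0, 0.05)
        data = rng.standard_normal((50, 2, 3, len(times)))
        data[..., times >= 0] += 2.0
        m = cs.paired_t_map(data, times, ["Cz", "Pz"], np.arange(3.0))
        assert (m.t[..., times >= 0] > 0).mean() > 0.95

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        times = np.arange(-0.5, 1.0, 0.05)
        data = rng.standard_normal((30, 2, 3, len(times))) + 0.3
        m = cs.paired_t_map(data, times, ["Cz", "Pz"], np.arange(3.0),
                            baseline=(-0.52, -0.12))
        sel = (times >= -0.52) & (times < -0.12)
        diffs = data - data[..., sel].mean(axis=-1, keepdims=True)
        ref = stats.ttest_1samp(diffs, 0.0, axis=0).statistic
        assert np.allclose(m.t, ref, atol=1e-10)

    def test_zero_variance_bin_flagged(self):
        times = np.arange(-0.5, 1.0, 0.05)
        data = np.random.default_rng(3).standard_normal((20, 1, 2, len(times)))
        data[:, 0, 0, :] = 5.0          # constant -> zero-variance diffs
        m = cs.paired_t_map(data, times, ["Cz"], np.arange(2.0))
        assert m.zero_variance_bins > 0
        assert np.all(m.t[0, 0] == 0.0)


class TestFindClusters:
    def test_subthreshold_map_is_empty(self):
        rng = np.random.default_rng(4)
        m = random_statmap(rng, scale=0.5)
        m.t.clip(-1.2, 1.2, out=m.t)
        cset = cs.find_clusters(m, small_adjacency(4))
        assert cset.clusters == []

    def test_rectangular_block_single_cluster(self):
        rng = np.random.default_rng(5)
        m = random_statmap(rng, scale=0.1)
        m.t[1, 1:3, 2:5] = 4.0
        cset = cs.find_clusters(m, small_adjacency(4))
        assert len(cset.clusters) == 1
        c = cset.clusters[0]
        assert c.sign == 1 and len(c.bins) == 6
        assert c.stat_max_abs == pytest.approx(4.0)

    def test_cross_channel_merge_requires_adjacency(self):
        """Supra-threshold bins at the same (f, t) on two channels form one
        cluster iff the channels are montage neighbors."""
        for chain, expected in ((((0, 1), (1, 2)), 1), (((0, 2), (1, 2)), 2)):
            m = random_statmap(np.random.default_rng(6), n_ch=3, scale=0.1)
            m.t[0, 2, 3] = m.t[1, 2, 3] = 3.0     # ch2 stays sub-threshold
            mat = np.zeros((3, 3), dtype=bool)
            for a, b in chain:
                mat[a, b] = mat[b, a] = True
            cset = cs.find_clusters(m, cs.Adjacency(mat, ["Cz", "Pz", "Fz"]))
            assert len(cset.clusters) == expected

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_components(self, seed):
        rng = np.random.default_rng(seed)
        m = random_statmap(rng, n_ch=4, n_f=4, n_t=5, scale=1.6)
        adj = small_adjacency(4)
        cset = cs.find_clusters(m, adj, threshold=1.28)
        ours = {(c.sign, frozenset(
            (b // (4 * 5), (b // 5) % 4, b % 5) for b in c.bins))
            for c in cset.clusters}
        ref = set(brute_force_clusters(m.t, adj.matrix, 1.28))
        assert ours == ref

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_threshold_monotonicity(self, seed):
        """Raising the threshold never enlarges any cluster."""
        rng = np.random.default_rng(seed)
        m = random_statmap(rng, scale=2.0)
        adj = small_adjacency(4)
        low = cs.find_clusters(m, adj, threshold=1.28)
        high = cs.find_clusters(m, adj, threshold=2.0)
        low_bins = set(np.concatenate([c.bins for c in low.clusters])
                       ) if low.clusters else set()
        for c in high.clusters:
            assert set(c.bins) <= low_bins


class TestPermutationTest:
    def _dataset(self, seed, effect=0.0, n_trials=24):
        rng = np.random.default_rng(seed)
        times = np.arange(-0.55, 1.0, 0.05)
        data = rng.standard_normal((n_trials, 3, 4, len(times)))
        if effect:
            data[:, 2, 2:, times >= 0.0] += effect
        return data, times

    def test_seed_determinism(self):
        data, times = self._dataset(0, effect=1.0)
        adj = small_adjacency(3)
        a = cs.permutation_test(data, times, ["Cz", "Pz", "Fz"],
                                np.arange(4.0), adj, n_perm=150, seed=5)
        b = cs.permutation_test(data, times, ["Cz", "Pz", "Fz"],
                                np.arange(4.0), adj, n_perm=150, seed=5)
        assert [c.p_fwer for c in a.clusters] == [c.p_fwer for c in b.clusters]

    def test_trial_order_invariance(self):
        """Reordering trials leaves the observed clusters identical and the
        permutation p-values equal up to permutation sampling resolution."""
        data, times = self._dataset(1, effect=0.8)
        adj = small_adjacency(3)
        a = cs.permutation_test(data, times, ["Cz", "Pz", "Fz"],
                                np.arange(4.0), adj, n_perm=300, seed=3)
        b = cs.permutation_test(data[::-1].copy(), times, ["Cz", "Pz", "Fz"],
                                np.arange(4.0), adj, n_perm=300, seed=3)
        stats_a = sorted(round(c.stat_max_abs, 9) for c in a.clusters)
        stats_b = sorted(round(c.stat_max_abs, 9) for c in b.clusters)
        assert stats_a == stats_b
        pa = np.array(sorted(c.p_fwer for c in a.clusters))
        pb = np.array(sorted(c.p_fwer for c in b.clusters))
        assert np.abs(pa - pb).max() < 0.12

    def test_sign_symmetry(self):
        data, times = self._dataset(2, effect=1.2)
        adj = small_adjacency(3)
        a = cs.permutation_test(data, times, ["Cz", "Pz", "Fz"],
                                np.arange(4.0), adj, n_perm=120, seed=1)
        b = cs.permutation_test(-data, times, ["Cz", "Pz", "Fz"],
                                np.arange(4.0), adj, n_perm=120, seed=1)
        assert sorted((c.sign, round(c.stat_max_abs, 9)) for c in a.clusters) \
            == sorted((-c.sign, round(c.stat_max_abs, 9)) for c in b.clusters)

    def test_effect_detected_with_mass_statistic_too(self):
        data, times = self._dataset(3, effect=1.5, n_trials=40)
        adj = small_adjacency(3)
        for statistic in ("max", "mass"):
            cset = cs.permutation_test(data, times, ["Cz", "Pz", "Fz"],
                                       np.arange(4.0), adj, n_perm=150,
                                       seed=0, statistic=statistic)
            assert min(c.p_fwer for c in cset.clusters) < 0.05

    def test_pvalues_within_bounds(self):
        data, times = self._dataset(4, effect=0.5)
        cset = cs.permutation_test(data, times, ["Cz", "Pz", "Fz"],
                                   np.arange(4.0), small_adjacency(3),
                                   n_perm=120, seed=2)
        for c in cset.clusters:
            assert 1 / 121 <= c.p_fwer <= 1.0


class TestSummaries:
    def _clusterset(self, member_bins, sign=1, shape=(3, 4, 5), p=0.01):
        clusters = [cs.Cluster(bins=np.array(member_bins), sign=sign,
                               stat_max_abs=5.0, stat_mass=10.0, p_fwer=p)]
        return cs.ClusterSet(clusters=clusters, shape=shape, threshold=1.28,
                             channels=list(mont.STANDARD_1020[:shape[0]]),
                             freqs=np.arange(shape[1], dtype=float),
                             times=np.arange(shape[2], dtype=float),
                             n_permutations=100)

    def test_no_significant_clusters_all_zero(self):
        cset = self._clusterset([0, 1], p=0.5)
        tf, topo = cs.summarize_clusters(cset)
        assert not tf[1].any() and not topo[1].any()

    def test_full_channel_coverage_is_100(self):
        shape = (3, 4, 5)
        bins = [c * 20 + 2 * 5 + 3 for c in range(3)]   # all ch at (f=2,t=3)
        tf, topo = cs.summarize_clusters(self._clusterset(bins, shape=shape))
        assert tf[1][2, 3] == pytest.approx(100.0)
        assert tf[1].sum() == pytest.approx(100.0)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(7)
        shape = (3, 4, 5)
        bins = rng.choice(60, size=17, replace=False)
        cset = self._clusterset(list(bins), shape=shape)
        tf, topo = cs.summarize_clusters(cset)
        member = np.zeros(shape, dtype=bool)
        member.ravel()[bins] = True
        assert np.allclose(tf[1], 100 * member.mean(axis=0))
        assert np.allclose(topo[1], 100 * member.mean(axis=(1, 2)))

    def test_gamma_effect_concentrates_on_injected_channels(self, quiet_profile,
                                                            adjacency):
        """gamma_gain=3 confined to O1/O2: topographic percentages peak
        there in the largest positive cluster summary."""
        from eegbench import spectral as sp
        from eegbench.pipeline import epoch_visual

        rec = synth.generate_visual(quiet_profile, n_trials=40, gamma_gain=3.0,
                                    alphabeta_drop=1.0,
                                    gamma_channels=("O1", "O2"), seed=4)
        ep = epoch_visual(rec)
        tfr = sp.multitaper_tfr(ep)
        cset = cs.permutation_test(tfr.data, tfr.times, tfr.channels,
                                   tfr.freqs, adjacency, n_perm=200, seed=0)
        gamma_sel = (tfr.freqs >= 50) & (tfr.freqs <= 75)
        roi = {"g": (50.0, 75.0 + 1e-6, 0.0, 1.0)}
        tf, topo = cs.summarize_clusters(cset, roi_boxes=roi)
        order = np.argsort(topo[1])[::-1]
        top2 = {tfr.channels[i] for i in order[:2]}
        assert top2 == {"O1", "O2"}
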