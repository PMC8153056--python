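import numpy as np
import pytest
from scipy import stats

from cardioaudio.cluster_stats import (AdjacencyGraph, Cluster,
                                       build_adjacency,
                                       cluster_permutation_test,
                                       condition_windows,
                                       extract_cluster_mean, form_clusters,
                                       interaction_contrast, pointwise_t)
from cardioaudio.containers import Evoked, SensorLayout
from helpers import ring_layout, smooth_null_field


def full_adjacency(n):
    return AdjacencyGraph([f"C{i}" for i in range(n)],
                          ~np.eye(n, dtype=bool))


class TestAdjacency:
    def test_distance_threshold(self):
        lay = SensorLayout(["a", "b", "c"],
                           [[0.0, 0.0], [0.10, 0.0], [0.0, 0.30]])
        adj = build_adjacency(lay, dist=0.15)
        names = adj.ch_names
        assert adj.neighbors[names.index("a"), names.index("b")]
        assert not adj.neighbors[names.index("a"), names.index("c")]

    def test_packaged_128_layout_median_degree(self, layout128):
        adj = build_adjacency(layout128, dist=0.15)
        assert np.median(adj.degrees) == 11

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            build_adjacency(SensorLayout.__new__(SensorLayout), 0.15) \
                if False else SensorLayout(["a", "a"], [[0, 0], [1, 1]])


class TestPointwiseT:
    def test_identical_conditions_zero_t(self, rng):
        a = rng.standard_normal((6, 4, 10))
        t, p = pointwise_t(a, a.copy(), "paired")
        assert np.allclose(t, 0.0)

    def test_matches_scipy_paired(self, rng):
        a = rng.standard_normal((5, 3, 7))
        b = rng.standard_normal((5, 3, 7))
        t, p = pointwise_t(a, b, "paired")
        ref_t, ref_p = stats.ttest_rel(a, b, axis=0)
        assert np.allclose(t, ref_t)
        assert np.allclose(p, ref_p)

    def test_matches_scipy_independent(self, rng):
        a = rng.standard_normal((6, 2, 5))
        b = rng.standard_normal((9, 2, 5))
        t, p = pointwise_t(a, b, "independent")
        ref_t, ref_p = stats.ttest_ind(a, b, axis=0)
        assert np.allclose(t, ref_t)
        assert np.allclose(p, ref_p)

    def test_misaligned_paired_rejected(self, rng):
        with pytest.raises(ValueError):
            pointwise_t(rng.standard_normal((5, 2, 4)),
                        rng.standard_normal((6, 2, 4)), "paired")


class TestFormClusters:
    def test_everything_supra_one_cluster_per_polarity(self):
        t = np.ones((5, 6))
        t[3:] = -1.0
        p = np.full_like(t, 0.001)
        cl = form_clusters(t, p, full_adjacency(5), min_channels=2)
        assert len(cl) == 2
        masses = sorted(c.mass for c in cl)
        assert masses == [-12.0, 18.0]

    def test_single_channel_streak_discarded(self):
        t = np.zeros((6, 20))
        p = np.ones_like(t)
        t[2, 5:15] = 4.0
        p[2, 5:15] = 0.001
        assert form_clusters(t, p, full_adjacency(6)) == []

    def test_single_timepoint_blob_discarded(self):
        t = np.zeros((6, 20))
        p = np.ones_like(t)
        t[:5, 7] = 4.0
        p[:5, 7] = 0.001
        assert form_clusters(t, p, full_adjacency(6)) == []

    def test_minimum_extent_cluster_kept(self):
        t = np.zeros((6, 20))
        p = np.ones_like(t)
        t[:4, 7:9] = 4.0
        p[:4, 7:9] = 0.001
        cl = form_clusters(t, p, full_adjacency(6))
        assert len(cl) == 1
        assert cl[0].n_channels == 4 and cl[0].time_extent == 2
        assert cl[0].mass == pytest.approx(32.0)

    def test_mass_additive_over_members(self, rng):
        t = rng.standard_normal((8, 30)) * 3
        p = 2 * stats.norm.sf(np.abs(t))
        for cl in form_clusters(t, p, full_adjacency(8)):
            assert cl.mass == pytest.approx(t[cl.channels, cl.times].sum())


class TestPermutationTest:
    def test_exhaustive_equals_explicit_enumeration(self, rng):
        lay = ring_layout(6)
        adj = build_adjacency(lay, 0.45)
        a, b = smooth_null_field(rng, lay, n_subj=8, n_t=20)
        auto = cluster_permutation_test(a, b, "paired", adj, seed=0)
        assert auto.method == "exhaustive" and auto.n_perm == 256
        bits = np.arange(256)
        signs = 1.0 - 2.0 * ((bits[:, None] >> np.arange(8)) & 1)
        manual = cluster_permutation_test(a, b, "paired", adj, seed=99,
                                          permutations=signs[::-1])
        assert [c.p for c in auto.clusters] == [c.p for c in manual.clusters]
        assert sorted(auto.null_max) == pytest.approx(sorted(manual.null_max))

    def test_relabel_symmetry(self, rng):
        lay = ring_layout(6)
        adj = build_adjacency(lay, 0.45)
        a, b = smooth_null_field(rng, lay, n_subj=9, n_t=25)
        r1 = cluster_permutation_test(a, b, "paired", adj, seed=5)
        r2 = cluster_permutation_test(b, a, "paired", adj, seed=5)
        assert sorted(c.p for c in r1.clusters) == \
            pytest.approx(sorted(c.p for c in r2.clusters))

    def test_large_effect_detected_in_injection_window(self, rng):
        lay = ring_layout(8)
        adj = build_adjacency(lay, 0.45)
        a, b = smooth_null_field(rng, lay, n_subj=20, n_t=50)
        a[:, 2:7, 20:30] += 5.0
        res = cluster_permutation_test(a, b, "paired", adj, n_perm=1000, seed=4)
        assert res.method == "montecarlo"
        best = res.clusters[0]
        assert best.p == pytest.approx(1.0 / 1001.0)
        assert set(best.times) & set(range(20, 30))
        assert set(best.channels) & set(range(2, 7))

    def test_few_permutations_warn(self, rng):
        lay = ring_layout(6)
        adj = build_adjacency(lay, 0.45)
        a, b = smooth_null_field(rng, lay, n_subj=16, n_t=10)
        with pytest.warns(UserWarning):
            cluster_permutation_test(a, b, "paired", adj, n_perm=50, seed=0)


class TestInteraction:
    def test_identical_cells_no_clusters(self, rng):
        base = rng.standard_normal((10, 6, 20))
        cells = np.stack([np.stack([base, base], axis=1)] * 2, axis=1)
        res = interaction_contrast(cells, full_adjacency(6), n_perm=200,
                                   seed=1)
        assert res.interaction.clusters == []
        assert res.simple_internal is None

    def test_additive_data_cancels_in_double_difference(self, rng):
        lay = ring_layout(6)
        adj = build_adjacency(lay, 0.45)
        n = 10
        cells = np.empty((n, 2, 2, 6, 30))
        att_eff = rng.standard_normal((n, 6, 30))
        dly_eff = rng.standard_normal((n, 6, 30))
        for i_att in range(2):
            for i_dly in range(2):
                noise = smooth_null_field(rng, lay, n, 30)[0]
                cells[:, i_att, i_dly] = (i_att * att_eff + i_dly * dly_eff
                                          + noise)
        res = interaction_contrast(cells, adj, n_perm=300, seed=2,
                                   run_simple_effects=False)
        # additive structure leaves the double difference pure noise
        assert res.interaction.min_p > 0.01

    def test_missing_cell_rejected(self, rng):
        cells = rng.standard_normal((5, 2, 2, 4, 10))
        cells[0, 1, 1] = np.nan
        with pytest.raises(ValueError):
            interaction_contrast(cells, full_adjacency(4))


class TestWindowsAndMeans:
    @pytest.mark.parametrize("analysis,cond,expected", [
        ("omission_locked", "short", (0.287, 0.500)),
        ("omission_locked", "long", (0.587, 0.800)),
        ("R_locked", "short", (0.0, 0.229)),
        ("R_locked", "long", (0.0, 0.229)),
    ])
    def test_literal_windows(self, analysis, cond, expected):
        assert condition_windows(analysis, cond) == expected

    def test_omission_relative_window(self):
        assert condition_windows("omission_locked", "short",
                                 relative_to_omission=True) == (0.0, 0.213)

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            condition_windows("R_locked", "medium")

    def test_cluster_mean_constant_field(self):
        ev = Evoked(np.ones((3, 10)), np.arange(10) / 512, 512.0,
                    ["a", "b", "c"], "x", 5)
        cl = Cluster(np.array([0, 1]), np.array([2, 2]), 1, 2.0)
        assert extract_cluster_mean(ev, cl) == 1.0

    def test_cluster_mean_matches_hand_computation(self):
        data = np.arange(8, dtype=float).reshape(2, 4)
        ev = Evoked(data, np.arange(4) / 512, 512.0, ["a", "b"], "x", 1)
        members = [(0, 1), (1, 2)]
        assert extract_cluster_mean(ev, members) == pytest.approx((1 + 6) / 2)

    def test_empty_member_set_rejected(self):
        ev = Evoked(np.ones((2, 4)), np.arange(4) / 512, 512.0,
                    ["a", "b"], "x", 1)
        with pytest.raises(ValueError):
            extract_cluster_mean(ev, [])
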