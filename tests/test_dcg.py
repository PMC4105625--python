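import itertools

import numpy as np
import pytest

from bidcg.dcg import (
    DCGConfig,
    build_dcg_tree,
    build_transition_matrix,
    ensemble_from_walks,
    estimate_cluster_count,
    find_critical_temperatures,
    ClusterCountProfile,
    make_temperature_grid,
    regulated_random_walk,
    scan_temperatures,
    segment_walk,
    tree_to_newick,
    ultrametric_distance,
)
from bidcg.distances import DistanceMatrix

from conftest import planted_blobs


def blocks_of(partition):
    return sorted(sorted(b) for b in partition.blocks)


class TestTransitionMatrix:
    def test_equal_distances_give_uniform_rows(self):
        d = DistanceMatrix(list("abc"), np.array([[0, 2, 2], [2, 0, 2],
                                                  [2, 2, 0]], float))
        p = build_transition_matrix(d, t=1.0)
        assert np.allclose(p[0], [0, 0.5, 0.5])
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_high_temperature_limit_is_uniform(self, two_pair_distances):
        p = build_transition_matrix(two_pair_distances,
                                    t=1e6 * two_pair_distances.values.max())
        off = p[p > 0]
        assert np.allclose(off, 1 / 3, atol=1e-3)

    def test_closed_form_normalization_linear_kernel(self):
        d = DistanceMatrix(list("abc"), np.array([[0, 1, 2], [1, 0, 3],
                                                  [2, 3, 0]], float))
        p = build_transition_matrix(d, t=1.0, kernel_power=1.0)
        z = np.exp(-1) + np.exp(-2)
        assert np.allclose(p[0], [0, np.exp(-1) / z, np.exp(-2) / z])

    def test_invalid_inputs(self, two_pair_distances):
        with pytest.raises(ValueError):
            build_transition_matrix(two_pair_distances, t=0.0)


class TestTemperatureGrid:
    def test_two_point_grid_is_endpoints(self, two_pair_distances):
        g = make_temperature_grid(two_pair_distances, n_temps=2)
        assert len(g) == 2

    def test_log_spacing(self, rng):
        from scipy.spatial.distance import pdist, squareform
        X = rng.uniform(size=(15, 3))
        d = DistanceMatrix([f"x{i}" for i in range(15)],
                           squareform(pdist(X)))
        g = make_temperature_grid(d, n_temps=20)
        ratios = g.temperatures[1:] / g.temperatures[:-1]
        assert np.allclose(ratios, ratios[0], atol=1e-9)

    def test_all_zero_distances_rejected(self):
        d = DistanceMatrix(list("ab"), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            make_temperature_grid(d)


class TestRegulatedWalk:
    def test_walk_is_full_permutation_with_recurrence_times(self):
        p = np.ones((6, 6)) - np.eye(6)
        w = regulated_random_walk(p, removal_threshold=5, rng_seed=0)
        assert sorted(w.removal_order.tolist()) == list(range(6))
        assert w.recurrence_times.shape == (6,)
        assert (w.recurrence_times >= 1).all()

    def test_deterministic_given_seed(self):
        p = np.ones((8, 8)) - np.eye(8)
        w1 = regulated_random_walk(p, 5, rng_seed=42)
        w2 = regulated_random_walk(p, 5, rng_seed=42)
        assert np.array_equal(w1.removal_order, w2.removal_order)
        assert np.array_equal(w1.recurrence_times, w2.recurrence_times)

    def test_pair_members_removed_together_at_low_temperature(
            self, two_pair_distances):
        from bidcg.dcg import _potential_weights

        W = _potential_weights(two_pair_distances.values, t=0.05)
        hits = 0
        for seed in range(200):
            w = regulated_random_walk(W, 5, rng_seed=seed)
            first_two = set(w.removal_order[:2].tolist())
            hits += first_two in ({0, 1}, {2, 3})
        assert hits / 200 > 0.9

    def test_single_stranded_node_terminates(self):
        # walk on 2 nodes: after one is retired the other is forced out
        p = np.array([[0.0, 1.0], [1.0, 0.0]])
        w = regulated_random_walk(p, 3, rng_seed=1)
        assert sorted(w.removal_order.tolist()) == [0, 1]


class TestEnsemble:
    def test_uncut_walk_gives_all_ones(self):
        p = np.ones((5, 5)) - np.eye(5)
        w = regulated_random_walk(p, 5, rng_seed=0)
        # constant recurrence times: no spikes, one segment
        lab = segment_walk(w)
        if lab.max() == 0:
            e = ensemble_from_walks([w])
            assert np.allclose(e.co_occurrence, 1.0)

    def test_two_pair_ensemble_separates(self, two_pair_distances):
        from bidcg.dcg import _potential_weights

        W = _potential_weights(two_pair_distances.values, t=0.05)
        walks = [regulated_random_walk(W, 5, s, 0.05) for s in range(100)]
        e = ensemble_from_walks(walks, two_pair_distances)
        co = e.co_occurrence
        assert co[0, 1] > 0.8 and co[2, 3] > 0.8
        assert co[0, 2] < 0.2 and co[1, 3] < 0.2
        assert estimate_cluster_count(e, d=two_pair_distances) == 2

    def test_inconsistent_walks_rejected(self):
        p4 = np.ones((4, 4)) - np.eye(4)
        p5 = np.ones((5, 5)) - np.eye(5)
        walks = [regulated_random_walk(p4, 5, 0),
                 regulated_random_walk(p5, 5, 0)]
        with pytest.raises(ValueError):
            ensemble_from_walks(walks)


class TestCriticalTemperatures:
    def test_plateau_starts(self):
        prof = ClusterCountProfile([0.1, 0.2, 0.3, 0.4, 0.5],
                                   [4, 4, 2, 2, 1])
        crit = find_critical_temperatures(prof, min_plateau_len=1)
        assert crit == [0.1, 0.3, 0.5]

    def test_constant_profile_single_plateau(self):
        prof = ClusterCountProfile([0.1, 0.2, 0.3], [3, 3, 3])
        assert find_critical_temperatures(prof) == [0.1]

    def test_too_short_profile_rejected(self):
        prof = ClusterCountProfile([0.1], [2])
        with pytest.raises(ValueError):
            find_critical_temperatures(prof)


class TestScan:
    def test_profile_matches_grid(self, two_pair_distances):
        grid = make_temperature_grid(two_pair_distances, n_temps=5)
        prof, ens = scan_temperatures(two_pair_distances, grid,
                                      walks_per_temp=10, rng_seed=0)
        assert np.array_equal(prof.temperatures, grid.temperatures)
        assert len(ens) == 5

    def test_high_temperature_limit_k_equals_one(self):
        d, _ = planted_blobs(3, 8, seed=5)
        pot_max = d.values.max() ** 2
        grid_vals = np.array([100 * pot_max, 200 * pot_max, 400 * pot_max])
        from bidcg.dcg import TemperatureGrid

        prof, _ = scan_temperatures(d, TemperatureGrid(grid_vals),
                                    walks_per_temp=20, rng_seed=0)
        assert (prof.counts == 1).all()


class TestDCGTree:
    def test_two_pair_toy_structure(self, two_pair_distances):
        tree = build_dcg_tree(two_pair_distances, DCGConfig(seed=1))
        assert blocks_of(tree.levels[0]) == [["a", "b"], ["c", "d"]]
        assert blocks_of(tree.levels[-1]) == [["a", "b", "c", "d"]]
        assert ultrametric_distance(tree, "a", "b") < \
            ultrametric_distance(tree, "a", "c")

    def test_two_scale_hierarchy(self, two_scale_distances):
        tree = build_dcg_tree(two_scale_distances, DCGConfig(seed=3))
        assert blocks_of(tree.levels[0]) == [["a", "b"], ["c", "d"],
                                             ["e", "f"], ["g", "h"]]
        assert blocks_of(tree.levels[1]) == [["a", "b", "c", "d"],
                                             ["e", "f", "g", "h"]]

    def test_minimal_two_item_tree(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        tree = build_dcg_tree(d, DCGConfig(seed=0))
        assert set(tree.items) == {"a", "b"}
        assert blocks_of(tree.levels[-1]) == [["a", "b"]]

    def test_nestedness_and_monotone_block_counts(self):
        d, _ = planted_blobs(4, 6, seed=9)
        tree = build_dcg_tree(d, DCGConfig(seed=9))
        counts = [len(p) for p in tree.levels]
        assert counts == sorted(counts, reverse=True)
        for fine, coarse in zip(tree.levels, tree.levels[1:]):
            for b in fine.blocks:
                assert any(b <= c for c in coarse.blocks)

    def test_ultrametric_inequality_exhaustive(self, two_scale_distances):
        tree = build_dcg_tree(two_scale_distances, DCGConfig(seed=3))
        items = tree.items
        for i, j, k in itertools.permutations(items, 3):
            u = lambda a, b: ultrametric_distance(tree, a, b)
            assert u(i, k) <= max(u(i, j), u(j, k)) + 1e-12

    def test_deterministic_given_seed(self, two_scale_distances):
        t1 = build_dcg_tree(two_scale_distances, DCGConfig(seed=7))
        t2 = build_dcg_tree(two_scale_distances, DCGConfig(seed=7))
        assert [blocks_of(p) for p in t1.levels] == \
            [blocks_of(p) for p in t2.levels]
        assert t1.level_heights == t2.level_heights

    def test_unknown_item_rejected(self, two_pair_distances):
        tree = build_dcg_tree(two_pair_distances, DCGConfig(seed=1))
        with pytest.raises(KeyError):
            ultrametric_distance(tree, "a", "zzz")


class TestNewickExport:
    def test_round_trips_through_a_parser(self, two_scale_distances):
        import io

        from Bio import Phylo

        tree = build_dcg_tree(two_scale_distances, DCGConfig(seed=3))
        nwk = tree_to_newick(tree)
        parsed = Phylo.read(io.StringIO(nwk), "newick")
        leaves = sorted(t.name for t in parsed.get_terminals())
        assert leaves == sorted(tree.items)


class TestPlantedRecovery:
    def test_planted_partitions_recovered(self):
        """Finest level recovers planted blobs in >=95% of seeded runs."""
        good = total = 0
        for c in (2, 3, 4, 5):
            for seed in range(10):
                d, truth = planted_blobs(c, 10, seed=1000 * c + seed)
                tree = build_dcg_tree(d, DCGConfig(seed=seed))
                found = sorted(sorted(int(x[1:]) for x in b)
                               for b in tree.levels[0].blocks)
                good += found == truth
                total += 1
        assert good / total >= 0.95
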