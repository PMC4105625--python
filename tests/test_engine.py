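import numpy as np
import pytest

from bidcg.benchmarks import generate_dataset
from bidcg.core import ExpressionMatrix, Partition
from bidcg.dcg import DCGConfig, DCGTree
from bidcg.engine import (
    BiDCG,
    BidcgConfig,
    candidate_gene_groups,
    check_dual_relationship,
    gene_tree_for_class,
    initial_sample_partition,
    naive_dcg_biclusters,
    reorder_heatmap,
    run_bidcg,
    sample_tree_for_genes,
)


@pytest.fixture(scope="module")
def small_dataset():
    """4 implanted modules of 6 genes x 4 conditions, light noise."""
    return generate_dataset("constant", 4, 6, 4, 0, 0.05, seed=5)


def make_tree(levels, heights):
    items = sorted(set().union(*levels[0]))
    return DCGTree(items, [Partition(items, lv) for lv in levels], heights)


class TestInitialPartition:
    def test_supervised_passthrough(self):
        m = ExpressionMatrix(np.eye(4), [f"g{i}" for i in range(4)],
                             ["s1", "s2", "s3", "s4"])
        labels = Partition(["s1", "s2", "s3", "s4"],
                           [{"s1", "s2"}, {"s3", "s4"}])
        out = initial_sample_partition(m, BidcgConfig(), labels)
        assert out is labels

    def test_unsupervised_covers_all_samples(self, small_dataset):
        part = initial_sample_partition(small_dataset.matrix,
                                        BidcgConfig(seed=5))
        assert set().union(*part.blocks) == set(small_dataset.matrix.sample_ids)

    def test_clean_modules_found_as_classes(self, small_dataset):
        part = initial_sample_partition(small_dataset.matrix,
                                        BidcgConfig(seed=5))
        truth_classes = {b.sample_ids for b in small_dataset.truth}
        assert truth_classes <= set(part.blocks)


class TestTreesForSubsets:
    def test_gene_tree_spans_all_genes(self, small_dataset):
        cls = next(iter(small_dataset.truth)).sample_ids
        tree = gene_tree_for_class(small_dataset.matrix, cls,
                                   BidcgConfig(seed=5))
        assert set(tree.items) == set(small_dataset.matrix.gene_ids)

    def test_gene_tree_isolates_module_genes(self, small_dataset):
        t0 = small_dataset.truth[0]
        tree = gene_tree_for_class(small_dataset.matrix, t0.sample_ids,
                                   BidcgConfig(seed=5))
        assert t0.gene_ids in candidate_gene_groups(tree, BidcgConfig(seed=5))

    def test_sample_tree_spans_all_samples(self, small_dataset):
        t0 = small_dataset.truth[0]
        tree = sample_tree_for_genes(small_dataset.matrix, t0.gene_ids,
                                     BidcgConfig(seed=5))
        assert set(tree.items) == set(small_dataset.matrix.sample_ids)

    def test_spearman_needs_enough_features(self, small_dataset):
        cfg = BidcgConfig(gene_metric="spearman")
        with pytest.raises(ValueError):
            gene_tree_for_class(small_dataset.matrix, {"c000", "c001"}, cfg)


class TestCandidateGeneGroups:
    def test_enumeration_matches_brute_force(self):
        tree = make_tree(
            [[{"a", "b"}, {"c"}, {"d", "e", "f"}],
             [{"a", "b", "c"}, {"d", "e", "f"}],
             [{"a", "b", "c", "d", "e", "f"}]],
            [0.1, 0.5, 1.0],
        )
        cfg = BidcgConfig(min_gene_group_size=2)
        got = candidate_gene_groups(tree, cfg)
        expect = {frozenset("ab"), frozenset("def"), frozenset("abc")}
        assert set(got) == expect  # full set excluded, dedup applied

    def test_min_size_filters_everything(self):
        tree = make_tree([[{"a"}, {"b"}], [{"a", "b"}]], [0.1, 0.2])
        assert candidate_gene_groups(tree, BidcgConfig(min_gene_group_size=3)) == []


class TestDualRelationship:
    @pytest.fixture
    def sample_tree(self):
        return make_tree(
            [[{"s1", "s2"}, {"s3"}, {"s4", "s5"}],
             [{"s1", "s2", "s3"}, {"s4", "s5"}],
             [{"s1", "s2", "s3", "s4", "s5"}]],
            [0.1, 0.5, 1.0],
        )

    def test_exact_class_block_found(self, sample_tree):
        ok, branch = check_dual_relationship(sample_tree, {"s1", "s2"},
                                             BidcgConfig())
        assert ok and branch == frozenset({"s1", "s2"})

    def test_no_pure_branch(self, sample_tree):
        cfg = BidcgConfig(branch_purity=1.0)
        ok, branch = check_dual_relationship(sample_tree, {"s2", "s3"}, cfg)
        assert not ok and branch is None

    def test_relaxed_coverage(self, sample_tree):
        cfg = BidcgConfig(branch_purity=1.0, coverage_fraction=0.8)
        # block {s4,s5} holds 2 of the 2-member class exactly
        ok, branch = check_dual_relationship(sample_tree, {"s4", "s5"}, cfg)
        assert ok and branch == frozenset({"s4", "s5"})
        # but covering only 2 of 3 class members fails at coverage 0.8
        ok, _ = check_dual_relationship(sample_tree, {"s1", "s2", "s4"},
                                        cfg)
        assert not ok

    def test_purity_threshold_allows_extension(self, sample_tree):
        cfg = BidcgConfig(branch_purity=0.6)
        ok, branch = check_dual_relationship(sample_tree, {"s1", "s2"}, cfg)
        assert ok and branch == frozenset({"s1", "s2"})


class TestRunBidcg:
    def test_recovers_small_planted_modules(self, small_dataset):
        res = run_bidcg(small_dataset.matrix, BidcgConfig(seed=5))
        found = {(b.gene_ids, b.sample_ids) for b in res.biclusters}
        truth = {(b.gene_ids, b.sample_ids) for b in small_dataset.truth}
        assert found == truth
        assert res.converged

    def test_single_implanted_block(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 0.2, size=(20, 12))
        values[4:10, 3:7] += 1.0
        m = ExpressionMatrix(values, [f"g{i:02d}" for i in range(20)],
                             [f"s{j:02d}" for j in range(12)])
        res = run_bidcg(m, BidcgConfig(seed=3))
        genes = {f"g{i:02d}" for i in range(4, 10)}
        samples = {f"s{j:02d}" for j in range(3, 7)}
        assert any(b.gene_ids == genes and b.sample_ids == samples
                   for b in res.biclusters)

    def test_every_bicluster_passes_dual_check(self, small_dataset):
        cfg = BidcgConfig(seed=5)
        res = run_bidcg(small_dataset.matrix, cfg)
        for b in res.biclusters:
            tree = sample_tree_for_genes(small_dataset.matrix, b.gene_ids, cfg)
            ok, _ = check_dual_relationship(tree, b.sample_ids, cfg)
            assert ok

    def test_idempotent_at_convergence(self, small_dataset):
        cfg = BidcgConfig(seed=5)
        res = run_bidcg(small_dataset.matrix, cfg)
        assert res.converged
        again = run_bidcg(small_dataset.matrix,
                          BidcgConfig(seed=5, max_sweeps=res.n_sweeps + 1))
        assert {(b.gene_ids, b.sample_ids) for b in again.biclusters} == \
            {(b.gene_ids, b.sample_ids) for b in res.biclusters}

    def test_deterministic_given_seed(self, small_dataset):
        r1 = run_bidcg(small_dataset.matrix, BidcgConfig(seed=8))
        r2 = run_bidcg(small_dataset.matrix, BidcgConfig(seed=8))
        assert {(b.gene_ids, b.sample_ids) for b in r1.biclusters} == \
            {(b.gene_ids, b.sample_ids) for b in r2.biclusters}

    def test_audit_log_records_every_test(self, small_dataset):
        res = run_bidcg(small_dataset.matrix, BidcgConfig(seed=5))
        assert res.audit
        assert {"sweep", "class", "genes", "dual", "accepted",
                "branch"} <= set(res.audit[0])


class TestNaiveBaseline:
    def test_clean_data_matches_iterative(self, small_dataset):
        nb = naive_dcg_biclusters(small_dataset.matrix, BidcgConfig(seed=5))
        truth_genes = {b.gene_ids for b in small_dataset.truth}
        assert {b.gene_ids for b in nb} == truth_genes


class TestReorderHeatmap:
    def test_single_bicluster_leads(self, small_dataset):
        m = small_dataset.matrix
        from bidcg.core import BiclusterSet

        b = BiclusterSet([small_dataset.truth[2]])
        rp, cp, rects = reorder_heatmap(m, b)
        t = small_dataset.truth[2]
        assert {m.gene_ids[i] for i in rp[:len(t.gene_ids)]} == set(t.gene_ids)
        assert {m.sample_ids[i] for i in cp[:len(t.sample_ids)]} == \
            set(t.sample_ids)
        assert rects[0][:2] == (0, len(t.gene_ids))

    def test_outputs_are_permutations(self, small_dataset):
        m = small_dataset.matrix
        rp, cp, _ = reorder_heatmap(m, small_dataset.truth)
        assert sorted(rp.tolist()) == list(range(m.shape[0]))
        assert sorted(cp.tolist()) == list(range(m.shape[1]))

    def test_disjoint_truth_gives_disjoint_diagonal_blocks(self):
        ds = generate_dataset("constant", 10, 10, 5, 0, 0.0, seed=2)
        rp, cp, rects = reorder_heatmap(ds.matrix, ds.truth)
        for k, (r0, r1, c0, c1) in enumerate(rects):
            t = ds.truth[k]
            assert (r1 - r0, c1 - c0) == (len(t.gene_ids), len(t.sample_ids))
        spans = sorted((r[0], r[1]) for r in rects)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 <= b0  # contiguous, non-overlapping rows


class TestModelFacade:
    def test_fit_returns_results_with_summary(self, small_dataset):
        res = BiDCG(small_dataset.matrix, seed=5).fit()
        text = res.summary()
        assert "biclusters" in text
        assert f"{len(res.biclusters)}" in text
        sc = res.scores(small_dataset.truth)
        assert sc.relevance == sc.recovery == 1.0

    def test_from_dataframe_and_overrides(self, small_dataset):
        df = small_dataset.matrix.to_frame()
        model = BiDCG.from_dataframe(df, seed=5, walks_per_temp=20)
        assert model.config.dcg.walks_per_temp == 20
        with pytest.raises(TypeError):
            BiDCG(df, bogus_option=1)

    def test_plot_heatmap_draws_rectangles(self, small_dataset):
        import matplotlib

        matplotlib.use("Agg")
        res = BiDCG(small_dataset.matrix, seed=5).fit()
        ax = res.plot_heatmap()
        assert len(ax.patches) == len(res.biclusters)
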