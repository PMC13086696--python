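"""Dendrograms, multiscale bootstrap, AU fitting, ensemble grouping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.stats import norm

from nanopotency.clustering import (
    AttemptResult,
    ClusterConfig,
    NodeSupport,
    attempt_to_newick,
    au_from_counts,
    co_cluster_summary,
    default_configs,
    dendrogram_node_sets,
    derive_groups,
    extract_supported,
    hierarchical_cluster,
    multiscale_bootstrap,
    run_attempt,
    run_ensemble,
    select_best_attempt,
)


class TestHierarchicalCluster:
    def test_nearest_pair_merges_first(self):
        X = np.array([[0.0], [1.0], [10.0]])
        Z = hierarchical_cluster(X, "single", "euclidean")
        sets = dendrogram_node_sets(Z, ["a", "b", "c"])
        assert sets[0] == frozenset({"a", "b"})

    def test_duplicate_rows_merge_at_height_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        Z = hierarchical_cluster(X, "complete", "manhattan")
        assert Z[0, 2] == 0.0

    def test_nan_cells_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            hierarchical_cluster(np.array([[1.0, np.nan], [0.0, 1.0]]), "average",
                                 "euclidean")

    @pytest.mark.parametrize("linkage", ["ward", "single"])
    def test_planted_four_cluster_partition_recovered(self, linkage):
        rng = np.random.default_rng(3)
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
        X = np.vstack([c + rng.normal(0, 0.3, size=(3, 2)) for c in centers])
        Z = hierarchical_cluster(X, linkage, "euclidean")
        cut = hierarchy.fcluster(Z, 4, criterion="maxclust")
        # brute-force check: rows from the same planted cluster share a label
        for i, j in itertools.combinations(range(12), 2):
            same_truth = i // 3 == j // 3
            assert (cut[i] == cut[j]) == same_truth


class TestMultiscaleBootstrap:
    def test_separated_groups_counted_in_every_resample(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.05, (3, 7)), rng.normal(9, 0.05, (3, 7))])
        labels = list("abcdef")
        cfg = ClusterConfig("average", "euclidean", nboot=50, seed=1)
        supports = {s.members: s for s in multiscale_bootstrap(X, labels, cfg)}
        for grp in (frozenset("abc"), frozenset("def")):
            assert all(c == 50 for c in supports[grp].bp_counts.values())

    def test_same_seed_identical_counts(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(6, 7))
        cfg = ClusterConfig("complete", "euclidean", nboot=30, seed=9)
        s1 = multiscale_bootstrap(X, list("abcdef"), cfg)
        s2 = multiscale_bootstrap(X, list("abcdef"), cfg)
        assert [s.bp_counts for s in s1] == [s.bp_counts for s in s2]

    def test_zero_nboot_rejected(self):
        with pytest.raises(ValueError):
            ClusterConfig("complete", "euclidean", nboot=0)

    def test_tiny_scales_skipped(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 3))  # round(0.4*3) = 1 feature -> skipped
        cfg = ClusterConfig("average", "euclidean", nboot=10, seed=0,
                            scales=(0.4, 1.0))
        supports = multiscale_bootstrap(X, list("abcde"), cfg)
        assert set(supports[0].bp_counts) == {1.0}


class TestAuFromCounts:
    def _support(self, counts_by_scale, nboot):
        ns = NodeSupport(members=frozenset("ab"), nboot=nboot)
        ns.bp_counts = dict(counts_by_scale)
        return ns

    def test_symmetric_bp_half_gives_au_half(self):
        ns = self._support({r: 500 for r in (0.4, 0.6, 0.8, 1.0, 1.2, 1.4)}, 1000)
        au_from_counts(ns)
        assert ns.au == pytest.approx(0.5, abs=1e-9)
        assert ns.bp == pytest.approx(0.5, abs=1e-9)

    def test_full_counts_pin_au_to_one(self):
        ns = self._support({r: 100 for r in (0.5, 1.0, 1.4)}, 100)
        au_from_counts(ns)
        assert ns.au == 1.0

    def test_zero_counts_pin_au_to_zero(self):
        ns = self._support({r: 0 for r in (0.5, 1.0, 1.4)}, 100)
        au_from_counts(ns)
        assert ns.au == 0.0

    def test_generate_and_recover_signed_distance_and_curvature(self):
        v, c, nboot = -1.0, 0.5, 10**6
        rng = np.random.default_rng(13)
        scales = np.round(np.arange(0.4, 1.41, 0.1), 10)
        counts = {float(r): int(rng.binomial(nboot, 1 - norm.cdf(v * np.sqrt(r) + c / np.sqrt(r))))
                  for r in scales}
        ns = self._support(counts, nboot)
        au_from_counts(ns)
        assert ns.v_signed == pytest.approx(v, abs=0.02)
        assert ns.c_curvature == pytest.approx(c, abs=0.02)
        assert ns.au == pytest.approx(1 - norm.cdf(v - c), abs=0.005)

    def test_single_scale_falls_back_to_bp(self):
        ns = self._support({1.0: 70}, 100)
        au_from_counts(ns)
        assert not ns.fit_ok
        assert ns.au == pytest.approx(0.7)


class TestExtractSupported:
    def _attempt_nodes(self, aus):
        out = []
        for members, au in aus.items():
            ns = NodeSupport(members=frozenset(members), nboot=100)
            ns.au = au
            out.append(ns)
        return out

    def test_no_support_means_all_singletons(self):
        nodes = self._attempt_nodes({("a", "b"): 0.5, ("a", "b", "c"): 0.9})
        supported, singles = extract_supported(nodes, frozenset("abc"), 0.95)
        assert supported == [] and singles == ["a", "b", "c"]

    def test_root_excluded_even_at_full_support(self):
        nodes = self._attempt_nodes({("a", "b"): 0.99, ("a", "b", "c"): 1.0})
        supported, singles = extract_supported(nodes, frozenset("abc"), 0.95)
        assert supported == [frozenset("ab")]
        assert singles == ["c"]

    def test_nested_supported_clusters_both_reported(self):
        nodes = self._attempt_nodes({("a", "b"): 0.99, ("a", "b", "c"): 0.97,
                                     ("a", "b", "c", "d"): 1.0})
        supported, singles = extract_supported(nodes, frozenset("abcd"), 0.95)
        assert frozenset("ab") in supported and frozenset("abc") in supported
        assert singles == ["d"]


class TestSelectBestAttempt:
    def _attempt(self, label, n_sup, n_single):
        cfg = ClusterConfig("complete", "euclidean", nboot=10, seed=0)
        sup = [frozenset({f"x{i}", f"y{i}"}) for i in range(n_sup)]
        return AttemptResult(cfg, [label], np.empty((0, 4)), [], sup,
                             [f"s{i}" for i in range(n_single)])

    def test_most_supported_clusters_wins_then_fewest_singletons(self):
        a = self._attempt("a", 3, 0)
        b = self._attempt("b", 5, 2)
        c = self._attempt("c", 5, 4)
        assert select_best_attempt([a, b, c]) is b

    def test_full_tie_keeps_first_config_order(self):
        a = self._attempt("a", 2, 1)
        b = self._attempt("b", 2, 1)
        assert select_best_attempt([a, b]) is a

    def test_single_attempt(self):
        a = self._attempt("a", 0, 5)
        assert select_best_attempt([a]) is a


class TestCoClusterSummary:
    def _attempt_with(self, labels, clusters):
        cfg = ClusterConfig("complete", "euclidean", nboot=10, seed=0)
        sup = [frozenset(c) for c in clusters]
        covered = set().union(*sup) if sup else set()
        singles = sorted(set(labels) - covered)
        return AttemptResult(cfg, list(labels), np.empty((0, 4)), [], sup, singles)

    def test_fraction_of_attempts_together(self):
        labels = list("abc")
        attempts = [self._attempt_with(labels, [("a", "b")])] * 10 + \
                   [self._attempt_with(labels, [])] * 2
        summ = co_cluster_summary(attempts)
        assert summ.co_occurrence.loc["a", "b"] == pytest.approx(10 / 12)
        assert summ.co_occurrence.loc["a", "a"] == 1.0

    def test_never_clustered_compound_flagged_with_zero_rows(self):
        labels = list("abc")
        attempts = [self._attempt_with(labels, [("a", "b")])] * 3
        summ = co_cluster_summary(attempts)
        assert summ.never_clustered == ["c"]
        assert summ.co_occurrence.loc["c"].sum() == 0.0
        assert summ.jaccard.loc["c"].sum() == 0.0

    def test_jaccard_over_pooled_clusters(self):
        labels = list("abc")
        attempts = [self._attempt_with(labels, [("a", "b")]),
                    self._attempt_with(labels, [("a", "c")])]
        summ = co_cluster_summary(attempts)
        # pooled clusters {a,b}, {a,c}: both contain a; only one contains b
        assert summ.jaccard.loc["a", "b"] == pytest.approx(0.5)
        assert summ.jaccard.loc["b", "c"] == 0.0

    def test_matrices_symmetric_and_bounded(self):
        labels = list("abcd")
        attempts = [self._attempt_with(labels, [("a", "b"), ("c", "d")]),
                    self._attempt_with(labels, [("a", "b", "c")])]
        summ = co_cluster_summary(attempts)
        for df in (summ.co_occurrence, summ.jaccard):
            arr = df.to_numpy()
            assert np.allclose(arr, arr.T)
            assert arr.min() >= 0.0 and arr.max() <= 1.0


class TestDeriveGroups:
    def _summary(self, labels, co):
        df = pd.DataFrame(co, index=labels, columns=labels, dtype=float)
        return type("S", (), {"co_occurrence": df})()

    def test_chain_links_into_one_component(self):
        co = [[1.0, 0.6, 0.1], [0.6, 1.0, 0.6], [0.1, 0.6, 1.0]]
        groups = derive_groups(self._summary(list("ABC"), co), threshold=0.5)
        assert groups == [["A", "B", "C"]]

    def test_threshold_above_one_gives_no_groups(self):
        co = [[1.0, 1.0], [1.0, 1.0]]
        assert derive_groups(self._summary(list("AB"), co), threshold=1.01) == []

    def test_singleton_components_dropped(self):
        co = [[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 0.0]]
        groups = derive_groups(self._summary(list("ABC"), co), threshold=0.5)
        assert groups == [["A", "B"]]


class TestEnsembleOnPlantedGroups:
    def test_group_recovery_and_newick_export(self, planted_two_group_matrix):
        attempts = run_ensemble(planted_two_group_matrix, nboot=40, seed=3)
        assert len(attempts) == 12
        assert [a.config.label for a in attempts] == [
            f"{lk}-{ds}" for lk in ("complete", "average", "single", "ward")
            for ds in ("euclidean", "manhattan", "minkowski")]
        summ = co_cluster_summary(attempts)
        groups = derive_groups(summ)
        assert groups == [[f"cmpd{i}" for i in range(4)],
                          [f"cmpd{i}" for i in range(4, 8)]]
        # Newick export parses with an independent tree library
        import dendropy

        nwk = attempt_to_newick(attempts[0])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 8

    def test_master_seed_reproducibility(self, planted_two_group_matrix):
        a1 = run_ensemble(planted_two_group_matrix, nboot=20, seed=7)
        a2 = run_ensemble(planted_two_group_matrix, nboot=20, seed=7)
        for x, y in zip(a1, a2):
            assert [s.bp_counts for s in x.node_supports] == \
                [s.bp_counts for s in y.node_supports]

    def test_monte_carlo_error_shrinks_with_nboot(self):
        # one fixed node with BP 0.7: AU spread across seeds shrinks as nboot grows
        rng = np.random.default_rng(0)
        scales = np.round(np.arange(0.4, 1.41, 0.1), 10)

        def au_draws(nboot, n=30):
            out = []
            for _ in range(n):
                ns = NodeSupport(members=frozenset("ab"), nboot=nboot)
                for r in scales:
                    p = 1 - norm.cdf(-0.3 * np.sqrt(r) + 0.2 / np.sqrt(r))
                    ns.bp_counts[float(r)] = int(rng.binomial(nboot, p))
                au_from_counts(ns)
                out.append(ns.au)
            return np.std(out)

        assert au_draws(10_000) < au_draws(100)
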