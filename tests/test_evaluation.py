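import numpy as np
import pytest

from mapclust import (
    Clustering,
    EnrichmentRecord,
    ReferenceClasses,
    count_unique_terms,
    enrich,
    evaluate_solution_set,
    f_beta,
    f_beta_of,
)
from _oracles import brute_f_beta, exact_hypergeom_tail


class TestFBeta:
    def test_perfect_recovery_scores_one(self):
        ref = ReferenceClasses(classes=[("L", {"a", "b"}), ("R", {"c", "d"})])
        score = f_beta([0, 0, 1, 1], ["a", "b", "c", "d"], ref)
        assert score == pytest.approx(1.0)

    def test_closed_form_half_overlap(self):
        # class of 4, cluster holds 2 of them plus 2 outsiders:
        # P = R = 0.5, F5 = 26 * 0.25 / (25 * 0.5 + 0.5) = 0.5
        ref = ReferenceClasses(classes=[("C", {"a", "b", "c", "d"})])
        ids = ["a", "b", "c", "d", "x", "y"]
        # best-matching cluster is {c, d, x, y}; a and b sit in singletons
        # whose F5 (P=1, R=0.25) is lower
        labels = [0, 1, 2, 2, 2, 2]
        assert f_beta(labels, ids, ref) == pytest.approx(0.5)

    def test_matches_pair_scan_oracle_on_random_toys(self):
        rng = np.random.default_rng(15)
        ids = [f"e{i}" for i in range(12)]
        for _ in range(30):
            labels = rng.integers(0, 4, size=12)
            groups = rng.integers(0, 3, size=12)
            classes = [
                (f"c{g}", {ids[i] for i in range(12) if groups[i] == g})
                for g in range(3)
                if (groups == g).any()
            ]
            ref = ReferenceClasses(classes=classes)
            assert f_beta(labels, ids, ref) == pytest.approx(
                brute_f_beta(labels, ids, classes, 5.0)
            )

    def test_large_beta_limit_is_weighted_recall(self):
        rng = np.random.default_rng(16)
        ids = [f"e{i}" for i in range(10)]
        labels = rng.integers(0, 3, size=10)
        groups = rng.integers(0, 2, size=10)
        classes = [(f"c{g}", {ids[i] for i in range(10) if groups[i] == g})
                   for g in range(2)]
        ref = ReferenceClasses(classes=classes)
        clusters = {}
        for i, lab in enumerate(labels):
            clusters.setdefault(int(lab), set()).add(ids[i])
        total = sum(len(m) for _, m in classes)
        recall = sum(
            len(m) / total * max(len(m & g) / len(m) for g in clusters.values())
            for _, m in classes
        )
        assert abs(f_beta(labels, ids, ref, beta=1e6) - recall) < 1e-6

    def test_invariant_under_relabeling_and_reordering(self):
        ref = ReferenceClasses(classes=[("L", {"a", "b"}), ("R", {"c"})])
        base = f_beta([0, 0, 1], ["a", "b", "c"], ref)
        relabeled = f_beta([5, 5, 2], ["a", "b", "c"], ref)
        reordered = f_beta([1, 0, 0], ["c", "b", "a"], ref)
        assert base == pytest.approx(relabeled) == pytest.approx(reordered)

    def test_per_cluster_variant_weighs_clusters(self):
        ref = ReferenceClasses(classes=[("L", {"a", "b"})])
        ids = ["a", "b", "c", "d"]
        # per-class ignores elements outside any class; per-cluster does not
        per_class = f_beta([0, 0, 1, 1], ids, ref, variant="per_class")
        per_cluster = f_beta([0, 0, 1, 1], ids, ref, variant="per_cluster")
        assert per_class == pytest.approx(1.0)
        assert per_cluster < 1.0

    def test_empty_reference_is_error(self):
        with pytest.raises(ValueError):
            ReferenceClasses(classes=[])


class TestEnrichment:
    def background(self, n):
        return [f"e{i}" for i in range(n)]

    def test_cluster_equal_to_background_is_never_surprising(self):
        bg = self.background(8)
        term_map = {e: {"T"} for e in bg[:5]}
        clu = Clustering(bg, np.zeros(8, int))
        records = enrich(clu, term_map, bg, alpha=0.05)
        assert len(records) == 1
        assert records[0].p_raw == pytest.approx(1.0)

    def test_tail_matches_exact_combinatorial_sum(self):
        # cluster of 5 with 4 carriers of T; background 50 with 5 carriers
        bg = self.background(50)
        carriers = bg[:5]
        term_map = {e: {"T"} for e in carriers}
        labels = np.ones(50, int)
        for i in range(4):
            labels[i] = 0
        labels[5] = 0  # cluster 0 = 4 carriers + 1 outsider
        clu = Clustering(bg, np.where(labels == 0, 0, 1))
        records = enrich(clu, term_map, bg, alpha=0.05)
        rec = next(r for r in records if r.cluster_id == 0 and r.term_id == "T")
        assert rec.a == 4 and rec.cluster_size == 5
        assert rec.p_raw == pytest.approx(exact_hypergeom_tail(4, 50, 5, 5))

    def test_tails_match_enumeration_for_small_backgrounds(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            M = int(rng.integers(6, 31))
            bg = self.background(M)
            n_annot = int(rng.integers(1, M))
            term_map = {bg[i]: {"T"} for i in rng.choice(M, n_annot, replace=False)}
            labels = rng.integers(0, 3, size=M)
            labels = np.unique(labels, return_inverse=True)[1]
            clu = Clustering(bg, labels)
            for rec in enrich(clu, term_map, bg, alpha=0.05):
                expected = exact_hypergeom_tail(
                    rec.a, rec.background_size, rec.background_annotated,
                    rec.cluster_size)
                assert rec.p_raw == pytest.approx(expected, rel=1e-9)

    def test_absent_term_never_reported(self):
        bg = self.background(6)
        term_map = {"e0": {"A"}, "e3": {"B"}}
        clu = Clustering(bg, np.array([0, 0, 0, 1, 1, 1]))
        records = enrich(clu, term_map, bg, alpha=0.05)
        reported = {(r.cluster_id, r.term_id) for r in records}
        assert reported == {(0, "A"), (1, "B")}

    def test_bh_adjustment_properties(self):
        bg = self.background(20)
        term_map = {}
        rng = np.random.default_rng(31)
        for t in "ABCDE":
            for i in rng.choice(20, 6, replace=False):
                term_map.setdefault(bg[i], set()).add(t)
        clu = Clustering(bg, np.array([0] * 10 + [1] * 10))
        records = enrich(clu, term_map, bg, alpha=0.05)
        for cid in (0, 1):
            sub = sorted((r for r in records if r.cluster_id == cid),
                         key=lambda r: r.p_raw)
            adj = [r.p_adj for r in sub]
            assert all(a >= r.p_raw for a, r in zip(adj, sub))
            assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))

    def test_single_term_adjustment_is_identity(self):
        bg = self.background(10)
        term_map = {e: {"T"} for e in bg[:3]}
        clu = Clustering(bg, np.array([0] * 5 + [1] * 5))
        for rec in enrich(clu, term_map, bg, alpha=0.05):
            assert rec.p_adj == pytest.approx(rec.p_raw)

    def test_alpha_out_of_range(self):
        bg = self.background(4)
        clu = Clustering(bg, np.zeros(4, int))
        with pytest.raises(ValueError):
            enrich(clu, {}, bg, alpha=1.5)


class TestUniqueTermCounting:
    def make(self, cid, term, p_adj):
        return EnrichmentRecord(cluster_id=cid, term_id=term, a=1,
                                cluster_size=2, background_annotated=2,
                                background_size=10, p_raw=p_adj, p_adj=p_adj)

    def test_no_enriched_records(self):
        assert count_unique_terms([self.make(0, "T", 0.9)], alpha=0.05) == 0

    def test_term_in_three_clusters_counts_once(self):
        records = [self.make(c, "T", 0.001) for c in range(3)]
        assert count_unique_terms(records, alpha=0.05) == 1

    def test_union_across_clusters(self):
        records = [self.make(0, t, 0.001) for t in ("T1", "T2")]
        records += [self.make(1, t, 0.001) for t in ("T2", "T3")]
        assert count_unique_terms(records, alpha=0.05) == 3


class TestSolutionSetTable:
    def test_one_row_per_solution_with_term_counts(self):
        ids = [f"e{i}" for i in range(8)]
        ref = ReferenceClasses(classes=[("L", set(ids[:4])), ("R", set(ids[4:]))])
        term_map = {e: {"T"} for e in ids[:4]}
        solutions = {
            2: Clustering(ids, np.array([0] * 4 + [1] * 4)),
            4: Clustering(ids, np.array([0, 0, 1, 1, 2, 2, 3, 3])),
        }
        table = evaluate_solution_set(
            solutions, ref, {"GO": term_map}, alphas=[0.05, 0.01], background=ids,
            method="hcw", metric_pair="eu")
        assert len(table) == 2
        assert list(table["k"]) == [2, 4]
        assert table.loc[table.k == 2, "f5"].item() == pytest.approx(1.0)
        assert {"unique_GO_terms_p0.05", "unique_GO_terms_p0.01"} <= set(table.columns)

    def test_summed_f_measure_ranks_methods(self):
        ids = [f"e{i}" for i in range(4)]
        ref = ReferenceClasses(classes=[("L", set(ids[:2])), ("R", set(ids[2:]))])
        good = {2: Clustering(ids, np.array([0, 0, 1, 1]))}
        bad = {2: Clustering(ids, np.array([0, 1, 0, 1]))}
        t_good = evaluate_solution_set(good, ref, {}, [0.05], ids, method="good")
        t_bad = evaluate_solution_set(bad, ref, {}, [0.05], ids, method="bad")
        assert t_good["f5"].sum() > t_bad["f5"].sum()
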