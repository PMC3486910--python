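"""The HGT chain: screen, nearest-neighbor inference, support, summary."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from endohgt import hgt
from endohgt.io_formats import HitRecord, TaxonRecord
from endohgt.tree import read_newick
from _oracles import graph_path_metrics, oracle_candidate, random_tree

SELF = "Bacteroidetes"

TAX = {
    "InPhylum": TaxonRecord("InPhylum", SELF, "X"),
    "OutPhylum": TaxonRecord("OutPhylum", "Proteobacteria", "ART"),
    "Focal": TaxonRecord("Focal", SELF, "ART"),
}


def _hits(gene, taxa):
    return [
        HitRecord(
            query_id=gene,
            subject_id=f"s{i}",
            subject_taxon=taxon,
            percent_identity=90.0 - i,
            alignment_length=100,
            evalue=10.0 ** -(50 - i),
            bitscore=200.0 - i,
            rank=i + 1,
        )
        for i, taxon in enumerate(taxa)
    ]


class TestScreen:
    def test_all_outside_is_candidate(self):
        tables = {"g1": _hits("g1", ["OutPhylum"] * 10)}
        [cand] = hgt.screen_hgt_candidates(tables, TAX)
        assert cand.candidate and cand.outside_phylum_in_top_k == 10

    def test_within_phylum_hit_blocks(self):
        taxa = ["OutPhylum"] * 10
        taxa[2] = "InPhylum"
        [cand] = hgt.screen_hgt_candidates({"g1": _hits("g1", taxa)}, TAX)
        assert not cand.candidate
        assert cand.outside_phylum_in_top_k == 9

    def test_too_few_hits_strict_and_lenient(self):
        tables = {"g1": _hits("g1", ["OutPhylum"] * 7)}
        [strict] = hgt.screen_hgt_candidates(tables, TAX)
        assert not strict.candidate and strict.excluded_reason == "too_few_hits"
        [lenient] = hgt.screen_hgt_candidates(tables, TAX, lenient=True)
        assert lenient.candidate

    def test_self_hits_removed_before_ranking(self):
        taxa = ["Focal"] * 3 + ["OutPhylum"] * 10
        [cand] = hgt.screen_hgt_candidates(
            {"g1": _hits("g1", taxa)}, TAX, self_taxon="Focal"
        )
        assert cand.candidate and cand.n_hits_examined == 10

    @pytest.mark.parametrize(
        "product, reason",
        [
            ("IS5 family transposase", "transposase"),
            ("ankyrin repeat protein", "repeat_protein"),
            ("Na+/proline symporter", "symporter_family"),
        ],
    )
    def test_product_exclusions(self, product, reason):
        tables = {"g1": _hits("g1", ["OutPhylum"] * 10)}
        [cand] = hgt.screen_hgt_candidates(tables, TAX, products={"g1": product})
        assert not cand.candidate and cand.excluded_reason == reason

    def test_shared_with_sister_excluded(self):
        tables = {"g1": _hits("g1", ["OutPhylum"] * 10)}
        [cand] = hgt.screen_hgt_candidates(tables, TAX, shared_with_sister={"g1"})
        assert not cand.candidate and cand.excluded_reason == "shared_with_sister_genome"

    def test_unknown_taxon_policy(self):
        tables = {"g1": _hits("g1", ["Mystery"] * 10)}
        with pytest.raises(KeyError):
            hgt.screen_hgt_candidates(tables, TAX)
        with pytest.warns(UserWarning):
            [cand] = hgt.screen_hgt_candidates(tables, TAX, unknown_taxon="outside")
        assert cand.candidate

    @pytest.mark.parametrize("k", [3, 10])
    @pytest.mark.parametrize("lenient", [False, True])
    def test_exhaustive_rule_evaluation(self, k, lenient):
        """Every in/out hit composition with n <= 12 matches the rule."""
        for n in range(0, 13):
            for combo in itertools.product((SELF, "Proteobacteria"), repeat=n):
                taxa = ["InPhylum" if p == SELF else "OutPhylum" for p in combo]
                tables = {"g": _hits("g", taxa)}
                [cand] = hgt.screen_hgt_candidates(tables, TAX, k=k, lenient=lenient)
                assert cand.candidate == oracle_candidate(list(combo), SELF, k, lenient), (
                    n, combo,
                )

    def test_monotone_in_k(self):
        rng = np.random.default_rng(55)
        for _ in range(50):
            taxa = [
                "OutPhylum" if rng.random() < 0.8 else "InPhylum"
                for _ in range(int(rng.integers(10, 13)))
            ]
            tables = {"g": _hits("g", taxa)}
            [at5] = hgt.screen_hgt_candidates(tables, TAX, k=5, lenient=True)
            [at10] = hgt.screen_hgt_candidates(tables, TAX, k=10, lenient=True)
            if not at5.candidate:
                assert not at10.candidate


class TestNearestNeighbor:
    def test_tie_broken_by_branch_length(self):
        tree = read_newick("(Q:1,B:1,C:0.5);")
        tax = {"B": TaxonRecord("B", "P", "ART"), "C": TaxonRecord("C", "P", "AM")}
        call = hgt.infer_nearest_neighbor(tree, "Q", tax)
        assert call.neighbor_taxon == "C"
        assert call.neighbor_category == "AM"
        assert call.internal_node_count == 1
        assert call.branch_length_sum == pytest.approx(1.5)

    def test_node_count_dominates(self):
        tree = read_newick("((Q:1,X:1):1,(Y:1,Z:1):1,W:2);")
        tax = {t: TaxonRecord(t, "P", "X") for t in "XYZW"}
        call = hgt.infer_nearest_neighbor(tree, "Q", tax)
        assert call.neighbor_taxon == "X"
        assert call.internal_node_count == 1

    def test_leaves_without_taxonomy_ignored(self):
        tree = read_newick("(Q:1,B:0.1,C:5);")
        tax = {"C": TaxonRecord("C", "P", "E")}
        assert hgt.infer_nearest_neighbor(tree, "Q", tax).neighbor_taxon == "C"
        with pytest.raises(ValueError):
            hgt.infer_nearest_neighbor(tree, "Q", {})

    def test_matches_bruteforce_argmin_on_random_trees(self):
        rng = np.random.default_rng(314)
        for _ in range(200):
            n = int(rng.integers(4, 15))
            newick, graph, leaves = random_tree(rng, n)
            tree = read_newick(newick)
            query = leaves[int(rng.integers(0, n))]
            tax = {l: TaxonRecord(l, "P", "X") for l in leaves if l != query}
            call = hgt.infer_nearest_neighbor(tree, query, tax)
            expected = min(
                (l for l in leaves if l != query),
                key=lambda l: (*graph_path_metrics(graph, query, l), l),
            )
            expected_metrics = graph_path_metrics(graph, query, expected)
            got_metrics = (call.internal_node_count, call.branch_length_sum)
            assert got_metrics[0] == expected_metrics[0]
            assert got_metrics[1] == pytest.approx(expected_metrics[1], abs=1e-6)
            assert call.neighbor_taxon == expected


class TestSupportAndRetention:
    TAX2 = {
        "B": TaxonRecord("B", "P", "ART"),
        "C": TaxonRecord("C", "P", "AM"),
    }

    def test_full_agreement(self):
        trees = [read_newick("(Q:1,B:1,C:0.5);")] * 4
        assert hgt.assess_support(trees, "Q", self.TAX2, "AM") == pytest.approx(100.0)

    def test_half_agreement(self):
        trees = [read_newick("(Q:1,B:1,C:0.5);"), read_newick("(Q:1,B:0.5,C:1);")] * 2
        assert hgt.assess_support(trees, "Q", self.TAX2, "AM") == pytest.approx(50.0)

    def test_missing_query_skipped_with_warning(self):
        trees = [read_newick("(Q:1,B:1,C:0.5);"), read_newick("(X:1,B:1,C:1);")]
        with pytest.warns(UserWarning):
            support = hgt.assess_support(trees, "Q", self.TAX2, "AM")
        assert support == pytest.approx(100.0)
        with pytest.raises(ValueError):
            hgt.assess_support([read_newick("(X:1,B:1,C:1);")], "Q", self.TAX2, "AM")

    @staticmethod
    def _call(category, gene="g1", source="NJ"):
        return hgt.DonorCall(
            gene_id=gene, tree_source=source, neighbor_taxon="T",
            neighbor_category=category, internal_node_count=1, branch_length_sum=1.0,
        )

    def test_retention_rules(self):
        nj, ml = self._call("AM"), self._call("AM", source="ML")
        assert hgt.consistency_filter(nj, ml, 80.0)
        assert not hgt.consistency_filter(nj, ml, 75.0)  # strictly greater than
        assert not hgt.consistency_filter(nj, self._call("ART", source="ML"), 90.0)

    def test_filter_symmetric_and_checks_gene(self):
        nj, ml = self._call("AM"), self._call("AM", source="ML")
        assert hgt.consistency_filter(nj, ml, 90.0) == hgt.consistency_filter(ml, nj, 90.0)
        with pytest.raises(ValueError, match="mismatch"):
            hgt.consistency_filter(nj, self._call("AM", gene="g2"), 90.0)


class TestCategorySummary:
    def test_worked_example(self):
        calls = []
        for cat, count in [("ART", 19), ("AM", 7), ("AA", 12), ("X", 8), ("E", 4)]:
            calls += [TestSupportAndRetention._call(cat, gene=f"{cat}{i}") for i in range(count)]
        summary = hgt.summarize_categories(calls)
        assert summary.n_total == 50
        assert summary.fractions_percent == pytest.approx(
            {"ART": 38.0, "AM": 14.0, "AA": 24.0, "X": 16.0, "E": 8.0}
        )
        assert sum(summary.fractions_percent.values()) == pytest.approx(100.0)

    def test_single_call(self):
        summary = hgt.summarize_categories([TestSupportAndRetention._call("E")])
        assert summary.fractions_percent["E"] == pytest.approx(100.0)

    def test_matches_independent_tally(self):
        rng = np.random.default_rng(6)
        cats = [str(c) for c in rng.choice(["AM", "AA", "ART", "E", "X"], size=40)]
        calls = [TestSupportAndRetention._call(c, gene=f"g{i}") for i, c in enumerate(cats)]
        summary = hgt.summarize_categories(calls)
        for cat in ("AM", "AA", "ART", "E", "X"):
            assert summary.counts[cat] == cats.count(cat)
            assert summary.fractions_percent[cat] == pytest.approx(100.0 * cats.count(cat) / 40)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hgt.summarize_categories([])
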