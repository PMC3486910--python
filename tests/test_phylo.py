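"""Distances, neighbor joining, bootstrap, and tree path metrics."""

from __future__ import annotations

import numpy as np
import pytest

from endohgt import phylo
from endohgt.io_formats import AlignmentSet
from endohgt.phylo import DistanceMatrix, bootstrap_nj, nj_tree, pdistance_matrix
from endohgt.tree import read_newick
from _oracles import additive_matrix, graph_path_metrics, random_tree


class TestPDistance:
    def test_identical_sequences(self):
        aln = AlignmentSet({"A": "MKVL", "B": "MKVL", "C": "MKVL"})
        dm = pdistance_matrix(aln)
        assert np.allclose(dm.d, 0.0)

    def test_half_different(self):
        dm = pdistance_matrix(AlignmentSet({"A": "AAAA", "B": "AATT"}))
        assert dm.value("A", "B") == pytest.approx(0.5)

    def test_gap_handling_against_hand_count(self):
        # columns:        123456
        aln = AlignmentSet({"A": "MK-LQR", "B": "MKV-QR", "C": "MAVLQW"})
        pairwise = pdistance_matrix(aln, "pairwise_deletion")
        # A/B comparable columns: 1,2,5,6 -> 0 mismatches
        assert pairwise.value("A", "B") == pytest.approx(0.0)
        # A/C comparable: 1,2,4,5,6 -> mismatches at 2 (K/A) and 6 (R/W)
        assert pairwise.value("A", "C") == pytest.approx(2 / 5)
        # B/C comparable: 1,2,3,5,6 -> mismatches at 2 and 6
        assert pairwise.value("B", "C") == pytest.approx(2 / 5)
        complete = pdistance_matrix(aln, "complete_deletion")
        # ungapped columns: 1,2,5,6; A/C and B/C differ at 2 of 4
        assert complete.value("A", "B") == pytest.approx(0.0)
        assert complete.value("A", "C") == pytest.approx(0.5)

    def test_no_comparable_columns_names_pair(self):
        aln = AlignmentSet({"A": "MK--", "B": "--VL", "C": "MKVL"})
        with pytest.raises(ValueError, match="'A' and 'B'"):
            pdistance_matrix(aln, "pairwise_deletion")

    def test_poisson_correction(self):
        dm = pdistance_matrix(AlignmentSet({"A": "AAAA", "B": "AATT"}), model="poisson")
        assert dm.value("A", "B") == pytest.approx(-np.log(0.5))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = nj_tree(dm)
        lengths = {n.label: n.length for n in tree.iter_leaves()}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> pairwise distances below
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))
        assert tree.path_metrics("A", "B").internal_node_count == 1
        assert tree.path_metrics("C", "D").internal_node_count == 1
        assert tree.path_metrics("A", "C").internal_node_count == 2
        got = phylo.tree_distance_matrix(tree)
        assert np.allclose(got.d, d, atol=1e-9)

    def test_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            n = int(rng.integers(4, 8))
            newick, graph, leaves = random_tree(rng, n)
            d = additive_matrix(graph, leaves)
            tree = nj_tree(DistanceMatrix(list(leaves), d))
            got = phylo.tree_distance_matrix(tree)
            assert got.labels == sorted(leaves)
            order = [got.labels.index(l) for l in leaves]
            assert np.allclose(got.d[np.ix_(order, order)], d, atol=1e-9)

    def test_agrees_with_skbio_on_additive_matrix(self):
        skbio_tree = pytest.importorskip("skbio.tree")
        from skbio import DistanceMatrix as SkbioDM

        rng = np.random.default_rng(5)
        newick, graph, leaves = random_tree(rng, 6)
        d = additive_matrix(graph, leaves)
        ours = phylo.tree_distance_matrix(nj_tree(DistanceMatrix(list(leaves), d)))
        theirs = skbio_tree.nj(SkbioDM(d, ids=leaves))
        for i, a in enumerate(leaves):
            for b in leaves[i + 1 :]:
                assert ours.value(a, b) == pytest.approx(
                    theirs.find(a).distance(theirs.find(b)), abs=1e-6
                )

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))


class TestPathMetrics:
    def test_worked_examples(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        for a, b, count, total in [
            ("A", "B", 1, 2.0),
            ("A", "E", 2, 3.0),
            ("A", "C", 3, 4.0),
        ]:
            pm = tree.path_metrics(a, b)
            assert (pm.internal_node_count, pm.branch_length_sum) == (count, pytest.approx(total))

    def test_star_tree(self):
        tree = read_newick("(Q:1,B:1,C:0.5);")
        assert tree.path_metrics("Q", "B").branch_length_sum == pytest.approx(2.0)
        assert tree.path_metrics("Q", "C").branch_length_sum == pytest.approx(1.5)
        assert tree.path_metrics("Q", "C").internal_node_count == 1

    def test_rooted_and_unrooted_forms_agree(self):
        rooted = read_newick("((A:1,B:1):0.5,((C:1,D:1):1,E:1):0.5);")
        unrooted = read_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        for a, b in [("A", "B"), ("A", "C"), ("B", "E")]:
            pm_r = rooted.path_metrics(a, b)
            pm_u = unrooted.path_metrics(a, b)
            assert pm_r.internal_node_count == pm_u.internal_node_count
            assert pm_r.branch_length_sum == pytest.approx(pm_u.branch_length_sum)

    def test_symmetry_and_unknown_leaf(self):
        tree = read_newick("((A:1,B:2):1,C:1,D:4);")
        assert tree.path_metrics("A", "D") == tree.path_metrics("A", "D")
        pm1, pm2 = tree.path_metrics("A", "D"), tree.path_metrics("D", "A")
        assert pm1.internal_node_count == pm2.internal_node_count
        assert pm1.branch_length_sum == pytest.approx(pm2.branch_length_sum)
        with pytest.raises(KeyError):
            tree.path_metrics("A", "Z")

    def test_500_random_trees_match_graph_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(500):
            n = int(rng.integers(4, 41))
            newick, graph, leaves = random_tree(rng, n)
            tree = read_newick(newick)
            i, j = rng.choice(n, size=2, replace=False)
            a, b = leaves[int(i)], leaves[int(j)]
            count, total = graph_path_metrics(graph, a, b)
            pm = tree.path_metrics(a, b)
            assert pm.internal_node_count == count
            assert pm.branch_length_sum == pytest.approx(total, abs=1e-6)


class TestBootstrap:
    @staticmethod
    def _alignment(rng, n_cols=120):
        # A/B nearly identical, C/D nearly identical, AB far from CD
        base = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n_cols)
        other = np.roll(base, 1)
        seqs = {}
        for label, src, flips in [("A", base, 4), ("B", base, 4), ("C", other, 4), ("D", other, 4)]:
            s = src.copy()
            pos = rng.choice(n_cols, size=flips, replace=False)
            for p in pos:
                s[p] = "W" if s[p] != "W" else "Y"
            seqs[label] = "".join(s)
        return AlignmentSet(seqs)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        aln = self._alignment(rng)
        t1 = bootstrap_nj(aln, replicates=10, seed=99)
        t2 = bootstrap_nj(aln, replicates=10, seed=99)
        from endohgt.tree import write_newick

        assert [write_newick(t) for t in t1] == [write_newick(t) for t in t2]

    def test_constant_columns_give_constant_topology(self):
        aln = AlignmentSet({"A": "K" * 50, "B": "R" * 50, "C": "N" * 50, "D": "D" * 50})
        trees = bootstrap_nj(aln, replicates=20, seed=0)
        splits = {frozenset(map(frozenset, t.bipartitions())) for t in trees}
        assert len(splits) == 1

    def test_strong_signal_support(self):
        rng = np.random.default_rng(8)
        aln = self._alignment(rng)
        trees = bootstrap_nj(aln, replicates=200, seed=4)
        target = frozenset({"C", "D"})
        freq = 100.0 * sum(target in t.bipartitions() for t in trees) / len(trees)
        assert freq >= 95.0

    def test_support_invariant_to_leaf_order(self):
        rng = np.random.default_rng(8)
        aln = self._alignment(rng)
        reordered = AlignmentSet({k: aln.sequences[k] for k in ["D", "B", "C", "A"]})
        t1 = bootstrap_nj(aln, replicates=100, seed=5)
        t2 = bootstrap_nj(reordered, replicates=100, seed=5)
        target = frozenset({"C", "D"})
        f1 = sum(target in t.bipartitions() for t in t1)
        f2 = sum(target in t.bipartitions() for t in t2)
        assert 0 <= f1 <= 100 and 0 <= f2 <= 100
        assert abs(f1 - f2) <= 10  # same signal, independent resampling noise

    def test_invalid_replicates(self):
        aln = AlignmentSet({"A": "KK", "B": "RR", "C": "NN"})
        with pytest.raises(ValueError):
            bootstrap_nj(aln, replicates=0)
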