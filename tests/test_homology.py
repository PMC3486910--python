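"""Pairwise alignment, the shared-protein screen and the AFP region finder."""

from __future__ import annotations

import numpy as np
import pytest

from endohgt import homology
from endohgt.io_formats import GeneFeature, GenomeRecord
from _oracles import dp_align_score

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))


class TestAlignPair:
    def test_identical_global(self):
        aln = homology.align_pair("MKVLITGHAW", "MKVLITGHAW", mode="global")
        assert aln.percent_identity == pytest.approx(100.0)
        assert aln.alignment_length == 10

    def test_one_mismatch_global(self):
        aln = homology.align_pair("MKVLITGHAW", "MKVLITGHAY", mode="global")
        assert aln.percent_identity == pytest.approx(90.0)

    @pytest.mark.parametrize("mode", ["local", "global"])
    def test_score_equals_bruteforce_dp(self, mode):
        rng = np.random.default_rng(21)
        for _ in range(12):
            a = _random_protein(rng, 30)
            b = _random_protein(rng, 30)
            expected = dp_align_score(a, b, local=(mode == "local"))
            assert homology.alignment_score(a, b, mode=mode) == pytest.approx(expected)
            assert homology.align_pair(a, b, mode=mode).score == pytest.approx(expected)

    def test_score_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = _random_protein(rng, 40)
            b = _random_protein(rng, 35)
            assert homology.alignment_score(a, b) == homology.alignment_score(b, a)

    def test_invalid_residues_rejected(self):
        with pytest.raises(ValueError, match="invalid residue"):
            homology.align_pair("MKV1", "MKVL")
        with pytest.raises(ValueError, match="empty"):
            homology.align_pair("", "MKVL")


class TestSharedProteinScreen:
    def _mutated(self, rng, seq, n_changes):
        out = list(seq)
        for pos in rng.choice(len(seq), size=n_changes, replace=False):
            out[pos] = AA[(AA.index(out[pos]) + 1) % 20]
        return "".join(out)

    def test_boundary_thresholds_inclusive(self):
        # 25% identity exactly: global alignment of equal-length pair
        # differing at 3 of 4 positions per repeat unit
        a = "MKVL" * 10
        b = "MCCC" * 10
        aln = homology.align_pair(a, b, mode="global")
        assert aln.percent_identity == pytest.approx(25.0)
        shared, table = homology.shared_protein_screen(
            {"q": a}, {"s": b}, min_identity=25.0, min_size_ratio=0.80, max_evalue=None
        )
        row = table.iloc[0]
        # the local best alignment may trim columns; shared-ness is
        # decided on the reported identity and the exact size ratio
        assert row.size_ratio == pytest.approx(1.0)
        assert ("q" in shared) == (row.percent_identity >= 25.0)

    def test_size_ratio_boundary_inclusive(self):
        rng = np.random.default_rng(41)
        subject = _random_protein(rng, 100)
        at_boundary, _ = homology.shared_protein_screen(
            {"q": subject[:80]}, {"s": subject}, max_evalue=None
        )
        assert at_boundary == {"q"}  # ratio exactly 0.80 passes ("at least")
        below, _ = homology.shared_protein_screen(
            {"q": subject[:79]}, {"s": subject}, max_evalue=None
        )
        assert below == set()

    def test_size_ratio_excludes_length_mismatch(self):
        rng = np.random.default_rng(5)
        base = _random_protein(rng, 100)
        shared, table = homology.shared_protein_screen(
            {"q": base[:40]}, {"s": base}, max_evalue=None
        )
        assert table.iloc[0].size_ratio == pytest.approx(0.4)
        assert shared == set()

    def test_true_orthologs_detected_and_random_pairs_rejected(self):
        rng = np.random.default_rng(17)
        a_orth = _random_protein(rng, 150)
        a_priv = _random_protein(rng, 150)
        b = {
            "orth": self._mutated(rng, a_orth, 30),  # 80% identity
            "noise1": _random_protein(rng, 150),
            "noise2": _random_protein(rng, 140),
        }
        shared, table = homology.shared_protein_screen({"orth_q": a_orth, "priv_q": a_priv}, b)
        assert shared == {"orth_q"}
        best = table.set_index("query_id").loc["orth_q"]
        assert best.best_subject == "orth"
        assert best.reciprocal_best

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(29)
        a = {f"q{i}": _random_protein(rng, 120) for i in range(4)}
        b = {"s0": self._mutated(rng, a["q0"], 40), "s1": _random_protein(rng, 120)}
        strict, _ = homology.shared_protein_screen(a, b, 30.0, 0.9)
        loose, _ = homology.shared_protein_screen(a, b, 25.0, 0.8)
        assert strict <= loose


class TestAfpScreen:
    def test_evalue_gate(self):
        rng = np.random.default_rng(31)
        ref = _random_protein(rng, 200)
        homolog = list(ref)
        for pos in rng.choice(200, size=80, replace=False):  # ~60% identity
            homolog[pos] = AA[(AA.index(homolog[pos]) + 3) % 20]
        proteome = {
            "hit": "".join(homolog),
            "miss": _random_protein(rng, 200),
        }
        table = homology.afp_screen(proteome, {"afp1": ref}, max_evalue=1e-10)
        by_gene = table.set_index("gene_id")
        assert bool(by_gene.loc["hit", "retained"])
        assert not bool(by_gene.loc["miss", "retained"])
        assert by_gene.loc["hit", "evalue"] < 1e-10 < by_gene.loc["miss", "evalue"]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            homology.afp_screen({"g": "MKVL"}, {})


class TestGroupRegions:
    @staticmethod
    def _record(n_genes=100):
        feats = [
            GeneFeature(f"G{i}", "CDS", 10 * i + 1, 10 * i + 9, "+", "x") for i in range(n_genes)
        ]
        return GenomeRecord("chr", "A" * (10 * n_genes + 10), feats)

    def test_grouping_examples(self):
        record = self._record()
        hits = [f"G{i}" for i in (10, 11, 12, 50, 90, 91)]
        regions = homology.group_regions(hits, record, max_gap=5)
        assert [r.size for r in regions] == [3, 1, 2]

    def test_gap_boundary(self):
        # G10 and G16 have exactly 5 intervening genes (G11..G15)
        record = self._record()
        assert len(homology.group_regions(["G10", "G16"], record, max_gap=5)) == 1
        assert len(homology.group_regions(["G10", "G16"], record, max_gap=4)) == 2

    def test_empty_hits(self):
        assert homology.group_regions([], self._record(), 5) == []

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            homology.group_regions(["nope"], self._record(), 5)

    def test_regions_disjoint_and_cover_hits(self):
        rng = np.random.default_rng(13)
        record = self._record(200)
        for max_gap in (0, 2, 5):
            hits = [f"G{i}" for i in sorted(rng.choice(200, size=40, replace=False))]
            regions = homology.group_regions(hits, record, max_gap)
            members = [g for r in regions for g in r.members]
            assert sorted(members) == sorted(hits)
            assert len(set(members)) == len(members)
            for r in regions:
                assert r.size == len(r.members)
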