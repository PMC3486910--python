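"""Pairwise protein homology and the two screens built on it.

The screens mirror how reduced symbiont proteomes are compared in
practice: a *shared-protein* screen that calls a query shared with the
sister proteome when its best local alignment reaches a minimum percent
identity and the two proteins are of similar size, and an *AFP screen*
that finds genes homologous to a reference set of antifeeding-prophage
(phage-tail secretion system) proteins at an E-value cutoff, then
groups the hits into genome regions by gene order.

Alignments are exact affine-gap dynamic programming (BLOSUM62, gap
open 11 / extend 1 — the classic blastp scoring), computed with
Biopython's ``PairwiseAligner``.  E-values follow the Karlin-Altschul
form ``E = K * m * n * exp(-lambda * S)`` with the gapped BLOSUM62-11-1
parameters, so the cutoff is reproducible without a BLAST installation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import exp
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import GenomeRecord

__all__ = [
    "PairAlignment",
    "HomologyRegion",
    "align_pair",
    "alignment_score",
    "karlin_altschul_evalue",
    "shared_protein_screen",
    "afp_screen",
    "group_regions",
]

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 /
# extend 1 (the values BLAST reports for this scoring scheme).
KA_LAMBDA = 0.267
KA_K = 0.041

#: Residues accepted by the BLOSUM62 scoring alphabet (no stop '*').
VALID_RESIDUES = frozenset("ARNDCQEGHILKMFPSTWYVBZX")


@dataclass(frozen=True)
class PairAlignment:
    """Result of one pairwise protein alignment.

    ``percent_identity`` is identities over alignment *columns* (gap
    columns included in the denominator).
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    score: float
    evalue: float | None = None


@dataclass(frozen=True)
class HomologyRegion:
    """A run of retained genes on one replicon, ordered by gene rank."""

    region_id: str
    replicon_id: str
    members: tuple[str, ...]
    first_index: int
    last_index: int

    @property
    def size(self) -> int:
        return len(self.members)


def _validate_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty protein sequence")
    bad = set(seq.upper()) - VALID_RESIDUES
    if bad:
        raise ValueError(f"{name}: invalid residue characters {sorted(bad)}")


@lru_cache(maxsize=4)
def _aligner(mode: str, matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.mode = mode
    # BLAST convention: a gap of length k costs open + k*extend, so the
    # first gapped residue scores -(open + extend).
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def alignment_score(
    a: str,
    b: str,
    mode: str = "local",
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> float:
    """Optimal alignment score only (much faster than a full traceback)."""
    _validate_protein(a, "query")
    _validate_protein(b, "subject")
    return float(_aligner(mode, matrix, gap_open, gap_extend).score(a.upper(), b.upper()))


def align_pair(
    a: str,
    b: str,
    mode: str = "local",
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "query",
    subject_id: str = "subject",
    db_size: int | None = None,
) -> PairAlignment:
    """Optimal pairwise alignment under affine-gap scoring.

    ``mode`` is ``"local"`` (Smith-Waterman) or ``"global"``
    (Needleman-Wunsch).  When ``db_size`` (total residues searched) is
    given, a Karlin-Altschul E-value is attached.
    """
    if mode not in ("local", "global"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    _validate_protein(a, query_id)
    _validate_protein(b, subject_id)
    aligner = _aligner(mode, matrix, gap_open, gap_extend)
    alignment = aligner.align(a.upper(), b.upper())[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    columns = len(row_a)
    identities = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    evalue = karlin_altschul_evalue(alignment.score, len(a), db_size) if db_size else None
    return PairAlignment(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=100.0 * identities / columns if columns else 0.0,
        alignment_length=columns,
        score=float(alignment.score),
        evalue=evalue,
    )


def karlin_altschul_evalue(score: float, query_length: int, db_size: int) -> float:
    """``E = K * m * n * exp(-lambda * S)`` for the BLOSUM62-11-1 preset."""
    if query_length < 1 or db_size < 1:
        raise ValueError("query_length and db_size must be positive")
    return KA_K * query_length * db_size * exp(-KA_LAMBDA * score)


# ----------------------------------------------------------------------
# shared-protein screen
# ----------------------------------------------------------------------
def shared_protein_screen(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    min_identity: float = 25.0,
    min_size_ratio: float = 0.80,
    max_evalue: float | None = 1e-5,
) -> tuple[set[str], pd.DataFrame]:
    """Which proteins of proteome A are shared with proteome B?

    A query is *shared* when its best-scoring subject alignment has
    percent identity >= ``min_identity`` and the two protein lengths
    are within ``min_size_ratio`` (shorter/longer); both thresholds are
    inclusive.  The best hit must additionally be statistically
    significant (E-value <= ``max_evalue`` against the size of
    proteome B), mirroring how a database search only surfaces
    significant alignments in the first place; short spurious local
    alignments between unrelated proteins routinely exceed 25%
    identity, and the significance gate is what keeps them out.  Pass
    ``max_evalue=None`` to disable the gate.  The report also flags
    reciprocal best hits so either one-way or reciprocal readings can
    be tallied.

    Returns the set of shared query ids and a per-query report table.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")

    db_size = sum(len(s) for s in proteome_b.values())
    b_ids = list(proteome_b)
    best_for_a: dict[str, tuple[str, float]] = {}
    best_for_b: dict[str, tuple[str, float]] = {}
    for qid, qseq in proteome_a.items():
        best_sid, best_score = None, float("-inf")
        for sid in b_ids:
            score = alignment_score(qseq, proteome_b[sid])
            if score > best_score or (score == best_score and (best_sid is None or sid < best_sid)):
                best_sid, best_score = sid, score
            prev = best_for_b.get(sid)
            if prev is None or score > prev[1] or (score == prev[1] and qid < prev[0]):
                best_for_b[sid] = (qid, score)
        best_for_a[qid] = (best_sid, best_score)

    rows = []
    shared: set[str] = set()
    for qid, (sid, score) in best_for_a.items():
        aln = align_pair(proteome_a[qid], proteome_b[sid], query_id=qid, subject_id=sid)
        la, lb = len(proteome_a[qid]), len(proteome_b[sid])
        size_ratio = min(la, lb) / max(la, lb)
        evalue = karlin_altschul_evalue(score, la, db_size)
        is_shared = (
            aln.percent_identity >= min_identity
            and size_ratio >= min_size_ratio
            and (max_evalue is None or evalue <= max_evalue)
        )
        if is_shared:
            shared.add(qid)
        rows.append(
            {
                "query_id": qid,
                "best_subject": sid,
                "score": score,
                "percent_identity": aln.percent_identity,
                "size_ratio": size_ratio,
                "evalue": evalue,
                "shared": is_shared,
                "reciprocal_best": best_for_b[sid][0] == qid,
            }
        )
    return shared, pd.DataFrame(rows)


# ----------------------------------------------------------------------
# AFP-like gene screen
# ----------------------------------------------------------------------
def afp_screen(
    proteome: Mapping[str, str],
    reference_afp_set: Mapping[str, str],
    max_evalue: float = 1e-10,
    db_size: int | None = None,
) -> pd.DataFrame:
    """Find genes homologous to a reference prophage-protein set.

    Each gene is aligned (local, BLOSUM62-11-1) against every reference
    protein; the gene is retained when the E-value of its best hit is
    <= ``max_evalue``.  ``db_size`` defaults to the residue count of
    the searched proteome, which fixes the E-value scale.
    """
    if not reference_afp_set:
        raise ValueError("reference AFP set is empty")
    if db_size is None:
        db_size = sum(len(s) for s in proteome.values())
    rows = []
    for gid, gseq in proteome.items():
        best: PairAlignment | None = None
        for rid, rseq in reference_afp_set.items():
            aln = align_pair(gseq, rseq, query_id=gid, subject_id=rid, db_size=db_size)
            if best is None or aln.score > best.score:
                best = aln
        rows.append(
            {
                "gene_id": gid,
                "best_reference": best.subject_id,
                "score": best.score,
                "percent_identity": best.percent_identity,
                "evalue": best.evalue,
                "retained": best.evalue <= max_evalue,
            }
        )
    return pd.DataFrame(rows)


def group_regions(
    hit_gene_ids: Sequence[str],
    record: GenomeRecord,
    max_gap: int = 5,
) -> list[HomologyRegion]:
    """Group retained genes into genome regions by gene order.

    Two consecutive retained genes belong to the same region when at
    most ``max_gap`` non-retained genes lie between them.
    """
    indexed = []
    for gid in hit_gene_ids:
        feat = record.feature_by_tag(gid)  # raises KeyError if absent
        indexed.append((feat.order_index, gid))
    indexed.sort()
    regions: list[HomologyRegion] = []
    current: list[tuple[int, str]] = []
    for idx, gid in indexed:
        if current and idx - current[-1][0] - 1 > max_gap:
            regions.append(_make_region(current, record.replicon_id, len(regions)))
            current = []
        current.append((idx, gid))
    if current:
        regions.append(_make_region(current, record.replicon_id, len(regions)))
    return regions


def _make_region(members: list[tuple[int, str]], replicon_id: str, n: int) -> HomologyRegion:
    return HomologyRegion(
        region_id=f"{replicon_id}_region_{n + 1}",
        replicon_id=replicon_id,
        members=tuple(gid for _, gid in members),
        first_index=members[0][0],
        last_index=members[-1][0],
    )
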