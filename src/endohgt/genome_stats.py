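"""Per-replicon genome statistics for reduced symbiont genomes.

GC content, sliding-window GC skew, CDS counts and coding density, RNA
gene counts, and a product-text census of transposable-element genes.
Ambiguous bases (``N``, e.g. an unclosed assembly gap) are excluded
from GC numerators and denominators so they cannot bias composition
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenomeRecord

__all__ = [
    "GcSkewProfile",
    "GenomeSummary",
    "gc_content",
    "at_content",
    "gc_skew",
    "coding_stats",
    "count_keyword_features",
    "summarize",
    "DEFAULT_TRANSPOSASE_KEYWORDS",
]

#: Product-text substrings identifying transposable-element genes.
DEFAULT_TRANSPOSASE_KEYWORDS = ("transposase", "insertion sequence", "is element")


@dataclass(frozen=True)
class GcSkewProfile:
    """Windowed (G-C)/(G+C) along a replicon.

    ``values`` holds one ``(window_start, skew)`` pair per window
    (1-based start).  A final partial window, if any, is included and
    flagged via ``has_partial_window``.
    """

    window_size: int
    step: int
    values: tuple[tuple[int, float], ...]
    has_partial_window: bool = False


@dataclass
class GenomeSummary:
    """The headline per-replicon statistics."""

    replicon_id: str
    size_bp: int
    gc_percent: float
    cds_count: int
    avg_cds_length_bp: int
    coding_density_percent: float
    trna_count: int
    rrna_set_count: int
    transposase_count: int = 0
    transposase_fraction_percent: float = 0.0
    transposase_locus_tags: tuple[str, ...] = field(default=(), repr=False)


def _counts(sequence: str) -> tuple[int, int, int, int]:
    s = sequence.upper()
    return s.count("A"), s.count("C"), s.count("G"), s.count("T")


def gc_content(sequence: str) -> float:
    """GC percentage over unambiguous bases, e.g. ``"ATGC" -> 50.0``."""
    if not sequence:
        raise ValueError("empty sequence")
    a, c, g, t = _counts(sequence)
    total = a + c + g + t
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * (g + c) / total


def at_content(sequence: str) -> float:
    """AT percentage over unambiguous bases (complement of :func:`gc_content`)."""
    if not sequence:
        raise ValueError("empty sequence")
    a, c, g, t = _counts(sequence)
    total = a + c + g + t
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * (a + t) / total


def gc_skew(sequence: str, window_size: int = 887, step: int | None = None) -> GcSkewProfile:
    """Sliding-window GC skew (G-C)/(G+C).

    The default window is 887 bp; the default step equals the window
    size (non-overlapping windows).  Windows with G+C == 0 report a
    skew of 0.  A trailing partial window is included.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if window_size > len(sequence):
        raise ValueError(f"window_size {window_size} exceeds sequence length {len(sequence)}")
    if step is None:
        step = window_size
    if step <= 0:
        raise ValueError("step must be positive")

    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_g = np.concatenate([[0], np.cumsum(arr == ord("G"))])
    is_c = np.concatenate([[0], np.cumsum(arr == ord("C"))])

    values: list[tuple[int, float]] = []
    has_partial = False
    start = 0
    while start < len(sequence):
        end = min(start + window_size, len(sequence))
        if end - start < window_size:
            has_partial = True
        g = int(is_g[end] - is_g[start])
        c = int(is_c[end] - is_c[start])
        skew = 0.0 if g + c == 0 else (g - c) / (g + c)
        values.append((start + 1, skew))
        if end == len(sequence):
            break
        start += step
    return GcSkewProfile(
        window_size=window_size, step=step, values=tuple(values), has_partial_window=has_partial
    )


def coding_stats(record: GenomeRecord) -> GenomeSummary:
    """CDS count, mean CDS length, coding density and RNA gene counts.

    Coding density is the fraction of the replicon covered by the
    *union* of CDS intervals, so overlapping genes are counted once.
    The rRNA statistic counts gene *sets*, one per 16S gene, matching
    how unlinked rRNA operons are reported for symbiont genomes.
    """
    cdss = record.cds_features()
    cds_count = len(cdss)
    avg_len = round(sum(f.length for f in cdss) / cds_count) if cds_count else 0

    covered = 0
    if cdss:
        intervals = sorted((f.start, f.end) for f in cdss)
        cur_start, cur_end = intervals[0]
        for start, end in intervals[1:]:
            if start > cur_end + 1:
                covered += cur_end - cur_start + 1
                cur_start, cur_end = start, end
            else:
                cur_end = max(cur_end, end)
        covered += cur_end - cur_start + 1

    rrnas = [f for f in record.features if f.kind == "rRNA"]
    rrna_sets = sum(1 for f in rrnas if "16s" in f.product.lower())
    if rrnas and rrna_sets == 0:
        # annotation without explicit 16S products: fall back to one set
        # per three rRNA genes (16S/23S/5S), rounded up
        rrna_sets = -(-len(rrnas) // 3)

    return GenomeSummary(
        replicon_id=record.replicon_id,
        size_bp=record.length,
        gc_percent=gc_content(record.sequence),
        cds_count=cds_count,
        avg_cds_length_bp=avg_len,
        coding_density_percent=100.0 * covered / record.length,
        trna_count=sum(1 for f in record.features if f.kind == "tRNA"),
        rrna_set_count=rrna_sets,
    )


def count_keyword_features(
    record: GenomeRecord,
    keywords: tuple[str, ...] = DEFAULT_TRANSPOSASE_KEYWORDS,
) -> tuple[int, list[str]]:
    """Count CDSs whose product text contains any keyword (lowercased).

    Returns the count and the matched locus tags; a product matching
    several keywords is counted once.
    """
    if not keywords:
        raise ValueError("keywords must be a non-empty list of lowercase substrings")
    matched = [
        f.locus_tag
        for f in record.cds_features()
        if any(kw in f.product.lower() for kw in keywords)
    ]
    return len(matched), matched


def summarize(record: GenomeRecord, keywords=DEFAULT_TRANSPOSASE_KEYWORDS) -> GenomeSummary:
    """Full :class:`GenomeSummary` including the transposase census."""
    summary = coding_stats(record)
    count, tags = count_keyword_features(record, keywords)
    summary.transposase_count = count
    summary.transposase_locus_tags = tuple(tags)
    summary.transposase_fraction_percent = (
        100.0 * count / summary.cds_count if summary.cds_count else 0.0
    )
    return summary
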