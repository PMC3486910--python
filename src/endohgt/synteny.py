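"""Synton detection: collinear runs of ortholog pairs between two genomes.

A synton is a maximal chain of ortholog pairs whose gene-order indices
advance together on both genomes — in the same direction (conserved)
or in opposite directions (inverted) — with at most ``max_gap``
intervening genes allowed on each axis between consecutive members.
Chains are assigned greedily, longest first, so each ortholog pair
belongs to at most one synton; chains shorter than ``min_genes`` are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["OrthologPair", "Synton", "detect_syntons"]


@dataclass(frozen=True)
class OrthologPair:
    """A best-hit ortholog pair with gene-order ranks in both genomes."""

    a_locus: str
    b_locus: str
    a_index: int
    b_index: int

    def __post_init__(self) -> None:
        if self.a_index < 0 or self.b_index < 0:
            raise ValueError(f"{self.a_locus}/{self.b_locus}: negative order index")


@dataclass(frozen=True)
class Synton:
    """A detected collinear block (members ordered by a_index)."""

    pairs: tuple[OrthologPair, ...]
    orientation: str  # "conserved" | "inverted"

    @property
    def size(self) -> int:
        return len(self.pairs)

    @property
    def a_loci(self) -> tuple[str, ...]:
        return tuple(p.a_locus for p in self.pairs)


def _step_ok(p: OrthologPair, q: OrthologPair, direction: int, max_gap: int) -> bool:
    da = q.a_index - p.a_index
    db = q.b_index - p.b_index
    return 0 < da <= max_gap + 1 and direction * db > 0 and abs(db) <= max_gap + 1


def _longest_chain(
    pairs: Sequence[OrthologPair], max_gap: int
) -> tuple[list[OrthologPair], str] | None:
    """Longest collinear chain over ``pairs`` (already sorted by a_index).

    Ties are broken by smallest starting a_index, then by preferring the
    conserved direction, then by smallest a_index at each extension.
    """
    if not pairs:
        return None
    best: tuple[int, int, int, list[OrthologPair], str] | None = None
    for direction, name in ((1, "conserved"), (-1, "inverted")):
        n = len(pairs)
        # length of the longest chain starting at i, walking successors
        length = [1] * n
        for i in range(n - 1, -1, -1):
            for j in range(i + 1, n):
                if pairs[j].a_index - pairs[i].a_index > max_gap + 1:
                    break
                if _step_ok(pairs[i], pairs[j], direction, max_gap):
                    length[i] = max(length[i], 1 + length[j])
        i_best = max(range(n), key=lambda i: (length[i], -pairs[i].a_index))
        chain = [pairs[i_best]]
        i = i_best
        while length[i] > 1:
            nxt = None
            for j in range(i + 1, n):
                if pairs[j].a_index - pairs[i].a_index > max_gap + 1:
                    break
                if _step_ok(pairs[i], pairs[j], direction, max_gap) and length[j] == length[i] - 1:
                    nxt = j
                    break
            i = nxt
            chain.append(pairs[i])
        dir_pref = 0 if name == "conserved" else 1
        key = (-len(chain), chain[0].a_index, dir_pref)
        if best is None or key < (-len(best[3]), best[1], best[2]):
            best = (len(chain), chain[0].a_index, dir_pref, chain, name)
    chain, name = best[3], best[4]
    if len(chain) == 1:
        name = "conserved"  # a single pair carries no direction signal
    return chain, name


def detect_syntons(
    pairs: Iterable[OrthologPair],
    min_genes: int = 3,
    max_gap: int = 3,
) -> list[Synton]:
    """Detect syntons among a set of ortholog pairs.

    Parameters
    ----------
    pairs:
        Ortholog pairs; ``a_locus`` must be unique (best-hit mapping).
    min_genes:
        Minimum chain size retained (inclusive; default 3).
    max_gap:
        Maximum number of intervening genes tolerated on each genome
        axis between consecutive chain members.
    """
    pool = sorted(pairs, key=lambda p: p.a_index)
    seen_loci = [p.a_locus for p in pool]
    if len(set(seen_loci)) != len(seen_loci):
        dupes = sorted({x for x in seen_loci if seen_loci.count(x) > 1})
        raise ValueError(f"duplicate a_locus in ortholog pairs: {dupes}")
    seen_idx = [p.a_index for p in pool]
    if len(set(seen_idx)) != len(seen_idx):
        raise ValueError("duplicate a_index in ortholog pairs")

    syntons: list[Synton] = []
    while pool:
        found = _longest_chain(pool, max_gap)
        if found is None:
            break
        chain, orientation = found
        if len(chain) < min_genes:
            break
        syntons.append(Synton(pairs=tuple(chain), orientation=orientation))
        used = set(id(p) for p in chain)
        pool = [p for p in pool if id(p) not in used]
    syntons.sort(key=lambda s: s.pairs[0].a_index)
    return syntons
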