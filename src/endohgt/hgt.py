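"""Horizontal-gene-transfer inference for an endosymbiont proteome.

The chain has four steps:

1. **Candidate screen** — a gene is an HGT candidate when its *k* best
   non-self homology hits (default k=10) all come from organisms
   outside the focal organism's own phylum (default Bacteroidetes).
   Genes encoding transposases, repeat proteins or Na+/proline
   symporters, and genes shared with the sequenced sister genome, are
   excluded up front.
2. **Nearest-neighbor donor inference** — on a phylogenetic tree of the
   candidate with its top database hits, the putative transfer partner
   is the leaf separated from the query by the fewest internal nodes;
   ties are broken by the minimum branch-length sum, then by taxon
   name.
3. **Support and consistency** — bootstrap replicates vote on the
   nearest-neighbor's host-association *category*; a call is retained
   only when support exceeds a threshold (strictly greater than 75%
   by default) and the neighbor-joining and maximum-likelihood trees
   agree on the category.
4. **Category summary** — retained calls are tallied by donor category
   (AM / AA / ART / E / X) to profile the ecological history of the
   lineage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import CATEGORIES, HitRecord, TaxonRecord
from .tree import Tree

__all__ = [
    "HgtCandidate",
    "DonorCall",
    "CategorySummary",
    "screen_hgt_candidates",
    "infer_nearest_neighbor",
    "assess_support",
    "consistency_filter",
    "finalize_call",
    "summarize_categories",
    "DEFAULT_EXCLUSION_KEYWORDS",
]

#: Product-text keywords driving the candidate-screen exclusions.
DEFAULT_EXCLUSION_KEYWORDS: dict[str, tuple[str, ...]] = {
    "transposase": ("transposase", "insertion sequence", "is element"),
    "repeat_protein": ("repeat protein", "ankyrin repeat", "tetratricopeptide repeat"),
    "symporter_family": ("na+/proline symporter", "sodium/proline symporter"),
}

EXCLUSION_REASONS = (
    "transposase",
    "repeat_protein",
    "symporter_family",
    "shared_with_sister_genome",
    "too_few_hits",
)


@dataclass(frozen=True)
class HgtCandidate:
    """Screen verdict for one gene."""

    gene_id: str
    candidate: bool
    n_hits_examined: int
    outside_phylum_in_top_k: int
    excluded_reason: str | None = None


@dataclass(frozen=True)
class DonorCall:
    """Per-candidate nearest-neighbor inference result."""

    gene_id: str
    tree_source: str  # "NJ" | "ML"
    neighbor_taxon: str
    neighbor_category: str
    internal_node_count: int
    branch_length_sum: float
    support_percent: float = float("nan")
    consistent_between_methods: bool = False
    retained: bool = False


@dataclass(frozen=True)
class CategorySummary:
    """Counts and percentages of donor calls per host-association category."""

    counts: dict[str, int]
    fractions_percent: dict[str, float]
    n_total: int


# ----------------------------------------------------------------------
# candidate screen
# ----------------------------------------------------------------------
def screen_hgt_candidates(
    hit_tables: Mapping[str, Sequence[HitRecord]],
    taxonomy: Mapping[str, TaxonRecord],
    self_phylum: str = "Bacteroidetes",
    self_taxon: str | None = None,
    k: int = 10,
    products: Mapping[str, str] | None = None,
    shared_with_sister: Iterable[str] | None = None,
    exclusion_keywords: Mapping[str, tuple[str, ...]] = DEFAULT_EXCLUSION_KEYWORDS,
    unknown_taxon: str = "error",
    lenient: bool = False,
) -> list[HgtCandidate]:
    """Screen ranked hit tables for HGT candidate genes.

    A gene is a candidate when all of its ``k`` best non-self hits have
    a phylum different from ``self_phylum``.  Hits whose subject taxon
    equals ``self_taxon`` are dropped before ranking.  Genes matching
    an exclusion keyword in their product text, or present in
    ``shared_with_sister``, are excluded with the corresponding reason.
    Genes with fewer than ``k`` usable hits are excluded with reason
    ``too_few_hits`` unless ``lenient`` is set, in which case all
    available hits must lie outside the phylum.

    ``unknown_taxon`` controls what happens when a subject taxon has no
    taxonomy entry: ``"error"`` (default) or ``"outside"`` (treat as
    outside-phylum, with a warning).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    shared = set(shared_with_sister or ())
    products = products or {}
    results: list[HgtCandidate] = []
    for gene_id, hits in hit_tables.items():
        non_self = [h for h in hits if self_taxon is None or h.subject_taxon != self_taxon]
        top = sorted(non_self, key=lambda h: h.rank)[:k]
        outside = 0
        for h in top:
            rec = taxonomy.get(h.subject_taxon)
            if rec is None:
                if unknown_taxon == "error":
                    raise KeyError(
                        f"{gene_id}: subject taxon {h.subject_taxon!r} missing from taxonomy"
                    )
                warnings.warn(
                    f"{gene_id}: unknown taxon {h.subject_taxon!r} treated as outside-phylum"
                )
                outside += 1
            elif rec.phylum != self_phylum:
                outside += 1

        reason = None
        product = products.get(gene_id, "").lower()
        for rsn, keywords in exclusion_keywords.items():
            if any(kw in product for kw in keywords):
                reason = rsn
                break
        if reason is None and gene_id in shared:
            reason = "shared_with_sister_genome"
        if reason is None and len(top) < k and not lenient:
            reason = "too_few_hits"

        candidate = (
            reason is None
            and len(top) > 0
            and outside == len(top)
            and (lenient or len(top) == k)
        )
        results.append(
            HgtCandidate(
                gene_id=gene_id,
                candidate=candidate,
                n_hits_examined=len(top),
                outside_phylum_in_top_k=outside,
                excluded_reason=reason,
            )
        )
    return results


# ----------------------------------------------------------------------
# nearest-neighbor donor inference
# ----------------------------------------------------------------------
def infer_nearest_neighbor(
    tree: Tree,
    query_leaf: str,
    taxonomy: Mapping[str, TaxonRecord],
    tree_source: str = "NJ",
) -> DonorCall:
    """Nearest neighbor of the query leaf by internal-node count.

    Only leaves with a taxonomy entry compete.  Ties on the node count
    are broken by the minimum branch-length sum along the path, then by
    lexicographic taxon name.
    """
    if query_leaf not in tree.leaf_labels:
        raise KeyError(f"query leaf {query_leaf!r} not in tree")
    best: tuple[int, float, str] | None = None
    for label in tree.leaf_labels:
        if label == query_leaf or label not in taxonomy:
            continue
        pm = tree.path_metrics(query_leaf, label)
        key = (pm.internal_node_count, pm.branch_length_sum, label)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError(f"{query_leaf}: no non-query leaf with a taxonomy entry")
    count, length_sum, taxon = best
    return DonorCall(
        gene_id=query_leaf,
        tree_source=tree_source,
        neighbor_taxon=taxon,
        neighbor_category=taxonomy[taxon].category,
        internal_node_count=count,
        branch_length_sum=length_sum,
    )


def assess_support(
    replicate_trees: Sequence[Tree],
    query_leaf: str,
    taxonomy: Mapping[str, TaxonRecord],
    reference_category: str,
) -> float:
    """Bootstrap support for a nearest-neighbor category.

    The support is the percentage of replicate trees whose inferred
    nearest-neighbor category equals ``reference_category``.
    Replicates missing the query leaf are skipped with a warning; if
    every replicate is skipped an error is raised.
    """
    if not replicate_trees:
        raise ValueError("no replicate trees supplied")
    agree = 0
    used = 0
    for rep in replicate_trees:
        if query_leaf not in rep.leaf_labels:
            warnings.warn(f"replicate tree lacks query leaf {query_leaf!r}; skipped")
            continue
        used += 1
        call = infer_nearest_neighbor(rep, query_leaf, taxonomy)
        if call.neighbor_category == reference_category:
            agree += 1
    if used == 0:
        raise ValueError(f"query leaf {query_leaf!r} absent from every replicate tree")
    return 100.0 * agree / used


def consistency_filter(
    nj_call: DonorCall,
    ml_call: DonorCall,
    support_percent: float,
    threshold: float = 75.0,
) -> bool:
    """Retain a call only with strong support and NJ/ML agreement.

    Retained iff ``support_percent`` is *strictly* greater than
    ``threshold`` and both tree methods place the query next to the
    same host-association category.
    """
    if nj_call.gene_id != ml_call.gene_id:
        raise ValueError(
            f"gene-id mismatch: NJ call for {nj_call.gene_id!r}, ML call for {ml_call.gene_id!r}"
        )
    return support_percent > threshold and nj_call.neighbor_category == ml_call.neighbor_category


def finalize_call(
    nj_call: DonorCall,
    ml_call: DonorCall,
    support_percent: float,
    threshold: float = 75.0,
) -> DonorCall:
    """Attach support and the retention verdict to the NJ call."""
    consistent = nj_call.neighbor_category == ml_call.neighbor_category
    return DonorCall(
        gene_id=nj_call.gene_id,
        tree_source="NJ",
        neighbor_taxon=nj_call.neighbor_taxon,
        neighbor_category=nj_call.neighbor_category,
        internal_node_count=nj_call.internal_node_count,
        branch_length_sum=nj_call.branch_length_sum,
        support_percent=support_percent,
        consistent_between_methods=consistent,
        retained=consistency_filter(nj_call, ml_call, support_percent, threshold),
    )


def summarize_categories(calls: Sequence[DonorCall]) -> CategorySummary:
    """Per-category counts and percentages over a set of donor calls."""
    if not calls:
        raise ValueError("no donor calls to summarize")
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        if call.neighbor_category not in counts:
            raise ValueError(f"{call.gene_id}: unknown category {call.neighbor_category!r}")
        counts[call.neighbor_category] += 1
    n = len(calls)
    fractions = {c: 100.0 * counts[c] / n for c in CATEGORIES}
    return CategorySummary(counts=counts, fractions_percent=fractions, n_total=n)
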