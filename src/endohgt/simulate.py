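"""Synthetic genome pairs with planted orthologs, syntons and HGT events.

The generator emulates the statistical situation of a reduced
arthropod-symbiont genome compared against its sequenced sister
lineage (an amoeba symbiont whose genome is a superset of the focal
gene set):

* ancestor proteins drawn uniformly over the 20 amino acids,
* sister orthologs derived by independent per-site substitution
  (uniform replacement by one of the 19 other residues, so the
  expected ortholog identity is ``100 * (1 - divergence)``),
* a focal gene order containing configured collinear blocks (conserved
  or inverted) embedded in otherwise shuffled order,
* planted HGT genes whose ranked hit tables and per-gene alignments
  point at donor taxa of known host-association category, while
  vertical genes always carry at least one within-phylum hit among
  their best hits,
* a taxonomy table assigning every simulated taxon its phylum and
  category.

Everything is reproducible: one seeded NumPy generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CATEGORIES,
    AlignmentSet,
    GeneFeature,
    GenomeRecord,
    HitRecord,
    TaxonRecord,
    write_fasta,
    write_features_tsv,
    write_hit_tables,
    write_taxonomy,
)
from .synteny import OrthologPair

__all__ = [
    "SimulationConfig",
    "TruthRow",
    "TruthTable",
    "simulate_genome_pair",
    "simulate_hgt_evidence",
    "build_taxon_panel",
    "truth_ortholog_pairs",
    "expected_ortholog_identity",
    "write_dataset",
]

AMINO_ACIDS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

FOCAL_TAXON = "Cardinium-like symbiont (simulated)"
SISTER_TAXON = "Amoebophilus-like symbiont (simulated)"
SELF_PHYLUM = "Bacteroidetes"

#: Phylum assigned to simulated donor taxa of each category (anything
#: outside the focal phylum works; names are cosmetic).
_DONOR_PHYLA = {
    "AM": "Chlamydiae",
    "AA": "Proteobacteria",
    "ART": "Proteobacteria",
    "E": "Ascomycota",
    "X": "Firmicutes",
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic genome pair.

    The defaults define the benchmark setting used throughout the test
    suite: 300 genes, 30 planted HGT events, sister divergence 0.2
    substitutions per site, HGT-gene-to-donor divergence 0.05, and a
    donor-category mix matching the ecological profile reported for
    arthropod endosymbionts (ART 38%, AA 24%, AM 14%, X 16%, E 8%).
    """

    seed: int = 1
    n_genes: int = 300
    n_hgt: int = 30
    donor_category_mix: dict[str, float] = field(
        default_factory=lambda: {"ART": 0.38, "AA": 0.24, "AM": 0.14, "X": 0.16, "E": 0.08}
    )
    divergence: float = 0.2
    hgt_divergence: float = 0.05
    n_taxa_per_tree: int = 12
    synteny_block_spec: tuple[tuple[int, str], ...] = (
        (5, "conserved"),
        (4, "inverted"),
        (3, "conserved"),
    )
    gene_length_range: tuple[int, int] = (100, 400)
    sister_ortholog_fraction: float = 0.67
    n_extra_sister_genes: int | None = None
    n_transposase: int = 8
    n_taxa_per_category: int = 4
    n_within_phylum_taxa: int = 4
    n_hits_per_gene: int = 12
    gc_content: float = 0.36

    def __post_init__(self) -> None:
        if abs(sum(self.donor_category_mix.values()) - 1.0) > 1e-9:
            raise ValueError("donor_category_mix proportions must sum to 1")
        if not set(self.donor_category_mix) <= set(CATEGORIES):
            raise ValueError(f"categories must be among {CATEGORIES}")
        for name in ("divergence", "hgt_divergence"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_hgt > self.n_genes:
            raise ValueError("n_hgt cannot exceed n_genes")
        if self.gene_length_range[0] < 10 or self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("invalid gene_length_range")
        for size, orient in self.synteny_block_spec:
            if size < 1 or orient not in ("conserved", "inverted"):
                raise ValueError(f"invalid synteny block ({size}, {orient!r})")
        if self.n_taxa_per_tree < 4:
            raise ValueError("n_taxa_per_tree must be >= 4")

    @property
    def extra_sister_genes(self) -> int:
        if self.n_extra_sister_genes is not None:
            return self.n_extra_sister_genes
        return round(0.85 * self.n_genes)


@dataclass(frozen=True)
class TruthRow:
    gene_id: str
    is_hgt: bool
    donor_taxon: str | None = None
    donor_category: str | None = None
    synton_id: str | None = None
    ortholog_in_sister: str | None = None


@dataclass
class TruthTable:
    """Ground truth of one simulation, keyed by focal gene id."""

    rows: dict[str, TruthRow]

    def hgt_genes(self) -> list[str]:
        return [g for g, r in self.rows.items() if r.is_hgt]

    def vertical_genes(self) -> list[str]:
        return [g for g, r in self.rows.items() if not r.is_hgt]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "is_hgt": r.is_hgt,
                    "donor_taxon": r.donor_taxon or "",
                    "donor_category": r.donor_category or "",
                    "synton_id": r.synton_id or "",
                    "ortholog_in_sister": r.ortholog_in_sister or "",
                }
                for r in self.rows.values()
            ]
        )


# ----------------------------------------------------------------------
# sequence helpers
# ----------------------------------------------------------------------
def _random_protein(rng: np.random.Generator, length: int) -> np.ndarray:
    return AMINO_ACIDS[rng.integers(0, 20, size=length)]


def _mutate(protein: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution to one of the 19 other residues."""
    out = protein.copy()
    mask = rng.random(len(protein)) < rate
    if mask.any():
        idx = np.searchsorted(AMINO_ACIDS, out[mask])
        out[mask] = AMINO_ACIDS[(idx + 1 + rng.integers(0, 19, size=mask.sum())) % 20]
    return out


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def expected_ortholog_identity(divergence: float) -> float:
    """Analytic expected percent identity under the substitution scheme."""
    return 100.0 * (1.0 - divergence)


def _allocate_categories(mix: dict[str, float], n: int) -> list[str]:
    """Largest-remainder allocation of n items to categories."""
    cats = sorted(mix, key=lambda c: (-mix[c], c))
    raw = {c: mix[c] * n for c in cats}
    counts = {c: int(raw[c]) for c in cats}
    short = n - sum(counts.values())
    for c in sorted(cats, key=lambda c: (-(raw[c] - counts[c]), c))[:short]:
        counts[c] += 1
    out: list[str] = []
    for c in cats:
        out.extend([c] * counts[c])
    return out


# ----------------------------------------------------------------------
# taxon panel
# ----------------------------------------------------------------------
def build_taxon_panel(config: SimulationConfig) -> dict[str, TaxonRecord]:
    """The fixed cast of taxa appearing in hit tables and trees."""
    panel: dict[str, TaxonRecord] = {
        FOCAL_TAXON: TaxonRecord(FOCAL_TAXON, SELF_PHYLUM, "ART"),
        SISTER_TAXON: TaxonRecord(SISTER_TAXON, SELF_PHYLUM, "AM"),
    }
    for i in range(1, config.n_within_phylum_taxa + 1):
        name = f"Bacteroidetes_sp_{i}"
        panel[name] = TaxonRecord(name, SELF_PHYLUM, "X")
    for cat in CATEGORIES:
        for i in range(1, config.n_taxa_per_category + 1):
            name = f"{cat}_donor_{i}"
            panel[name] = TaxonRecord(name, _DONOR_PHYLA[cat], cat)
    return panel


def donor_taxa(panel: dict[str, TaxonRecord], category: str) -> list[str]:
    return sorted(
        t for t, rec in panel.items() if rec.category == category and rec.phylum != SELF_PHYLUM
    )


# ----------------------------------------------------------------------
# genome pair
# ----------------------------------------------------------------------
def simulate_genome_pair(
    config: SimulationConfig,
) -> tuple[GenomeRecord, GenomeRecord, dict[str, dict[str, str]], TruthTable]:
    """Generate the focal/sister genome pair and its ground truth.

    Returns the focal genome record (A), the sister record (B), the two
    proteomes (keys ``"A"`` and ``"B"``), and the truth table.
    """
    rng = np.random.default_rng(config.seed)
    panel = build_taxon_panel(config)
    n = config.n_genes
    gene_ids = [f"SYMA_{i + 1:04d}" for i in range(n)]
    lengths = rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=n)
    proteins = {g: _random_protein(rng, int(lengths[i])) for i, g in enumerate(gene_ids)}

    # planted HGT genes and their donors
    hgt_ids = sorted(rng.choice(gene_ids, size=config.n_hgt, replace=False).tolist())
    categories = _allocate_categories(config.donor_category_mix, config.n_hgt)
    rng.shuffle(categories)
    donors: dict[str, tuple[str, str]] = {}
    for gid, cat in zip(hgt_ids, categories):
        pool = donor_taxa(panel, cat)
        donors[gid] = (pool[int(rng.integers(0, len(pool)))], cat)

    # transposase decoys among vertical genes (excluded by the screen)
    vertical = [g for g in gene_ids if g not in donors]
    transposase_ids = set(
        rng.choice(vertical, size=min(config.n_transposase, len(vertical)), replace=False).tolist()
    )

    # sister orthologs: a fraction of the non-HGT genes (the focal
    # genome is a subset of the sister genome; HGT genes are private)
    n_orth = min(round(config.sister_ortholog_fraction * n), len(vertical))
    ortholog_ids = sorted(rng.choice(vertical, size=n_orth, replace=False).tolist())
    sister_of = {g: f"SYMB_{i + 1:04d}" for i, g in enumerate(ortholog_ids)}
    proteins_b: dict[str, np.ndarray] = {
        sister_of[g]: _mutate(proteins[g], config.divergence, rng) for g in ortholog_ids
    }
    for i in range(config.extra_sister_genes):
        bid = f"SYMB_X{i + 1:04d}"
        length = int(
            rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1)
        )
        proteins_b[bid] = _random_protein(rng, length)

    # synteny blocks over ortholog genes
    total_block = sum(size for size, _ in config.synteny_block_spec)
    if total_block > len(ortholog_ids):
        raise ValueError(
            f"infeasible synteny block spec: {total_block} block genes but only "
            f"{len(ortholog_ids)} ortholog genes"
        )
    shuffled_orth = list(ortholog_ids)
    rng.shuffle(shuffled_orth)
    blocks: list[tuple[str, list[str], str]] = []
    cursor = 0
    synton_of: dict[str, str] = {}
    for bi, (size, orient) in enumerate(config.synteny_block_spec):
        members = shuffled_orth[cursor : cursor + size]
        cursor += size
        block_id = f"synton_{bi + 1}"
        blocks.append((block_id, members, orient))
        for g in members:
            synton_of[g] = block_id

    # gene orders: blocks are kept contiguous, everything else shuffled
    block_members = set(synton_of)
    a_units: list[list[str]] = [[g] for g in gene_ids if g not in block_members]
    a_units.extend([list(members) for _, members, _ in blocks])
    rng.shuffle(a_units)
    a_order = [g for unit in a_units for g in unit]

    b_single = [b for b in proteins_b if b not in {sister_of[g] for g in block_members}]
    b_units: list[list[str]] = [[b] for b in b_single]
    for _, members, orient in blocks:
        run = [sister_of[g] for g in members]
        if orient == "inverted":
            run = run[::-1]
        b_units.append(run)
    rng.shuffle(b_units)
    b_order = [b for unit in b_units for b in unit]

    products = {}
    for g in gene_ids:
        products[g] = (
            "IS5 family transposase" if g in transposase_ids else "hypothetical protein"
        )

    record_a = _build_record("symA_chr", a_order, proteins, products, config, rng, with_rna=True)
    record_b = _build_record(
        "symB_chr",
        b_order,
        proteins_b,
        {b: "hypothetical protein" for b in proteins_b},
        config,
        rng,
        with_rna=True,
    )

    truth = TruthTable(
        rows={
            g: TruthRow(
                gene_id=g,
                is_hgt=g in donors,
                donor_taxon=donors[g][0] if g in donors else None,
                donor_category=donors[g][1] if g in donors else None,
                synton_id=synton_of.get(g),
                ortholog_in_sister=sister_of.get(g),
            )
            for g in gene_ids
        }
    )
    proteomes = {
        "A": {g: _to_str(p) for g, p in proteins.items()},
        "B": {b: _to_str(p) for b, p in proteins_b.items()},
    }
    return record_a, record_b, proteomes, truth


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return bases[rng.choice(4, size=length, p=probs)].tobytes().decode("ascii")


def _build_record(
    replicon_id: str,
    gene_order: list[str],
    proteins: dict[str, np.ndarray],
    products: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
    with_rna: bool = False,
) -> GenomeRecord:
    """Lay genes along a chromosome with random intergenic spacers."""
    chunks: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for g in gene_order:
        spacer = int(rng.integers(20, 121))
        chunks.append(_random_dna(rng, spacer, config.gc_content))
        pos += spacer
        cds_len = 3 * (len(proteins[g]) + 1)
        chunks.append(_random_dna(rng, cds_len, config.gc_content))
        features.append(
            GeneFeature(
                locus_tag=g,
                kind="CDS",
                start=pos + 1,
                end=pos + cds_len,
                strand="+" if rng.random() < 0.5 else "-",
                product=products[g],
                protein_id=f"{g}.1",
            )
        )
        pos += cds_len
    if with_rna:
        for kind, length, product in (
            ("rRNA", 1500, "16S ribosomal RNA"),
            ("rRNA", 2900, "23S ribosomal RNA"),
            ("rRNA", 120, "5S ribosomal RNA"),
            *[("tRNA", 76, f"tRNA-{aa}") for aa in ("Ala", "Gly", "Leu", "Ser", "Thr")],
        ):
            spacer = int(rng.integers(20, 121))
            chunks.append(_random_dna(rng, spacer, config.gc_content))
            pos += spacer
            chunks.append(_random_dna(rng, length, config.gc_content))
            features.append(
                GeneFeature(
                    locus_tag=f"{replicon_id}_{kind}_{pos}",
                    kind=kind,
                    start=pos + 1,
                    end=pos + length,
                    strand="+",
                    product=product,
                )
            )
            pos += length
    return GenomeRecord(replicon_id=replicon_id, sequence="".join(chunks), features=features)


# ----------------------------------------------------------------------
# HGT evidence: hit tables, alignments, taxonomy
# ----------------------------------------------------------------------
def simulate_hgt_evidence(
    config: SimulationConfig,
    truth: TruthTable,
    proteome_a: dict[str, str],
) -> tuple[dict[str, list[HitRecord]], dict[str, AlignmentSet], dict[str, TaxonRecord]]:
    """Ranked hit tables, per-gene alignments, and the taxonomy table.

    HGT genes receive top hits exclusively from donor-lineage taxa
    (outside the focal phylum) with identities decreasing in rank;
    vertical genes always carry a within-phylum hit at rank 1.
    Alignments (gap-free) contain the query plus ``n_taxa_per_tree - 1``
    subjects at divergences that make the planted donor the nearest
    neighbor.
    """
    rng = np.random.default_rng([config.seed, 7])
    panel = build_taxon_panel(config)
    outside_cats = list(CATEGORIES)

    hit_tables: dict[str, list[HitRecord]] = {}
    alignments: dict[str, AlignmentSet] = {}
    for gene_id, row in truth.rows.items():
        protein = np.frombuffer(proteome_a[gene_id].encode("ascii"), dtype=np.uint8)
        alen = len(protein)
        if row.is_hgt:
            taxa = _hgt_hit_taxa(row, panel, config, rng)
            top_identity = 100.0 * (1.0 - config.hgt_divergence)
        else:
            taxa = _vertical_hit_taxa(row, panel, config, rng)
            top_identity = 100.0 * (1.0 - config.divergence)
        hits = []
        identity = top_identity
        for rank, taxon in enumerate(taxa, start=1):
            identity = max(15.0, identity - float(rng.uniform(0.5, 3.0)))
            bitscore = round(max(30.0, identity * alen / 40.0), 1)
            evalue = min(10.0, alen * 2.0e7 * 2.0 ** (-bitscore))
            hits.append(
                HitRecord(
                    query_id=gene_id,
                    subject_id=f"{taxon.replace(' ', '_')}|{gene_id}|{rank}",
                    subject_taxon=taxon,
                    percent_identity=round(identity, 1),
                    alignment_length=alen,
                    evalue=evalue,
                    bitscore=bitscore,
                    rank=rank,
                )
            )
        hit_tables[gene_id] = hits
        if row.is_hgt:
            alignments[gene_id] = _hgt_alignment(gene_id, protein, row, panel, config, rng)
    return hit_tables, alignments, build_taxon_panel(config)


def _hgt_hit_taxa(
    row: TruthRow,
    panel: dict[str, TaxonRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[str]:
    """Top hits: donor first, then other outside-phylum taxa; the
    within-phylum taxa only appear below rank 10."""
    outside = [
        t
        for t in panel
        if panel[t].phylum != SELF_PHYLUM and t != row.donor_taxon
    ]
    same_cat = sorted(t for t in outside if panel[t].category == row.donor_category)
    other = sorted(t for t in outside if panel[t].category != row.donor_category)
    rng.shuffle(other)
    taxa = [row.donor_taxon] + same_cat + other
    taxa = taxa[:10]
    within = sorted(t for t in panel if panel[t].phylum == SELF_PHYLUM and t != FOCAL_TAXON)
    taxa.extend(within[: config.n_hits_per_gene - len(taxa)])
    return taxa


def _vertical_hit_taxa(
    row: TruthRow,
    panel: dict[str, TaxonRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[str]:
    """Rank 1 is the sister lineage (or another within-phylum taxon),
    guaranteeing a within-phylum hit among the ten best."""
    within = sorted(t for t in panel if panel[t].phylum == SELF_PHYLUM and t != FOCAL_TAXON)
    first = SISTER_TAXON if row.ortholog_in_sister else within[int(rng.integers(0, len(within)))]
    rest = [t for t in within if t != first]
    outside = sorted(t for t in panel if panel[t].phylum != SELF_PHYLUM)
    rng.shuffle(outside)
    taxa = [first] + rest + outside
    return taxa[: config.n_hits_per_gene]


def _hgt_alignment(
    gene_id: str,
    protein: np.ndarray,
    row: TruthRow,
    panel: dict[str, TaxonRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> AlignmentSet:
    """Query + subjects; the planted donor sits at the lowest divergence."""
    sequences: dict[str, str] = {gene_id: _to_str(protein)}
    sequences[row.donor_taxon] = _to_str(_mutate(protein, config.hgt_divergence, rng))
    same_cat = [
        t
        for t in donor_taxa(panel, row.donor_category)
        if t != row.donor_taxon
    ]
    divergences = [0.18, 0.24]
    for taxon, div in zip(same_cat, divergences):
        sequences[taxon] = _to_str(_mutate(protein, div, rng))
    others = sorted(
        t
        for t in panel
        if panel[t].phylum != SELF_PHYLUM and t not in sequences
    )
    rng.shuffle(others)
    far = 0.40
    while len(sequences) < config.n_taxa_per_tree and others:
        taxon = others.pop()
        sequences[taxon] = _to_str(_mutate(protein, far, rng))
        far = min(0.55, far + 0.02)
    return AlignmentSet(sequences=sequences)


# ----------------------------------------------------------------------
# convenience
# ----------------------------------------------------------------------
def truth_ortholog_pairs(
    record_a: GenomeRecord,
    record_b: GenomeRecord,
    truth: TruthTable,
) -> list[OrthologPair]:
    """Ortholog pairs with order indices, straight from the truth table."""
    index_a = {f.locus_tag: f.order_index for f in record_a.cds_features()}
    index_b = {f.locus_tag: f.order_index for f in record_b.cds_features()}
    pairs = []
    for g, row in truth.rows.items():
        if row.ortholog_in_sister:
            pairs.append(
                OrthologPair(
                    a_locus=g,
                    b_locus=row.ortholog_in_sister,
                    a_index=index_a[g],
                    b_index=index_b[row.ortholog_in_sister],
                )
            )
    return pairs


def write_dataset(
    out_dir: str | Path,
    record_a: GenomeRecord,
    record_b: GenomeRecord,
    proteomes: dict[str, dict[str, str]],
    truth: TruthTable,
    hit_tables: dict[str, list[HitRecord]],
    alignments: dict[str, AlignmentSet],
    taxonomy: dict[str, TaxonRecord],
    seed: int | None = None,
) -> None:
    """Write a full synthetic dataset as plain-text files."""
    out = Path(out_dir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    for name, record in (("genome_A", record_a), ("genome_B", record_b)):
        write_fasta({record.replicon_id: record.sequence}, out / f"{name}.fna")
        write_features_tsv(record, out / f"{name}.features.tsv")
    write_fasta(proteomes["A"], out / "proteome_A.faa")
    write_fasta(proteomes["B"], out / "proteome_B.faa")
    write_hit_tables(hit_tables, out / "hits.tsv")
    write_taxonomy(taxonomy, out / "taxonomy.tsv")
    truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    for gene_id, aln in alignments.items():
        write_fasta(aln.sequences, out / "alignments" / f"{gene_id}.afa")
    if seed is not None:
        (out / "SEED.txt").write_text(f"seed\t{seed}\n")
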