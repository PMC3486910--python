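"""Readers and writers for the external formats the pipeline touches.

Supported formats: GenBank flat files (simple feature spans only),
nucleotide/protein FASTA, aligned multi-FASTA, Newick, ranked homology
hit tables (BLAST outfmt-6 columns plus subject taxon and optional
rank), gene-feature TSV, and taxon/phylum/host-association tables.

Coordinate convention: 1-based inclusive start/end on read and write
(the GenBank convention); interval arithmetic elsewhere converts to
0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

from .tree import Tree, read_newick, read_newick_list, write_newick, write_newick_list

__all__ = [
    "GeneFeature",
    "GenomeRecord",
    "HitRecord",
    "TaxonRecord",
    "AlignmentSet",
    "Tree",
    "CATEGORIES",
    "read_genome",
    "read_hit_tables",
    "write_hit_tables",
    "read_taxonomy",
    "write_taxonomy",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_features_tsv",
    "read_newick",
    "write_newick",
    "read_newick_list",
    "write_newick_list",
]

#: Host-association categories of potential HGT partners:
#: AM = amoeba-associated bacteria, AA = bacteria infecting both amoebae
#: and arthropods, ART = arthropod-associated bacteria, E = eukaryotes,
#: X = other bacteria.
CATEGORIES = ("AM", "AA", "ART", "E", "X")

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "other")

_NUCLEOTIDES = set("ACGTN")


@dataclass
class GeneFeature:
    """One annotated gene on a replicon (1-based inclusive coordinates)."""

    locus_tag: str
    kind: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein_id: str | None = None
    order_index: int = -1

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"{self.locus_tag}: unknown feature kind {self.kind!r}")
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise ValueError(f"{self.locus_tag}: non-integer coordinates")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.locus_tag}: invalid span {self.start}..{self.end} (need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: unknown strand symbol {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """A replicon: nucleotide sequence plus its ordered gene features."""

    replicon_id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _NUCLEOTIDES
        if bad:
            raise ValueError(
                f"{self.replicon_id}: invalid nucleotide characters {sorted(bad)} "
                "(allowed: A/C/G/T/N)"
            )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.locus_tag))
        tags = [f.locus_tag for f in self.features]
        if len(set(tags)) != len(tags):
            dupes = sorted({t for t in tags if tags.count(t) > 1})
            raise ValueError(f"{self.replicon_id}: duplicate locus tags {dupes}")
        for i, feat in enumerate(self.features):
            if feat.end > self.length:
                raise ValueError(
                    f"{self.replicon_id}: feature {feat.locus_tag} span "
                    f"{feat.start}..{feat.end} exceeds sequence length {self.length}"
                )
            feat.order_index = i

    @property
    def length(self) -> int:
        return len(self.sequence)

    def cds_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]

    def feature_by_tag(self, locus_tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(f"{locus_tag!r} not annotated on {self.replicon_id}")


@dataclass(frozen=True)
class HitRecord:
    """One ranked homology hit of a query protein."""

    query_id: str
    subject_id: str
    subject_taxon: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    rank: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"{self.query_id}->{self.subject_id}: identity {self.percent_identity} outside [0,100]"
            )
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}->{self.subject_id}: negative E-value {self.evalue}")
        if self.bitscore < 0:
            raise ValueError(f"{self.query_id}->{self.subject_id}: negative bit score")
        if self.rank < 1:
            raise ValueError(f"{self.query_id}->{self.subject_id}: rank must be >= 1")


@dataclass(frozen=True)
class TaxonRecord:
    """Taxon name with phylum and host-association category."""

    taxon: str
    phylum: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"{self.taxon}: unknown category {self.category!r}; "
                f"allowed values are {', '.join(CATEGORIES)}"
            )


@dataclass
class AlignmentSet:
    """A gap-aligned set of amino-acid sequences keyed by leaf label."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment is empty")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def labels(self) -> list[str]:
        return list(self.sequences)


# ----------------------------------------------------------------------
# genomes
# ----------------------------------------------------------------------
def _read_genbank(path: str | Path) -> GenomeRecord:
    record = SeqIO.read(str(path), "genbank")
    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        if isinstance(feat.location, CompoundLocation):
            raise ValueError(
                f"{record.id}: compound location {feat.location} not supported "
                "(only simple spans are accepted)"
            )
        if feat.location.strand not in (1, -1):
            raise ValueError(f"{record.id}: feature without strand: {feat.location}")
        quals = feat.qualifiers
        features.append(
            GeneFeature(
                locus_tag=quals.get("locus_tag", [f"feat_{len(features)}"])[0],
                kind=feat.type,
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                strand="+" if feat.location.strand == 1 else "-",
                product=quals.get("product", [""])[0],
                protein_id=quals.get("protein_id", [None])[0],
            )
        )
    return GenomeRecord(replicon_id=record.id, sequence=str(record.seq), features=features)


_FEATURE_COLUMNS = ("locus_tag", "kind", "start", "end", "strand", "product")


def _read_fasta_features(fasta_path: str | Path, features_path: str | Path) -> GenomeRecord:
    seqs = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(seqs) != 1:
        raise ValueError(f"{fasta_path}: expected exactly one sequence, found {len(seqs)}")
    features: list[GeneFeature] = []
    with open(features_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _FEATURE_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{features_path}: missing feature columns {missing}")
        col = {name: header.index(name) for name in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                start = int(fields[col["start"]])
                end = int(fields[col["end"]])
            except ValueError as exc:
                raise ValueError(f"{features_path} line {lineno}: non-integer coordinate") from exc
            try:
                features.append(
                    GeneFeature(
                        locus_tag=fields[col["locus_tag"]],
                        kind=fields[col["kind"]],
                        start=start,
                        end=end,
                        strand=fields[col["strand"]],
                        product=fields[col["product"]],
                        protein_id=(
                            fields[col["protein_id"]] or None
                            if "protein_id" in col and len(fields) > col["protein_id"]
                            else None
                        ),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{features_path} line {lineno}: {exc}") from exc
    return GenomeRecord(replicon_id=seqs[0].id, sequence=str(seqs[0].seq), features=features)


def read_genome(
    path: str | Path,
    format: str = "genbank",
    features_path: str | Path | None = None,
) -> GenomeRecord:
    """Read an annotated replicon.

    Parameters
    ----------
    path:
        GenBank flat file, or a single-record nucleotide FASTA when
        ``format="fasta+features_tsv"``.
    format:
        ``"genbank"`` or ``"fasta+features_tsv"``.
    features_path:
        Tab-separated feature table (columns locus_tag, kind, start,
        end, strand, product[, protein_id]); required for the FASTA
        route.
    """
    if format == "genbank":
        return _read_genbank(path)
    if format == "fasta+features_tsv":
        if features_path is None:
            raise ValueError("features_path is required for format 'fasta+features_tsv'")
        return _read_fasta_features(path, features_path)
    raise ValueError(f"unknown genome format {format!r}")


def write_features_tsv(record: GenomeRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_FEATURE_COLUMNS + ("protein_id",)) + "\n")
        for f in record.features:
            fh.write(
                f"{f.locus_tag}\t{f.kind}\t{f.start}\t{f.end}\t{f.strand}\t{f.product}\t"
                f"{f.protein_id or ''}\n"
            )


# ----------------------------------------------------------------------
# FASTA / alignments
# ----------------------------------------------------------------------
def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (protein or nucleotide) FASTA into an ordered id->sequence map."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path: str | Path) -> AlignmentSet:
    """Read an aligned multi-FASTA (gap character ``-``)."""
    return AlignmentSet(sequences=read_fasta(path))


# ----------------------------------------------------------------------
# hit tables
# ----------------------------------------------------------------------
_HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send "
    "evalue bitscore staxon"
).split()


def read_hit_tables(path: str | Path) -> dict[str, list[HitRecord]]:
    """Read a ranked homology hit table (outfmt-6 + staxon [+ rank]).

    Rows for one query need not be contiguous; they are grouped on read.
    When the rank column is absent, ranks are assigned by descending bit
    score, ties broken by ascending E-value then subject id.  When rank
    is present it must be 1..n per query with bit score non-increasing.
    """
    raw: dict[str, list[tuple]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 13:
                raise ValueError(
                    f"{path} line {lineno}: expected >= 13 tab-separated columns, got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                alen = int(fields[3])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: malformed numeric field") from exc
            rank = None
            if len(fields) >= 14 and fields[13] != "":
                try:
                    rank = int(fields[13])
                except ValueError as exc:
                    raise ValueError(f"{path} line {lineno}: malformed rank") from exc
            raw.setdefault(fields[0], []).append(
                (fields[1], fields[12], pident, alen, evalue, bitscore, rank, lineno)
            )

    tables: dict[str, list[HitRecord]] = {}
    for query, rows in raw.items():
        have_ranks = [r[6] for r in rows if r[6] is not None]
        if have_ranks and len(have_ranks) != len(rows):
            raise ValueError(f"{path}: query {query}: rank present on only some rows")
        if have_ranks:
            rows = sorted(rows, key=lambda r: r[6])
            if [r[6] for r in rows] != list(range(1, len(rows) + 1)):
                raise ValueError(f"{path}: query {query}: ranks are not 1..n without gaps")
        else:
            rows = sorted(rows, key=lambda r: (-r[5], r[4], r[0]))
        hits = []
        for i, (sseqid, staxon, pident, alen, evalue, bitscore, _, lineno) in enumerate(rows):
            try:
                hits.append(
                    HitRecord(
                        query_id=query,
                        subject_id=sseqid,
                        subject_taxon=staxon,
                        percent_identity=pident,
                        alignment_length=alen,
                        evalue=evalue,
                        bitscore=bitscore,
                        rank=i + 1,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
        for a, b in zip(hits, hits[1:]):
            if b.bitscore > a.bitscore + 1e-9:
                raise ValueError(
                    f"{path}: query {query}: bit score increases from rank {a.rank} to {b.rank}"
                )
        tables[query] = hits
    return tables


def write_hit_tables(tables: Mapping[str, Iterable[HitRecord]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for hits in tables.values():
            for h in hits:
                fh.write(
                    f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.1f}\t"
                    f"{h.alignment_length}\t0\t0\t1\t{h.alignment_length}\t1\t"
                    f"{h.alignment_length}\t{h.evalue:.3g}\t{h.bitscore:.1f}\t"
                    f"{h.subject_taxon}\t{h.rank}\n"
                )


# ----------------------------------------------------------------------
# taxonomy
# ----------------------------------------------------------------------
def read_taxonomy(path: str | Path) -> dict[str, TaxonRecord]:
    """Read a taxon -> (phylum, category) table (TSV, optional header)."""
    records: dict[str, TaxonRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and [f.lower() for f in fields[:3]] == ["taxon", "phylum", "category"]:
                continue
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: expected 3 columns (taxon, phylum, category)")
            taxon, phylum, category = fields[0], fields[1], fields[2]
            if taxon in records:
                raise ValueError(f"{path} line {lineno}: duplicate taxon {taxon!r}")
            try:
                records[taxon] = TaxonRecord(taxon=taxon, phylum=phylum, category=category)
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
    return records


def write_taxonomy(records: Mapping[str, TaxonRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tphylum\tcategory\n")
        for rec in records.values():
            fh.write(f"{rec.taxon}\t{rec.phylum}\t{rec.category}\n")
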