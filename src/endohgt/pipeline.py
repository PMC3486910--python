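"""End-to-end orchestration: stats -> orthologs -> synteny -> AFP ->
HGT screen -> trees -> donor inference -> category summary.

The pipeline consumes files (annotated genomes, proteomes, ranked hit
tables, a taxonomy table, per-gene alignments, optional ingested
maximum-likelihood trees) and emits a structured :class:`RunReport`
whose every number is traceable to a stage output file.  A given
configuration and seed always reproduce the identical report.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, genome_stats, hgt, homology, phylo, synteny
from .io_formats import (
    GenomeRecord,
    read_alignment,
    read_fasta,
    read_genome,
    read_hit_tables,
    read_newick,
    read_taxonomy,
    write_newick,
)
from .tree import write_newick_list

logger = logging.getLogger("endohgt")

__all__ = ["PipelineParams", "PipelineConfig", "RunReport", "run_pipeline", "write_report"]


@dataclass
class PipelineParams:
    """All stage parameters; defaults follow the standard screen values
    (k=10 best hits, identity >= 25%, size ratio >= 0.8, E <= 1e-10,
    GC-skew window 887 bp, syntons of >= 3 genes, 2000 bootstrap
    replicates, support threshold 75%)."""

    k: int = 10
    self_phylum: str = "Bacteroidetes"
    self_taxon: str | None = None
    min_identity: float = 25.0
    min_size_ratio: float = 0.80
    shared_max_evalue: float | None = 1e-5
    afp_max_evalue: float = 1e-10
    afp_max_gap: int = 5
    gc_window: int = 887
    gc_step: int | None = None
    synteny_min_genes: int = 3
    synteny_max_gap: int = 3
    replicates: int = 2000
    support_threshold: float = 75.0
    distance_model: str = "p"
    gap_handling: str = "pairwise_deletion"
    seed: int = 1

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PipelineConfig:
    """Input paths, stage switches and parameters for one run."""

    out_dir: str | Path
    genome_a: str | Path | None = None
    genome_a_features: str | Path | None = None
    genome_b: str | Path | None = None
    genome_b_features: str | Path | None = None
    proteome_a: str | Path | None = None
    proteome_b: str | Path | None = None
    hits: str | Path | None = None
    taxonomy: str | Path | None = None
    alignments_dir: str | Path | None = None
    ml_trees_dir: str | Path | None = None
    afp_reference: str | Path | None = None
    skip_stages: tuple[str, ...] = ()
    params: PipelineParams = field(default_factory=PipelineParams)


@dataclass
class RunReport:
    """The quantitative skeleton of a comparative-genomics run."""

    genome_summaries: list[genome_stats.GenomeSummary] = field(default_factory=list)
    shared_count: int | None = None
    shared_percent: float | None = None
    synton_count: int | None = None
    cds_in_syntons: int | None = None
    afp_gene_count: int | None = None
    afp_region_count: int | None = None
    hgt_candidate_count: int | None = None
    hgt_candidate_percent: float | None = None
    donor_calls: list[hgt.DonorCall] = field(default_factory=list)
    category_summary_retained: hgt.CategorySummary | None = None
    category_summary_all: hgt.CategorySummary | None = None
    provenance: dict = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name: str, config: PipelineConfig) -> bool:
    return name not in config.skip_stages


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages in order and write all outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.params
    report = RunReport()
    report.provenance = {
        "tool_version": __version__,
        "parameters": params.as_dict(),
        "input_checksums": {
            name: _sha256(p)
            for name, p in (
                ("genome_a", config.genome_a),
                ("genome_b", config.genome_b),
                ("proteome_a", config.proteome_a),
                ("proteome_b", config.proteome_b),
                ("hits", config.hits),
                ("taxonomy", config.taxonomy),
            )
            if p is not None
        },
    }

    record_a = record_b = None
    if config.genome_a is not None:
        record_a = _load_genome(config.genome_a, config.genome_a_features)
    if config.genome_b is not None:
        record_b = _load_genome(config.genome_b, config.genome_b_features)

    # ---------------------------------------------------------- stats
    if _stage("stats", config) and record_a is not None:
        t0 = time.perf_counter()
        for record in filter(None, (record_a, record_b)):
            summary = genome_stats.summarize(record)
            report.genome_summaries.append(summary)
            profile = genome_stats.gc_skew(record.sequence, params.gc_window, params.gc_step)
            pd.DataFrame(profile.values, columns=["window_start", "skew"]).to_csv(
                out / f"gc_skew.{record.replicon_id}.tsv", sep="\t", index=False
            )
        _write_genome_summaries(report.genome_summaries, out / "genome_summary.tsv")
        logger.info("stats: %d replicon(s) in %.1fs", len(report.genome_summaries),
                    time.perf_counter() - t0)

    proteome_a = read_fasta(config.proteome_a) if config.proteome_a else None
    proteome_b = read_fasta(config.proteome_b) if config.proteome_b else None

    # ------------------------------------------------------ orthologs
    shared: set[str] | None = None
    if _stage("orthologs", config) and proteome_a and proteome_b:
        t0 = time.perf_counter()
        shared, table = homology.shared_protein_screen(
            proteome_a, proteome_b, params.min_identity, params.min_size_ratio,
            params.shared_max_evalue,
        )
        table.to_csv(out / "shared_proteins.tsv", sep="\t", index=False)
        report.shared_count = len(shared)
        report.shared_percent = 100.0 * len(shared) / len(proteome_a)
        logger.info("orthologs: %d/%d shared in %.1fs", len(shared), len(proteome_a),
                    time.perf_counter() - t0)

        # ---------------------------------------------------- synteny
        if _stage("synteny", config) and record_a is not None and record_b is not None:
            pairs = _best_hit_pairs(table, record_a, record_b)
            syntons = synteny.detect_syntons(
                pairs, params.synteny_min_genes, params.synteny_max_gap
            )
            report.synton_count = len(syntons)
            report.cds_in_syntons = sum(s.size for s in syntons)
            _write_syntons(syntons, out / "syntons.tsv")
            logger.info("synteny: %d syntons covering %d genes",
                        report.synton_count, report.cds_in_syntons)

    # ------------------------------------------------------------ afp
    if _stage("afp", config) and config.afp_reference and proteome_a and record_a is not None:
        t0 = time.perf_counter()
        reference = read_fasta(config.afp_reference)
        table = homology.afp_screen(proteome_a, reference, params.afp_max_evalue)
        table.to_csv(out / "afp_screen.tsv", sep="\t", index=False)
        retained = table.loc[table["retained"], "gene_id"].tolist()
        regions = homology.group_regions(retained, record_a, params.afp_max_gap)
        report.afp_gene_count = len(retained)
        report.afp_region_count = len(regions)
        with open(out / "afp_regions.tsv", "w") as fh:
            fh.write("region_id\tsize\tfirst_index\tlast_index\tmembers\tmax_gap\n")
            for r in regions:
                fh.write(
                    f"{r.region_id}\t{r.size}\t{r.first_index}\t{r.last_index}\t"
                    f"{','.join(r.members)}\t{params.afp_max_gap}\n"
                )
        logger.info("afp: %d genes in %d regions in %.1fs", len(retained), len(regions),
                    time.perf_counter() - t0)

    # ----------------------------------------------------- hgt screen
    candidates = None
    taxonomy = read_taxonomy(config.taxonomy) if config.taxonomy else None
    if _stage("hgt", config) and config.hits and taxonomy is not None:
        hit_tables = read_hit_tables(config.hits)
        products = (
            {f.locus_tag: f.product for f in record_a.cds_features()}
            if record_a is not None
            else {}
        )
        candidates = hgt.screen_hgt_candidates(
            hit_tables,
            taxonomy,
            self_phylum=params.self_phylum,
            self_taxon=params.self_taxon,
            k=params.k,
            products=products,
            shared_with_sister=shared,
        )
        n_candidates = sum(1 for c in candidates if c.candidate)
        report.hgt_candidate_count = n_candidates
        denominator = len(record_a.cds_features()) if record_a is not None else len(hit_tables)
        report.hgt_candidate_percent = 100.0 * n_candidates / denominator
        pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "candidate": c.candidate,
                    "n_hits_examined": c.n_hits_examined,
                    "outside_phylum_in_top_k": c.outside_phylum_in_top_k,
                    "excluded_reason": c.excluded_reason or "",
                }
                for c in candidates
            ]
        ).to_csv(out / "hgt_candidates.tsv", sep="\t", index=False)
        logger.info("hgt screen: %d candidates", n_candidates)

    # ---------------------------------------- trees + donor inference
    if (
        _stage("trees", config)
        and candidates is not None
        and config.alignments_dir is not None
    ):
        t0 = time.perf_counter()
        aln_dir = Path(config.alignments_dir)
        tree_dir = out / "trees"
        tree_dir.mkdir(exist_ok=True)
        for idx, cand in enumerate(c for c in candidates if c.candidate):
            aln_path = aln_dir / f"{cand.gene_id}.afa"
            if not aln_path.exists():
                logger.warning("trees: no alignment for %s; skipped", cand.gene_id)
                continue
            aln = read_alignment(aln_path)
            dm = phylo.pdistance_matrix(aln, params.gap_handling, params.distance_model)
            nj = phylo.nj_tree(dm)
            nj_call = hgt.infer_nearest_neighbor(nj, cand.gene_id, taxonomy, "NJ")
            ml_tree = _ml_tree(config, cand.gene_id, aln, params)
            ml_call = hgt.infer_nearest_neighbor(ml_tree, cand.gene_id, taxonomy, "ML")
            reps = phylo.bootstrap_nj(
                aln,
                replicates=params.replicates,
                seed=[params.seed, idx],
                gap_handling=params.gap_handling,
                model=params.distance_model,
            )
            support = hgt.assess_support(reps, cand.gene_id, taxonomy, nj_call.neighbor_category)
            call = hgt.finalize_call(nj_call, ml_call, support, params.support_threshold)
            report.donor_calls.append(call)
            nj.annotate_support(reps)
            (tree_dir / f"{cand.gene_id}.nj.nwk").write_text(write_newick(nj) + "\n")
            (tree_dir / f"{cand.gene_id}.replicates.nwk").write_text(write_newick_list(reps))
        _write_donor_calls(report.donor_calls, out / "donor_calls.tsv")
        logger.info("trees: %d donor calls in %.1fs", len(report.donor_calls),
                    time.perf_counter() - t0)

        retained = [c for c in report.donor_calls if c.retained]
        if retained:
            report.category_summary_retained = hgt.summarize_categories(retained)
        if report.donor_calls:
            report.category_summary_all = hgt.summarize_categories(report.donor_calls)

    write_report(report, out)
    return report


def _load_genome(path: str | Path, features: str | Path | None) -> GenomeRecord:
    if features is not None:
        return read_genome(path, "fasta+features_tsv", features_path=features)
    return read_genome(path, "genbank")


def _ml_tree(config: PipelineConfig, gene_id: str, aln, params: PipelineParams):
    """Ingest an ML tree when provided; otherwise build the fallback
    second tree from Poisson-corrected distances so method consistency
    is still evaluated against an independently modelled tree."""
    if config.ml_trees_dir is not None:
        path = Path(config.ml_trees_dir) / f"{gene_id}.nwk"
        if path.exists():
            return read_newick(path.read_text())
    return phylo.nj_tree(phylo.pdistance_matrix(aln, params.gap_handling, "poisson"))


def _best_hit_pairs(table: pd.DataFrame, record_a: GenomeRecord, record_b: GenomeRecord):
    index_a = {f.locus_tag: f.order_index for f in record_a.cds_features()}
    index_b = {f.locus_tag: f.order_index for f in record_b.cds_features()}
    pairs = []
    for row in table.itertuples():
        if row.shared and row.query_id in index_a and row.best_subject in index_b:
            pairs.append(
                synteny.OrthologPair(
                    a_locus=row.query_id,
                    b_locus=row.best_subject,
                    a_index=index_a[row.query_id],
                    b_index=index_b[row.best_subject],
                )
            )
    return pairs


# ----------------------------------------------------------------------
# report writing
# ----------------------------------------------------------------------
def _fmt1(x: float) -> str:
    return f"{x:.1f}"


def _write_genome_summaries(summaries, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "replicon_id\tsize_bp\tgc_percent\tcds_count\tavg_cds_length_bp\t"
            "coding_density_percent\ttrna_count\trrna_set_count\t"
            "transposase_count\ttransposase_fraction_percent\n"
        )
        for s in summaries:
            fh.write(
                f"{s.replicon_id}\t{s.size_bp}\t{_fmt1(s.gc_percent)}\t{s.cds_count}\t"
                f"{s.avg_cds_length_bp}\t{_fmt1(s.coding_density_percent)}\t{s.trna_count}\t"
                f"{s.rrna_set_count}\t{s.transposase_count}\t"
                f"{_fmt1(s.transposase_fraction_percent)}\n"
            )


def _write_syntons(syntons, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("synton_id\tsize\torientation\ta_loci\tb_loci\n")
        for i, s in enumerate(syntons, 1):
            fh.write(
                f"synton_{i}\t{s.size}\t{s.orientation}\t"
                f"{','.join(p.a_locus for p in s.pairs)}\t"
                f"{','.join(p.b_locus for p in s.pairs)}\n"
            )


def _write_donor_calls(calls, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\ttree_source\tneighbor_taxon\tneighbor_category\t"
            "internal_node_count\tbranch_length_sum\tsupport_percent\t"
            "consistent_between_methods\tretained\n"
        )
        for c in calls:
            fh.write(
                f"{c.gene_id}\t{c.tree_source}\t{c.neighbor_taxon}\t{c.neighbor_category}\t"
                f"{c.internal_node_count}\t{c.branch_length_sum:.6f}\t"
                f"{_fmt1(c.support_percent)}\t{c.consistent_between_methods}\t{c.retained}\n"
            )


def write_report(report: RunReport, out_dir: str | Path) -> Path:
    """Write the human-readable summary; numbers use Table-1 precision
    (sizes as integers, percentages to one decimal)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# comparative-genomics run report", ""]
    if report.genome_summaries:
        lines.append("## genome statistics")
        for s in report.genome_summaries:
            lines += [
                f"replicon {s.replicon_id}: size {s.size_bp} bp, GC {_fmt1(s.gc_percent)}%, "
                f"{s.cds_count} CDSs (avg {s.avg_cds_length_bp} bp, coding density "
                f"{_fmt1(s.coding_density_percent)}%), {s.trna_count} tRNAs, "
                f"{s.rrna_set_count} rRNA set(s), {s.transposase_count} transposase genes "
                f"({_fmt1(s.transposase_fraction_percent)}% of CDSs)",
            ]
        lines.append("")
    lines.append("## cross-genome comparison")
    if report.shared_count is not None:
        lines.append(
            f"shared CDSs: {report.shared_count} ({_fmt1(report.shared_percent)}% of proteome A)"
        )
    else:
        lines.append("shared CDSs: not run")
    if report.synton_count is not None:
        lines.append(
            f"syntons: {report.synton_count} blocks covering {report.cds_in_syntons} CDSs"
        )
    else:
        lines.append("syntons: not run")
    if report.afp_gene_count is not None:
        lines.append(
            f"AFP-like genes: {report.afp_gene_count} in {report.afp_region_count} regions"
        )
    else:
        lines.append("AFP-like genes: not run")
    lines.append("")
    lines.append("## horizontal gene transfer")
    if report.hgt_candidate_count is not None:
        lines.append(
            f"HGT candidates: {report.hgt_candidate_count} "
            f"({_fmt1(report.hgt_candidate_percent)}% of CDSs)"
        )
    else:
        lines.append("HGT candidates: not run")
    for name, summary in (
        ("retained donor calls", report.category_summary_retained),
        ("all donor calls", report.category_summary_all),
    ):
        if summary is not None:
            parts = ", ".join(
                f"{cat} {summary.counts[cat]} ({_fmt1(summary.fractions_percent[cat])}%)"
                for cat in summary.counts
            )
            lines.append(f"{name} (n={summary.n_total}): {parts}")
    lines.append("")
    lines.append("## provenance")
    lines.append(f"tool_version: {report.provenance.get('tool_version', '')}")
    for key, value in sorted(report.provenance.get("parameters", {}).items()):
        lines.append(f"param {key}: {value}")
    for name, digest in sorted(report.provenance.get("input_checksums", {}).items()):
        lines.append(f"sha256 {name}: {digest}")
    text = "\n".join(lines) + "\n"
    path = out / "report.txt"
    path.write_text(text)
    if report.category_summary_retained is not None:
        with open(out / "category_summary.tsv", "w") as fh:
            fh.write("category\tcount\tfraction_percent\tdenominator\n")
            for denom, summary in (
                ("retained", report.category_summary_retained),
                ("all_candidates", report.category_summary_all),
            ):
                if summary is None:
                    continue
                for cat, count in summary.counts.items():
                    fh.write(
                        f"{cat}\t{count}\t{_fmt1(summary.fractions_percent[cat])}\t{denom}\n"
                    )
    return path
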