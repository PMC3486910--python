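from __future__ import annotations

import pytest

from endohgt import hgt, phylo, simulate


def run_recovery_benchmark(config: simulate.SimulationConfig, replicates: int = 200) -> dict:
    """Run the planted-HGT recovery benchmark and collect its metrics.

    Screens the simulated hit tables, infers donors on NJ trees (with a
    Poisson-distance second tree standing in for an ingested ML tree),
    votes bootstrap support, applies the retention filter, and compares
    everything against the planted truth.
    """
    record_a, record_b, proteomes, truth = simulate.simulate_genome_pair(config)
    hit_tables, alignments, taxonomy = simulate.simulate_hgt_evidence(
        config, truth, proteomes["A"]
    )
    shared = {g for g, row in truth.rows.items() if row.ortholog_in_sister}
    products = {f.locus_tag: f.product for f in record_a.cds_features()}
    candidates = hgt.screen_hgt_candidates(
        hit_tables,
        taxonomy,
        self_taxon=simulate.FOCAL_TAXON,
        products=products,
        shared_with_sister=shared,
    )
    flagged = {c.gene_id for c in candidates if c.candidate}
    planted = set(truth.hgt_genes())
    vertical = set(truth.vertical_genes())

    calls: dict[str, hgt.DonorCall] = {}
    for idx, gene in enumerate(sorted(flagged & set(alignments))):
        aln = alignments[gene]
        nj = phylo.nj_tree(phylo.pdistance_matrix(aln))
        nj_call = hgt.infer_nearest_neighbor(nj, gene, taxonomy, "NJ")
        ml = phylo.nj_tree(phylo.pdistance_matrix(aln, model="poisson"))
        ml_call = hgt.infer_nearest_neighbor(ml, gene, taxonomy, "ML")
        reps = phylo.bootstrap_nj(aln, replicates=replicates, seed=[config.seed, idx])
        support = hgt.assess_support(reps, gene, taxonomy, nj_call.neighbor_category)
        calls[gene] = hgt.finalize_call(nj_call, ml_call, support)

    retained = {g: c for g, c in calls.items() if c.retained}
    n_correct = sum(
        1 for g, c in retained.items() if c.neighbor_category == truth.rows[g].donor_category
    )
    return {
        "truth": truth,
        "candidates": candidates,
        "flagged": flagged,
        "recall_percent": 100.0 * len(flagged & planted) / len(planted),
        "false_positive_percent": 100.0 * len(flagged & vertical) / len(vertical),
        "calls": calls,
        "retained": retained,
        "category_accuracy_percent": (
            100.0 * n_correct / len(retained) if retained else float("nan")
        ),
    }


@pytest.fixture(scope="session")
def benchmark():
    """The default-condition recovery benchmark (300 genes, 30 planted
    HGT events, 200 bootstrap replicates, seed 1), computed once."""
    return run_recovery_benchmark(simulate.SimulationConfig(), replicates=200)
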