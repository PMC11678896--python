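"""End-to-end orchestration on a planted synthetic study.

``build_study`` assembles the default desk-scale scenario — 13 diseases x 40
subjects, 500 genes (first 50 designated TFs), latent-factor co-expression,
planted disease-specific over-expression at delta = 3 pooled-IQR units, and
a planted TF whose target block is co-regulated in three diseases — and
``run_pipeline`` drives every stage over it, returning a JSON-able summary
of what was recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dataclasses import replace as _dc_replace

from . import io
from .clustering import cluster_diseases
from .config import PipelineConfig
from .datamodel import GeneSetCollection
from .gsea import run_battery
from .panda import infer_disease_networks
from .signatures import (
    groups_to_frame,
    shared_overexpression_groups,
    shared_pathway_groups,
    tf_pathway_intersection_clusters,
)
from .specificity import score_cohort, score_networks
from .synthetic import SimConfig, generate_cohort, generate_gene_sets, generate_motif_prior, generate_ppi_prior


@dataclass
class StudyScenario:
    """A planted study: simulation config, pathway battery, expected answers."""

    sim: SimConfig
    pathways: GeneSetCollection
    planted_tf: str
    planted_pathway: str
    planted_reg_diseases: frozenset[str]
    expr_pathway_single: str = "PLANTED_EXPR_SINGLE"
    expr_single_disease: str = ""
    expr_pathway_pair: str = "PLANTED_EXPR_PAIR"
    expr_pair_diseases: frozenset[str] = frozenset()


def build_study(
    seed: int = 0,
    n_genes: int = 500,
    n_tfs: int = 50,
    subjects_per_disease: int = 40,
    delta: float = 3.0,
    n_planted_genes: int = 20,
    n_pathways: int = 20,
    reg_strength: float = 1.0,
) -> StudyScenario:
    """The default planted scenario used by the drivers and recovery tests.

    Planted over-expression: ``n_planted_genes`` (gene, disease) pairs at
    ``delta`` x pooled IQR, round-robin over diseases, plus two genes planted
    in the same disease pair (a multiplicity-2 signature).  Two planted
    expression pathways: a 15-gene set shifted in one disease and another
    shifted in two diseases, so the expression GSEA battery has a
    single-disease and a shared-enrichment ground truth.  Planted
    regulation: one TF coupled (strength ``reg_strength``) to a 15-gene
    target block in three diseases; since the motif prior carries those
    edges in every disease network, the regulation battery is expected to
    call the (pathway, TF) pair pan-disease — the shape of most observed
    TF-pathway clusters — with the block as common driving genes.
    """
    diseases = {f"D{i:02d}": subjects_per_disease for i in range(1, 14)}
    disease_names = list(diseases)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]

    planted_specifics = []
    for k in range(n_planted_genes):
        gene = gene_ids[100 + k]
        planted_specifics.append((gene, disease_names[k % len(disease_names)], delta))
    # a shared-signature pair: two genes over-expressed in the same two diseases
    for gene in (gene_ids[300], gene_ids[301]):
        planted_specifics.append((gene, disease_names[0], delta))
        planted_specifics.append((gene, disease_names[1], delta))

    # planted expression pathways: whole gene sets shifted in 1 or 2 diseases
    expr_single = gene_ids[320:335]
    expr_single_disease = disease_names[4]
    planted_specifics += [(g, expr_single_disease, delta) for g in expr_single]
    expr_pair = gene_ids[340:355]
    expr_pair_diseases = disease_names[5:7]
    planted_specifics += [(g, d, delta) for g in expr_pair for d in expr_pair_diseases]

    planted_tf = gene_ids[1]
    block = gene_ids[200:215]
    reg_diseases = disease_names[:3]
    planted_regulations = [
        (planted_tf, g, d, reg_strength) for g in block for d in reg_diseases
    ]

    sim = SimConfig(
        n_genes=n_genes,
        n_tfs=n_tfs,
        diseases=diseases,
        n_latent_factors=10,
        loading_scale=0.5,
        planted_specifics=planted_specifics,
        motif_density=0.05,
        ppi_density=0.1,
        planted_regulations=planted_regulations,
        seed=seed,
    )
    pathways = generate_gene_sets(
        gene_ids,
        n_sets=n_pathways,
        seed=seed,
        planted={
            "PLANTED_TFPATH": set(block),
            "PLANTED_EXPR_SINGLE": set(expr_single),
            "PLANTED_EXPR_PAIR": set(expr_pair),
        },
    )
    return StudyScenario(
        sim=sim,
        pathways=pathways,
        planted_tf=planted_tf,
        planted_pathway="PLANTED_TFPATH",
        planted_reg_diseases=frozenset(reg_diseases),
        expr_single_disease=expr_single_disease,
        expr_pair_diseases=frozenset(expr_pair_diseases),
    )


def gene_recovery(table, truth) -> tuple[float, float]:
    """(sensitivity, false-discovery proportion) of specificity calls vs truth."""
    called = {
        (row.feature, row.disease)
        for row in table.table.itertuples(index=False)
        if row.specific
    }
    true = truth.true_specific_genes
    tp = len(called & true)
    sensitivity = tp / len(true) if true else float("nan")
    fdp = (len(called) - tp) / len(called) if called else 0.0
    return sensitivity, fdp


def run_pipeline(cfg: PipelineConfig | None = None, outdir: str | None = None) -> dict:
    """Simulate the default study and run every stage; optionally write TSVs.

    The expression battery runs at 20000 permutations: with ~300 tests and a
    handful of true enrichments, the plus-one estimator needs a floor of
    ~1/(n_perm+1) well below 0.01 x rank/m for the BH call at 0.01 to be
    attainable at all — a Monte-Carlo resolution requirement, fixed a
    priori from the battery size.
    """
    cfg = cfg or PipelineConfig()
    if cfg.permutations_expr < 20000:
        cfg = _dc_replace(cfg, permutations_expr=20000)
    scenario = build_study(seed=cfg.seed)
    cohort, truth = generate_cohort(scenario.sim)
    motif = generate_motif_prior(scenario.sim)
    ppi = generate_ppi_prior(scenario.sim)

    gene_table = score_cohort(cohort, cfg, what="genes")
    tf_table = score_cohort(cohort, cfg, what="tfs")
    sensitivity, fdp = gene_recovery(gene_table, truth)

    dist, dend, assign = cluster_diseases(gene_table, cfg.min_cluster_size, cfg.prune_gap_fraction)

    networks = infer_disease_networks(cohort, motif, ppi, cfg.panda())
    edge_table = score_networks(networks, cfg)

    expr_records = run_battery("expression", scenario.pathways, cohort=cohort, cfg=cfg, significant_only=False)
    reg_records = run_battery(
        "regulation", scenario.pathways, networks=networks, cfg=cfg,
        significant_only=False, tfs=[scenario.planted_tf],
    )
    expr_sig = [r for r in expr_records if r.p_adjusted < cfg.p_pathway_expr]
    reg_sig = [r for r in reg_records if r.p_adjusted < cfg.p_pathway_reg]

    gene_groups = shared_overexpression_groups(gene_table)
    pathway_groups = shared_pathway_groups(expr_sig)
    tf_clusters = tf_pathway_intersection_clusters(reg_sig)

    recovered = any(
        g.diseases >= scenario.planted_reg_diseases
        and any(
            p == scenario.planted_pathway and tf == scenario.planted_tf and common
            for p, tf, common in g.shared_items
        )
        for g in tf_clusters
    )
    expr_single_hit = {
        r.disease for r in expr_sig if r.pathway == scenario.expr_pathway_single
    } == {scenario.expr_single_disease}
    expr_pair_hit = {
        r.disease for r in expr_sig if r.pathway == scenario.expr_pathway_pair
    } == set(scenario.expr_pair_diseases)

    summary = {
        "n_genes": scenario.sim.n_genes,
        "n_subjects": int(sum(scenario.sim.diseases.values())),
        "gene_null_mu": float(gene_table.null.mu),
        "gene_null_sigma": float(gene_table.null.sigma),
        "specific_gene_calls": int(gene_table.table["specific"].sum()),
        "specific_tf_calls": int(tf_table.table["specific"].sum()),
        "specific_edge_calls": int(edge_table.table["specific"].sum()),
        "planted_gene_sensitivity": round(sensitivity, 4),
        "planted_gene_fdp": round(fdp, 4),
        "n_clusters": len(assign.clusters()),
        "panda_converged": all(net.converged for net in networks),
        "expression_battery_tests": len(expr_records),
        "expression_battery_significant": len(expr_sig),
        "regulation_battery_tests": len(reg_records),
        "regulation_battery_significant": len(reg_sig),
        "tf_pathway_cluster_recovered": bool(recovered),
        "expr_pathway_single_recovered": bool(expr_single_hit),
        "expr_pathway_pair_recovered": bool(expr_pair_hit),
    }

    if outdir is not None:
        io.ensure_dir(outdir)
        io.write_expression_table(cohort, f"{outdir}/expression.tsv", f"{outdir}/labels.tsv")
        io.write_score_table(gene_table, f"{outdir}/scores_genes.tsv")
        io.write_score_table(tf_table, f"{outdir}/scores_tfs.tsv")
        io.write_score_table(edge_table, f"{outdir}/scores_edges.tsv")
        dist.to_csv(f"{outdir}/disease_distances.tsv", sep="\t")
        pd.DataFrame(dend.merges, columns=["left", "right", "height"]).to_csv(
            f"{outdir}/dendrogram.tsv", sep="\t", index=False
        )
        pd.Series(assign.assignment, name="cluster").to_csv(
            f"{outdir}/clusters.tsv", sep="\t", index_label="disease"
        )
        for net in networks:
            io.write_network(net, f"{outdir}/network_{net.disease}.tsv")
        io.write_enrichment_records(expr_records, f"{outdir}/gsea_expression.tsv")
        io.write_enrichment_records(reg_records, f"{outdir}/gsea_regulation.tsv")
        groups_to_frame(gene_groups).to_csv(f"{outdir}/signature_genes.tsv", sep="\t", index=False)
        groups_to_frame(pathway_groups).to_csv(f"{outdir}/signature_pathways.tsv", sep="\t", index=False)
        groups_to_frame(tf_clusters).to_csv(f"{outdir}/signature_tf_pathways.tsv", sep="\t", index=False)
    return summary
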