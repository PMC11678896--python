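"""Intersection-based signatures: shared genes, pathways, and TF-pathway clusters.

Groups diseases by identical specificity-flag patterns (shared
over-expressed genes), by identical sets of significantly enriched pathways
(annotated with common driving-gene counts), and by shared (pathway, TF)
regulation enrichments that retain at least one common driving gene.
"""

import argparse

from hemnet import io
from hemnet.config import PipelineConfig
from hemnet.signatures import (
    groups_to_frame,
    shared_overexpression_groups,
    shared_pathway_groups,
    tf_pathway_intersection_clusters,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    cfg = PipelineConfig()

    gene_table = io.read_score_table(f"{args.outdir}/scores_genes.tsv")
    gene_groups = shared_overexpression_groups(gene_table)
    groups_to_frame(gene_groups).to_csv(f"{args.outdir}/signature_genes.tsv", sep="\t", index=False)
    multi = [g for g in gene_groups if len(g.diseases) >= 2]
    print(f"gene signatures: {len(gene_groups)} disease sets, {len(multi)} multi-disease")
    for g in multi:
        print(f"  {sorted(g.diseases)}: {sorted(g.shared_items)}")

    expr = [
        r for r in io.read_enrichment_records(f"{args.outdir}/gsea_expression.tsv")
        if r.p_adjusted < cfg.p_pathway_expr
    ]
    pathway_groups = shared_pathway_groups(expr)
    groups_to_frame(pathway_groups).to_csv(f"{args.outdir}/signature_pathways.tsv", sep="\t", index=False)
    print(f"pathway signatures: {len(pathway_groups)} disease sets")
    for g in pathway_groups:
        items = ", ".join(f"{p} ({n})" for p, n in sorted(g.shared_items.items()))
        print(f"  {sorted(g.diseases)}: {items}")

    reg = [
        r for r in io.read_enrichment_records(f"{args.outdir}/gsea_regulation.tsv")
        if r.p_adjusted < cfg.p_pathway_reg
    ]
    clusters = tf_pathway_intersection_clusters(reg)
    groups_to_frame(clusters).to_csv(f"{args.outdir}/signature_tf_pathways.tsv", sep="\t", index=False)
    print(f"TF-pathway clusters (same pathway + same TF + common driving genes): {len(clusters)}")
    for g in clusters:
        for pathway, tf, common in g.shared_items:
            print(f"  {len(g.diseases)} diseases: {tf} -> {pathway}, {len(common)} common driving genes")


if __name__ == "__main__":
    main()
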