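"""Per-disease co-expression and PANDA regulatory-network inference.

For each disease: a gene-gene Pearson co-expression matrix over its
subjects, integrated with the shared motif and TF-TF priors by PANDA
message passing into a bipartite TF x gene network.  Edge-specificity
scores across the disease networks follow, plus disease clustering on the
edge-score vectors.
"""

import argparse

import pandas as pd

from hemnet import io
from hemnet.clustering import cluster_diseases
from hemnet.config import PipelineConfig
from hemnet.panda import infer_disease_networks
from hemnet.specificity import score_networks


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    cfg = PipelineConfig()

    cohort = io.read_expression_table(f"{args.outdir}/expression.tsv", f"{args.outdir}/labels.tsv")
    cohort.tf_ids = io.read_tf_list(f"{args.outdir}/tfs.txt")
    motif = io.read_prior_matrix(f"{args.outdir}/motif_prior.tsv")
    ppi = io.read_prior_matrix(f"{args.outdir}/ppi_prior.tsv")

    nets = infer_disease_networks(cohort, motif, ppi, cfg.panda())
    for net in nets:
        io.write_network(net, f"{args.outdir}/network_{net.disease}.tsv")
    iters = [net.n_iterations for net in nets]
    print(f"PANDA: {len(nets)} networks, all converged={all(n.converged for n in nets)}, "
          f"iterations {min(iters)}-{max(iters)}")

    edge_table = score_networks(nets, cfg)
    io.write_score_table(edge_table, f"{args.outdir}/scores_edges.tsv")
    n_spec = int(edge_table.table["specific"].sum())
    n_edges = len(edge_table.features)
    print(f"edges: null sigma={edge_table.null.sigma:.4f}; "
          f"{n_spec} disease-specific regulations of {n_edges} edges x {len(nets)} diseases")

    dist, dend, assign = cluster_diseases(edge_table, cfg.min_cluster_size, cfg.prune_gap_fraction)
    pd.Series(assign.assignment, name="cluster").to_csv(
        f"{args.outdir}/clusters_edges.tsv", sep="\t", index_label="disease"
    )
    print(f"edge-score clustering: {len(assign.clusters())} clusters")


if __name__ == "__main__":
    main()
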