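"""Hierarchical clustering of diseases on specificity-score vectors.

Builds the Euclidean distance matrix over gene-level (and TF-level) score
vectors, agglomerates with complete linkage, and cuts the dendrogram with
adaptive branch pruning; singleton clusters mark diseases with no close
transcriptional neighbour.
"""

import argparse

import pandas as pd

from hemnet import io
from hemnet.clustering import cluster_diseases
from hemnet.config import PipelineConfig


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    cfg = PipelineConfig()

    for what in ("genes", "tfs"):
        table = io.read_score_table(f"{args.outdir}/scores_{what}.tsv")
        dist, dend, assign = cluster_diseases(table, cfg.min_cluster_size, cfg.prune_gap_fraction)
        dist.to_csv(f"{args.outdir}/distances_{what}.tsv", sep="\t")
        pd.DataFrame(dend.merges, columns=["left", "right", "height"]).to_csv(
            f"{args.outdir}/dendrogram_{what}.tsv", sep="\t", index=False
        )
        pd.Series(assign.assignment, name="cluster").to_csv(
            f"{args.outdir}/clusters_{what}.tsv", sep="\t", index_label="disease"
        )
        clusters = assign.clusters()
        multi = {k: sorted(v) for k, v in clusters.items() if len(v) > 1}
        singletons = sorted(d for k, v in clusters.items() if len(v) == 1 for d in v)
        print(f"{what}: {len(clusters)} clusters; multi-member {list(multi.values())}; "
              f"singletons {singletons}")


if __name__ == "__main__":
    main()
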