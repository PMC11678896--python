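"""The two GSEA batteries: median expression and TF-gene regulation weights.

Expression battery: one preranked test per (disease, pathway) on the
disease's median-expression ranking, BH-corrected jointly, adjusted
p < 0.01.  It runs at 20000 permutations so the plus-one estimator can
resolve the 0.01 threshold after BH (the floor 1/(n_perm+1) x m/k must sit
below it).  Regulation battery: one test per (disease, TF, pathway) on the
TF's weight ranking, adjusted p < 0.05; its permutation count is likewise set so the floor clears 0.05
after BH over the tests actually run.  The regulation battery here is
restricted to the planted TF plus a small reference panel to keep the
driver quick; the full per-TF sweep is the same loop over all TFs.
"""

import argparse
from dataclasses import replace

from hemnet import io
from hemnet.config import PipelineConfig
from hemnet.gsea import battery_size, run_battery


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-ref-tfs", type=int, default=3)
    args = ap.parse_args()
    cfg = replace(PipelineConfig(), seed=args.seed, permutations_expr=20000, permutations_reg=4000)

    cohort = io.read_expression_table(f"{args.outdir}/expression.tsv", f"{args.outdir}/labels.tsv")
    cohort.tf_ids = io.read_tf_list(f"{args.outdir}/tfs.txt")
    pathways = io.read_gmt(f"{args.outdir}/pathways.gmt")

    expr = run_battery("expression", pathways, cohort=cohort, cfg=cfg, significant_only=False)
    io.write_enrichment_records(expr, f"{args.outdir}/gsea_expression.tsv")
    expr_sig = [r for r in expr if r.p_adjusted < cfg.p_pathway_expr]
    print(f"expression battery: {len(expr)} tests "
          f"(full-scale analogue: {battery_size(186, 13)}), {len(expr_sig)} significant at adj p<0.01")
    for r in expr_sig:
        print(f"  {r.disease}  {r.pathway}  ES={r.es:+.3f}  adj_p={r.p_adjusted:.4f}  "
              f"{r.driving_gene_count} driving genes")

    nets = [io.read_network(f"{args.outdir}/network_D{i:02d}.tsv") for i in range(1, 14)]
    tfs = sorted({*cohort.tf_ids[: args.n_ref_tfs], "g0001"})
    reg = run_battery("regulation", pathways, networks=nets, cfg=cfg, significant_only=False, tfs=tfs)
    io.write_enrichment_records(reg, f"{args.outdir}/gsea_regulation.tsv")
    reg_sig = [r for r in reg if r.p_adjusted < cfg.p_pathway_reg]
    print(f"regulation battery: {len(reg)} tests over {len(tfs)} TFs "
          f"(full-scale analogue: {battery_size(186, 13, 609)}), {len(reg_sig)} significant at adj p<0.05")
    pairs = sorted({(r.tf, r.pathway) for r in reg_sig})
    for tf, pathway in pairs:
        diseases = sorted(r.disease for r in reg_sig if r.tf == tf and r.pathway == pathway)
        print(f"  {tf} -> {pathway} in {len(diseases)} diseases")


if __name__ == "__main__":
    main()
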