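# hemnet

Disease-specificity and regulatory-network analysis for multi-disease
transcriptomic cohorts — the kind of pan-cancer design where one expression
matrix spans a dozen related malignancies and the questions are: which
genes and transcription factors (TFs) are over-expressed in exactly one
disease, which are shared by groups of diseases, how do diseases cluster
on those profiles, and which TF→gene regulations and pathways carry the
differences?

The pipeline, end to end:

1. **Specificity scores** — for each feature *j* and disease *d*,
   `s_j^d = (med(e_j^d) − med(e_j)) / IQR(e_j)`; an empirical Gaussian
   null over the pooled scores gives one-sided p-values, BH-adjusted;
   features with `score > 2` and `p_adj < 0.01` are called
   disease-specific, and a feature's *multiplicity* counts the diseases
   that claim it.
2. **Disease clustering** — Euclidean distances between score vectors,
   complete-linkage dendrogram, adaptive branch pruning (singleton
   clusters allowed).
3. **Regulatory networks** — per-disease gene–gene Pearson co-expression
   integrated with a TF×gene motif prior and a TF×TF cooperativity prior
   by PANDA-style Tanimoto message passing; one bipartite TF×gene network
   per disease. The same specificity score applied to edge weights yields
   disease-specific regulations.
4. **GSEA batteries** — preranked weighted-KS enrichment with
   permutation p-values and leading-edge ("driving gene") extraction: per
   (disease, pathway) on median expression (jointly BH-corrected,
   `p_adj < 0.01`) and per (disease, TF, pathway) on regulation weights
   (`p_adj < 0.05`).
5. **Intersection signatures** — groups of diseases bound by identical
   sets of over-expressed genes, identical enriched pathways (with common
   driving-gene counts), or shared (pathway, TF) regulation enrichments
   with at least one common driving gene.

Real cohorts plug in as TSV matrices; everything is also runnable on the
package's synthetic cohorts, which plant known specific genes,
co-expression blocks and TF→target couplings so each stage's recovery can
be verified. See `docs/methods.md` for the statistical details.

## Worked example

The numbered drivers under `analysis/` run the whole study on a planted
synthetic cohort (13 diseases × 40 subjects, 500 genes, 50 TFs):

```sh
python analysis/01_simulate.py --seed 1 --outdir results
python analysis/02_specificity.py --outdir results
python analysis/03_cluster_diseases.py --outdir results
python analysis/04_infer_networks.py --outdir results
python analysis/05_gsea_batteries.py --outdir results --seed 1
python analysis/06_signatures.py --outdir results
```

Output at seed 1 (abridged):

```
planted: 69 specific (gene, disease) pairs at delta=3 pooled-IQR units
genes: null mu=+0.0189 sigma=0.2907; 67 specific calls; 15 features with multiplicity >= 2
planted recovery: sensitivity=0.971, false-discovery proportion=0.000
genes: 3 clusters; multi-member [['D06', 'D07'], ['D01', ..., 'D13']]; singletons ['D05']
PANDA: 13 networks, all converged=True, iterations 14-14
edges: null sigma=0.9227; 482 disease-specific regulations of 25000 edges x 13 diseases
expression battery: 299 tests (full-scale analogue: 2418), 3 significant at adj p<0.01
  D05  PLANTED_EXPR_SINGLE  ES=+0.830  adj_p=0.0050  14 driving genes
  D06  PLANTED_EXPR_PAIR    ES=+0.698  adj_p=0.0050  11 driving genes
  D07  PLANTED_EXPR_PAIR    ES=+0.766  adj_p=0.0050  12 driving genes
gene signatures: ['D01', 'D02']: ['g0300', 'g0301'] ...
TF-pathway clusters (same pathway + same TF + common driving genes): 1
  13 diseases: g0001 -> PLANTED_TFPATH, 15 common driving genes
```

Reading this: the 69 planted over-expression shifts (3 pooled-IQR units)
are recovered with 97% sensitivity and no false calls; the two diseases
sharing a planted gene pair (D01, D02) and the planted pathway shifts
(D05 alone; D06 with D07) come back as exactly those signature groups;
and the planted TF→target block is recovered as a TF–pathway cluster with
its full 15-gene common driving set — enriched in all 13 networks because
the motif prior, as in any shared-prior design, carries the edges into
every disease and only co-expression varies between them.

The same stages are exposed as a CLI (`hemnet simulate|score|cluster|
coexpress|panda|score-edges|gsea-expr|gsea-reg|signatures|run-all`) for
use on external TSV/GMT inputs.

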