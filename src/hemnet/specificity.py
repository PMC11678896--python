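"""Disease-specificity scores with an empirical Gaussian null.

The score of feature j in disease ``dis`` is

    s_j^dis = (med(e_j^dis) - med(e_j)) / IQR(e_j)

i.e. how far the disease median sits above the pooled median, in units of
the feature's pooled interquartile range.  The same statistic applies to
gene expression (observations = subjects), TF expression (the TF subset of
genes), and network regulations (observations = the per-disease edge
weights, one per disease, so the disease "median" is that single value).

Because the vast majority of features are not disease-specific, the pooled
score distribution is approximately Gaussian around zero; p-values are
one-sided upper-tail probabilities under a moment-fitted Gaussian, corrected
by Benjamini-Hochberg, and a feature is called specific in a disease when
its score exceeds ``score_threshold`` (default 2) with adjusted p below
``p_gene`` (default 0.01).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .datamodel import (
    ExpressionCohort,
    NullModel,
    RegulatoryNetwork,
    ScoreTable,
    edge_id,
)

# Quantile convention for Q1/Q3: linear interpolation between order
# statistics (numpy's default), fixed for reproducibility.
_QUANTILE_METHOD = "linear"


def compute_scores(
    features: pd.DataFrame,
    grouping: Mapping[str, str] | pd.Series,
) -> ScoreTable:
    """Score every (feature, disease) pair.

    ``features`` is a feature x observation matrix; ``grouping`` maps each
    observation (column) to its disease.  Features whose pooled IQR is zero
    get NaN scores (flagged undefined, excluded downstream).
    """
    if features.shape[0] == 0:
        raise ValueError("empty feature matrix")
    grouping = pd.Series(grouping)
    grouping = grouping.reindex(features.columns)
    if grouping.isna().any():
        missing = features.columns[grouping.isna()][0]
        raise ValueError(f"observation {missing!r} has no disease label")
    diseases = list(dict.fromkeys(grouping))
    if len(diseases) < 2:
        raise ValueError("need at least 2 diseases to score specificity")

    x = features.to_numpy(dtype=float)
    pooled_med = np.median(x, axis=1)
    q1, q3 = np.quantile(x, [0.25, 0.75], axis=1, method=_QUANTILE_METHOD)
    iqr = q3 - q1
    defined = iqr > 0

    frames = []
    for dis in diseases:
        cols = (grouping == dis).to_numpy()
        dis_med = np.median(x[:, cols], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(defined, (dis_med - pooled_med) / np.where(defined, iqr, 1.0), np.nan)
        frames.append(
            pd.DataFrame(
                {"feature": features.index, "disease": dis, "score": score}
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return ScoreTable(table=table)


def fit_empirical_null(scores: Sequence[float] | np.ndarray) -> NullModel:
    """Moment-fit a Gaussian to the pooled defined scores."""
    arr = np.asarray(scores, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 30:
        raise ValueError(f"need >= 30 defined scores to fit a null, got {arr.size}")
    sigma = float(arr.std(ddof=1))
    if sigma == 0:
        raise ValueError("pooled scores are constant; null scale undefined")
    return NullModel(mu=float(arr.mean()), sigma=sigma, n_scores=int(arr.size))


def score_pvalues(table: ScoreTable, null: NullModel | None = None) -> ScoreTable:
    """Attach one-sided upper-tail p-values: p = 1 - Phi((s - mu) / sigma).

    Over-expression is the direction of interest, so only large positive
    scores earn small p-values.  Undefined (NaN) scores get no p-value.
    """
    if null is None:
        null = fit_empirical_null(table.table["score"].to_numpy())
    s = table.table["score"].to_numpy()
    p = np.full_like(s, np.nan)
    ok = np.isfinite(s)
    p[ok] = stats.norm.sf((s[ok] - null.mu) / null.sigma)
    out = table.table.copy()
    out["p_value"] = p
    return ScoreTable(table=out, null=null)


def benjamini_hochberg(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs pass through and do not count as tests."""
    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full_like(p, np.nan)
    if ok.sum():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return adj


def adjust_pvalues(table: ScoreTable) -> ScoreTable:
    out = table.table.copy()
    out["p_adjusted"] = benjamini_hochberg(out["p_value"].to_numpy())
    return ScoreTable(table=out, null=table.null)


def call_specific(table: ScoreTable, cfg: PipelineConfig | None = None) -> ScoreTable:
    """Flag (feature, disease) pairs: score > threshold AND p < p_gene.

    Uses adjusted p-values by default (``cfg.use_adjusted_p``); the raw-p
    variant is available as a documented switch.
    """
    cfg = cfg or PipelineConfig()
    out = table.table.copy()
    pcol = "p_adjusted" if cfg.use_adjusted_p else "p_value"
    if pcol not in out:
        raise ValueError(f"column {pcol!r} not computed yet")
    s = out["score"].to_numpy()
    p = out[pcol].to_numpy()
    out["specific"] = np.isfinite(s) & np.isfinite(p) & (s > cfg.score_threshold) & (p < cfg.p_gene)
    return ScoreTable(table=out, null=table.null)


def compute_multiplicity(table: ScoreTable) -> pd.Series:
    """Per feature, the number of diseases in which it is called specific."""
    return table.multiplicity()


def score_cohort(
    cohort: ExpressionCohort,
    cfg: PipelineConfig | None = None,
    what: str = "genes",
) -> ScoreTable:
    """Full specificity pass over a cohort: scores, null, p, BH, calls.

    ``what`` selects the feature class — "genes" scores all measured genes,
    "tfs" restricts to the designated TF subset.  The null is fitted
    separately per feature class, matching the per-class pooled-score
    distributions.
    """
    if what == "tfs":
        cohort = cohort.tf_view()
    elif what != "genes":
        raise ValueError(f"what must be 'genes' or 'tfs', got {what!r}")
    table = compute_scores(cohort.values, cohort.disease_of)
    table = score_pvalues(table)
    table = adjust_pvalues(table)
    return call_specific(table, cfg)


def score_networks(
    networks: Sequence[RegulatoryNetwork],
    cfg: PipelineConfig | None = None,
) -> ScoreTable:
    """Edge-specificity pass: each disease contributes one observation per edge.

    Edge features are serialized "tf→gene"; the disease median reduces to
    that network's single edge weight.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 disease networks to score edges")
    ref = networks[0]
    cols = {}
    for net in networks:
        if net.tf_ids != ref.tf_ids or net.gene_ids != ref.gene_ids:
            raise ValueError("networks must share identical TF and gene id order")
        cols[net.disease] = net.weights.to_numpy().ravel()
    feats = [edge_id(tf, g) for tf in ref.tf_ids for g in ref.gene_ids]
    matrix = pd.DataFrame(cols, index=feats)
    grouping = pd.Series({d: d for d in matrix.columns})
    table = compute_scores(matrix, grouping)
    table = score_pvalues(table)
    table = adjust_pvalues(table)
    return call_specific(table, cfg)
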