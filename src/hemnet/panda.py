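"""PANDA-style message passing for bipartite TF-gene network inference.

PANDA integrates three sources of evidence — a TF x gene motif prior
(putative binding targets), a TF x TF cooperativity prior, and a gene x gene
co-expression network — by iteratively nudging the regulatory network W
toward agreement between a TF's regulatory profile and its targets'
co-expression.  Agreement is measured with a continuous Tanimoto
similarity; each round updates W with the mean of a "responsibility"
message (from TF cooperativity) and an "availability" message (from gene
co-expression), then refreshes the two priors toward the evolving network.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PandaConfig
from .datamodel import ExpressionCohort, RegulatoryNetwork

log = logging.getLogger(__name__)


def pearson_coexpression(cohort: ExpressionCohort, disease: str) -> pd.DataFrame:
    """Gene x gene Pearson correlation over one disease's subjects.

    Zero-variance genes get 0 off-diagonal correlation (logged) and keep the
    unit diagonal, so the matrix stays a valid weighted adjacency.
    """
    subjects = cohort.subjects_of(disease)
    if len(subjects) < 3:
        raise ValueError(f"disease {disease!r} has {len(subjects)} subjects; need >= 3")
    x = cohort.values[subjects].to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        log.warning("disease %s: %d zero-variance gene(s); correlations set to 0", disease, flat.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c = np.where(np.isfinite(c), c, 0.0)
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=cohort.gene_ids, columns=cohort.gene_ids)


def normalize_matrix(x: np.ndarray) -> np.ndarray:
    """Two-pass z-score: X' = (Zrow + Zcol) / sqrt(2).

    Rows (columns) with zero variance fall back to the overall matrix
    z-score for that component, keeping every entry finite.
    """
    x = np.asarray(x, dtype=float)
    overall_sd = x.std(ddof=1) if x.size > 1 else 0.0
    if overall_sd == 0:
        raise ValueError("cannot normalize a constant matrix")
    overall_z = (x - x.mean()) / overall_sd

    def _z(axis: int) -> np.ndarray:
        mean = x.mean(axis=axis, keepdims=True)
        sd = x.std(axis=axis, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (x - mean) / sd
        bad = np.broadcast_to(~(sd > 0), x.shape)
        return np.where(bad, overall_z, z)

    z_col = _z(axis=0)  # z-score down each column
    z_row = _z(axis=1)  # z-score along each row
    return (z_row + z_col) / np.sqrt(2.0)


def tanimoto_product(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Continuous Tanimoto similarity between rows of X and columns of Y.

    T_ij = (XY)_ij / sqrt(|X_i.|^2 + |Y._j|^2 - |(XY)_ij|); a zero
    denominator yields 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    prod = x @ y
    xnorm = (x**2).sum(axis=1)[:, None]
    ynorm = (y**2).sum(axis=0)[None, :]
    denom_sq = xnorm + ynorm - np.abs(prod)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = prod / np.sqrt(denom_sq)
    return np.where(denom_sq > 0, t, 0.0)


def _update_diagonal(m: np.ndarray, alpha: float, t: int) -> None:
    """Replace diag(m) by (off-diagonal row std) x dim x exp(2 alpha t)."""
    n = m.shape[0]
    mask = ~np.eye(n, dtype=bool)
    off = m[mask].reshape(n, n - 1)
    row_sd = off.std(axis=1, ddof=1 if n > 2 else 0)  # ddof=1 needs >= 2 off-diagonal entries
    np.fill_diagonal(m, row_sd * n * np.exp(2.0 * alpha * t))


def panda_infer(
    motif: pd.DataFrame,
    ppi: pd.DataFrame,
    coexpr: pd.DataFrame,
    cfg: PandaConfig | None = None,
    disease: str = "",
) -> RegulatoryNetwork:
    """Run the message-passing loop; returns the final TF x gene weights.

    Each iteration computes responsibility R = Tanimoto(P, W) and
    availability A = Tanimoto(W, C), moves W by a step of size alpha toward
    (R + A)/2, then refreshes P and C toward the Tanimoto self-agreement of
    W (with the diagonal replaced by its off-diagonal row spread, amplified
    as exp(2 alpha t), so self-similarity never dominates).  Stops when the
    mean absolute change of W drops below the tolerance; non-convergence at
    max_iterations is recorded in the result, which is still returned.
    """
    cfg = cfg or PandaConfig()
    tf_ids, gene_ids = list(motif.index), list(motif.columns)
    if list(ppi.index) != tf_ids or list(ppi.columns) != tf_ids:
        raise ValueError("ppi prior ids must match motif TF ids")
    if list(coexpr.index) != gene_ids or list(coexpr.columns) != gene_ids:
        raise ValueError("co-expression ids must match motif gene ids")

    w = normalize_matrix(motif.to_numpy())
    p = normalize_matrix(ppi.to_numpy())
    c = normalize_matrix(coexpr.to_numpy())

    alpha = cfg.alpha
    converged = False
    t = 0
    for t in range(1, cfg.max_iterations + 1):
        r = tanimoto_product(p, w)
        a = tanimoto_product(w, c)
        w_new = (1.0 - alpha) * w + alpha * (r + a) / 2.0
        delta = float(np.abs(w_new - w).mean())
        w = w_new

        p = (1.0 - alpha) * p + alpha * tanimoto_product(w, w.T)
        _update_diagonal(p, alpha, t)
        c = (1.0 - alpha) * c + alpha * tanimoto_product(w.T, w)
        _update_diagonal(c, alpha, t)

        if delta < cfg.tolerance:
            converged = True
            break
    if not converged:
        log.warning("PANDA did not converge in %d iterations (disease=%s)", cfg.max_iterations, disease)

    return RegulatoryNetwork(
        weights=pd.DataFrame(w, index=tf_ids, columns=gene_ids),
        disease=disease,
        converged=converged,
        n_iterations=t,
        config={
            "alpha": cfg.alpha,
            "tolerance": cfg.tolerance,
            "max_iterations": cfg.max_iterations,
        },
    )


def infer_disease_networks(
    cohort: ExpressionCohort,
    motif: pd.DataFrame,
    ppi: pd.DataFrame,
    cfg: PandaConfig | None = None,
) -> list[RegulatoryNetwork]:
    """One network per disease: shared priors, disease-specific co-expression."""
    nets = []
    for disease in cohort.diseases:
        coexpr = pearson_coexpression(cohort, disease)
        nets.append(panda_infer(motif, ppi, coexpr, cfg, disease=disease))
    return nets
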