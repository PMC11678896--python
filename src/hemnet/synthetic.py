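"""Synthetic multi-disease cohorts with planted ground truth.

The generator emulates the statistical shape the downstream analysis
assumes: a genes x subjects matrix of log2-scale intensities with per-gene
baseline medians and dispersions, block-structured co-expression driven by
latent factors, and disease-specific over-expression shifts planted in units
of each gene's *realized* pooled IQR — so a planted shift of delta maps
directly onto the specificity-score threshold.  Sparse motif and TF-TF
priors with planted true regulations complete the inputs for network
inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ExpressionCohort

DEFAULT_DISEASES = {f"D{i:02d}": 40 for i in range(1, 14)}


@dataclass
class SimConfig:
    """Cohort-shape and effect-size parameters, all in log2 units.

    Defaults are desk-scale: 13 diseases x 40 subjects, 500 genes of which
    the first 50 are the designated TFs.
    """

    n_genes: int = 500
    n_tfs: int = 50
    diseases: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DISEASES))
    baseline_median_location: float = 7.0
    baseline_median_scale: float = 2.0
    gene_dispersion_range: tuple[float, float] = (0.3, 1.2)
    n_latent_factors: int = 0
    loading_scale: float = 0.0
    planted_specifics: list[tuple[str, str, float]] = field(default_factory=list)
    motif_density: float = 0.05
    ppi_density: float = 0.1
    planted_regulations: list[tuple[str, str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs must not exceed n_genes")
        if not 0 <= self.motif_density <= 1 or not 0 <= self.ppi_density <= 1:
            raise ValueError("prior densities must lie in [0, 1]")
        for d, n in self.diseases.items():
            if n < 3:
                raise ValueError(f"disease {d!r} needs >= 3 subjects, got {n}")
        for g, d, delta in self.planted_specifics:
            if delta <= 0:
                raise ValueError(f"planted delta must be > 0, got {delta} for ({g}, {d})")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    @property
    def tf_ids(self) -> list[str]:
        # TFs are the first n_tfs gene ids: a designated subset of measured genes
        return self.gene_ids[: self.n_tfs]


@dataclass
class GroundTruth:
    true_specific_genes: set[tuple[str, str]]
    true_specific_edges: set[tuple[str, str, str]]
    true_coexpression_blocks: dict[str, int]


def _check_planted(cfg: SimConfig) -> None:
    genes, tfs = set(cfg.gene_ids), set(cfg.tf_ids)
    diseases = set(cfg.diseases)
    for g, d, _ in cfg.planted_specifics:
        if g not in genes:
            raise ValueError(f"planted gene {g!r} not in simulated genes")
        if d not in diseases:
            raise ValueError(f"planted disease {d!r} not in config")
    for tf, g, d, _ in cfg.planted_regulations:
        if tf not in tfs:
            raise ValueError(f"planted regulation TF {tf!r} not a simulated TF")
        if g not in genes:
            raise ValueError(f"planted regulation gene {g!r} not simulated")
        if d not in diseases:
            raise ValueError(f"planted regulation disease {d!r} not in config")


def generate_cohort(cfg: SimConfig) -> tuple[ExpressionCohort, GroundTruth]:
    """Draw a cohort: e[g,s] = m_g + sum_f L[g,f] z[f,s] + eps, then plant shifts.

    Latent factors create block co-expression: each gene loads on exactly one
    factor (blocks of contiguous genes), with positive loadings of magnitude
    ~ loading_scale, so within-block Pearson correlations are positive.
    Planted (gene, disease, delta) shifts add delta x (pooled IQR of the
    gene's row *before* shifting) to every subject of that disease.
    """
    _check_planted(cfg)
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_ids
    subjects, labels = [], []
    for d, n in cfg.diseases.items():
        subjects += [f"{d}_s{i:03d}" for i in range(n)]
        labels += [d] * n
    n_sub = len(subjects)

    medians = rng.normal(cfg.baseline_median_location, cfg.baseline_median_scale, cfg.n_genes)
    lo, hi = cfg.gene_dispersion_range
    sigma = rng.uniform(lo, hi, cfg.n_genes)
    values = medians[:, None] + rng.normal(0.0, 1.0, (cfg.n_genes, n_sub)) * sigma[:, None]

    blocks = {g: -1 for g in genes}
    if cfg.n_latent_factors > 0 and cfg.loading_scale > 0:
        z = rng.normal(0.0, 1.0, (cfg.n_latent_factors, n_sub))
        block_of = np.arange(cfg.n_genes) % cfg.n_latent_factors
        loadings = cfg.loading_scale * rng.uniform(0.5, 1.5, cfg.n_genes)
        values += loadings[:, None] * z[block_of, :]
        blocks = {g: int(b) for g, b in zip(genes, block_of)}

    gene_pos = {g: i for i, g in enumerate(genes)}
    label_arr = np.asarray(labels)
    # Planted regulations couple the target to its TF within one disease:
    # the target inherits strength x (standardized TF profile) x its own sigma,
    # so the TF-target Pearson correlation is elevated in that disease only.
    for tf, g, d, strength in cfg.planted_regulations:
        mask = label_arr == d
        t = values[gene_pos[tf], mask]
        t_sd = t.std()
        if t_sd > 0:
            values[gene_pos[g], mask] += strength * sigma[gene_pos[g]] * (t - t.mean()) / t_sd

    for g, d, delta in cfg.planted_specifics:
        row = gene_pos[g]
        q1, q3 = np.quantile(values[row], [0.25, 0.75])
        values[row, label_arr == d] += delta * (q3 - q1)

    cohort = ExpressionCohort(
        values=pd.DataFrame(values, index=genes, columns=subjects),
        disease_of=pd.Series(labels, index=subjects, name="disease"),
        tf_ids=cfg.tf_ids,
    )
    truth = GroundTruth(
        true_specific_genes={(g, d) for g, d, _ in cfg.planted_specifics},
        true_specific_edges={(tf, g, d) for tf, g, d, _ in cfg.planted_regulations},
        true_coexpression_blocks=blocks,
    )
    return cohort, truth


def generate_motif_prior(cfg: SimConfig) -> pd.DataFrame:
    """Bernoulli(motif_density) TF x gene 0/1 prior; planted regulations forced to 1."""
    _check_planted(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    motif = (rng.random((cfg.n_tfs, cfg.n_genes)) < cfg.motif_density).astype(float)
    prior = pd.DataFrame(motif, index=cfg.tf_ids, columns=cfg.gene_ids)
    for tf, g, _, _ in cfg.planted_regulations:
        prior.loc[tf, g] = 1.0
    return prior


def generate_gene_sets(
    gene_ids: list[str],
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 30),
    seed: int = 0,
    planted: dict[str, set[str]] | None = None,
) -> "GeneSetCollection":
    """Random gene sets (a synthetic pathway battery), plus optional planted sets.

    Random sets are drawn uniformly without replacement from ``gene_ids``;
    planted sets are inserted verbatim (e.g. a co-regulated target block
    whose enrichment downstream stages should recover).
    """
    from .datamodel import GeneSetCollection

    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    lo, hi = set_size_range
    sets: dict[str, set[str]] = {}
    for name, members in (planted or {}).items():
        sets[name] = set(members)
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(gene_ids, size=size, replace=False)
        sets[f"P{i:03d}"] = set(members)
    return GeneSetCollection(sets=sets, descriptions={n: "synthetic" for n in sets})


def generate_ppi_prior(cfg: SimConfig) -> pd.DataFrame:
    """Symmetric unit-diagonal TF x TF cooperativity prior."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    upper = (rng.random((cfg.n_tfs, cfg.n_tfs)) < cfg.ppi_density).astype(float)
    ppi = np.triu(upper, k=1)
    ppi = ppi + ppi.T
    np.fill_diagonal(ppi, 1.0)
    return pd.DataFrame(ppi, index=cfg.tf_ids, columns=cfg.tf_ids)
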