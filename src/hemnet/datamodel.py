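"""Domain containers shared by every pipeline stage.

The pipeline operates on a multi-disease expression cohort (genes x subjects,
log2 intensities) with a designated transcription-factor subset, and produces
per-disease specificity score tables, bipartite TF-gene regulatory networks,
gene-set enrichment records and intersection-based disease signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EDGE_SEP = "→"  # "tf→gene" edge identifiers


def edge_id(tf: str, gene: str) -> str:
    """Serialize a (tf, gene) regulation as a single feature identifier."""
    return f"{tf}{EDGE_SEP}{gene}"


def split_edge_id(feature: str) -> tuple[str, str]:
    tf, _, gene = feature.partition(EDGE_SEP)
    if not gene:
        raise ValueError(f"not an edge identifier: {feature!r}")
    return tf, gene


@dataclass
class ExpressionCohort:
    """Log2 expression matrix with a subject -> disease partition.

    ``values`` is a genes x subjects DataFrame; ``disease_of`` maps every
    subject (column) to exactly one disease label; ``tf_ids`` designates the
    subset of measured genes treated as transcription factors.
    """

    values: pd.DataFrame
    disease_of: pd.Series
    tf_ids: list[str]

    def __post_init__(self) -> None:
        genes = self.values.index
        subjects = self.values.columns
        if genes.has_duplicates:
            dup = genes[genes.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if subjects.has_duplicates:
            dup = subjects[subjects.duplicated()][0]
            raise ValueError(f"duplicate subject identifier: {dup!r}")
        missing = subjects.difference(self.disease_of.index)
        if len(missing):
            raise ValueError(f"subject missing a disease label: {missing[0]!r}")
        self.disease_of = self.disease_of.reindex(subjects)
        unknown_tfs = set(self.tf_ids) - set(genes)
        if unknown_tfs:
            raise ValueError(f"tf_ids not measured in cohort: {sorted(unknown_tfs)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def diseases(self) -> list[str]:
        """Disease labels in first-appearance order over subjects."""
        return list(dict.fromkeys(self.disease_of))

    def subjects_of(self, disease: str) -> list[str]:
        return list(self.disease_of.index[self.disease_of == disease])

    def tf_view(self) -> "ExpressionCohort":
        """Cohort restricted to the TF subset (TF-level analyses)."""
        return ExpressionCohort(
            values=self.values.loc[self.tf_ids],
            disease_of=self.disease_of,
            tf_ids=list(self.tf_ids),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), e.g. a KEGG pathway battery."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class NullModel:
    """Gaussian fit to the pooled specificity-score distribution."""

    mu: float
    sigma: float
    n_scores: int

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass
class ScoreTable:
    """Feature x disease specificity scores with calls.

    ``table`` is a long-format DataFrame with columns
    feature, disease, score, p_value, p_adjusted, specific.  Features with an
    undefined score (pooled IQR = 0) carry NaN score and are excluded from
    null fitting and calls.  ``multiplicity`` counts, per feature, the
    diseases in which it is called specific.
    """

    table: pd.DataFrame
    null: NullModel | None = None

    @property
    def features(self) -> list[str]:
        return list(dict.fromkeys(self.table["feature"]))

    @property
    def diseases(self) -> list[str]:
        return list(dict.fromkeys(self.table["disease"]))

    def score_matrix(self) -> pd.DataFrame:
        """Wide feature x disease score matrix."""
        return self.table.pivot(index="feature", columns="disease", values="score")

    def multiplicity(self) -> pd.Series:
        if "specific" not in self.table:
            raise ValueError("specific flags not computed yet")
        return self.table.groupby("feature", sort=False)["specific"].sum().astype(int)


@dataclass
class RegulatoryNetwork:
    """Bipartite weighted TF x gene network (message-passing output)."""

    weights: pd.DataFrame  # TF x gene
    disease: str
    converged: bool = True
    n_iterations: int = 0
    config: Mapping | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights.to_numpy()).all():
            raise ValueError("network weights must be finite")

    @property
    def tf_ids(self) -> list[str]:
        return list(self.weights.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.weights.columns)


@dataclass
class EnrichmentRecord:
    """One GSEA test: (disease[, tf], pathway) -> ES, p, leading edge."""

    disease: str
    pathway: str
    es: float
    p_value: float
    leading_edge: tuple[str, ...]
    tf: str | None = None
    p_adjusted: float = float("nan")

    @property
    def driving_gene_count(self) -> int:
        return len(self.leading_edge)


@dataclass
class Dendrogram:
    """Agglomerative merge history over disease leaves.

    ``merges`` lists (left, right, height) triples; node ids 0..D-1 are the
    leaves (in ``labels`` order), node D+k is the cluster created by merge k.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        d = len(self.labels)
        if len(self.merges) != d - 1:
            raise ValueError("a dendrogram over D leaves has exactly D-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be nondecreasing")

    def leaves_under(self, node: int) -> list[int]:
        d = len(self.labels)
        if node < d:
            return [node]
        left, right, _ = self.merges[node - d]
        return self.leaves_under(left) + self.leaves_under(right)


@dataclass
class ClusterAssignment:
    """disease -> cluster id; singleton clusters allowed."""

    assignment: dict[str, int]

    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for disease, cid in self.assignment.items():
            out.setdefault(cid, set()).add(disease)
        return out


@dataclass
class SignatureGroup:
    """A set of diseases bound by shared items.

    ``shared_items`` is one of: a set of gene ids; a mapping pathway -> common
    driving-gene count; or a list of (pathway, tf, common driving genes)
    triples (where the common set is non-empty by construction).
    """

    diseases: frozenset[str]
    shared_items: object
    annotations: dict[str, Sequence[str]] = field(default_factory=dict)
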