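"""Intersection-based disease signatures.

Three groupings, each keyed by EXACT disease sets: (i) diseases bound by
sharing the same over-expressed (specific) genes; (ii) diseases where the
same pathway is enriched at expression level, annotated with the count of
driving genes common to all members; (iii) diseases where the same
(pathway, TF) pair is significant in the regulation battery AND at least
one driving gene is common to every member — pairs with an empty common
driving-gene set are dropped, which strictly narrows the output and
improves interpretability.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .datamodel import EnrichmentRecord, ScoreTable, SignatureGroup


def shared_overexpression_groups(table: ScoreTable) -> list[SignatureGroup]:
    """Group diseases by identical specificity-flag patterns over genes.

    Every gene with multiplicity >= 2 nominates its exact disease set;
    groups collect all genes with that same set.  Multiplicity-1 genes are
    returned as per-disease singleton groups (the disease's specific list).
    """
    flagged = table.table[table.table["specific"].astype(bool)]
    patterns: dict[frozenset[str], set[str]] = {}
    for feature, sub in flagged.groupby("feature", sort=False):
        key = frozenset(sub["disease"])
        patterns.setdefault(key, set()).add(feature)
    return [
        SignatureGroup(diseases=diseases, shared_items=genes)
        for diseases, genes in sorted(patterns.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0])))
    ]


def shared_pathway_groups(records: Sequence[EnrichmentRecord]) -> list[SignatureGroup]:
    """Group diseases by identical sets of significant pathways.

    ``records`` must already be filtered to significant tests.  Each pathway
    nominates the exact set of diseases where it is significant; within a
    group every pathway is annotated with the number of driving genes common
    to all member diseases (the intersection of its leading edges).  A zero
    count is retained but distinguishable — it flags pathways whose
    enrichment is carried by disjoint genes in different diseases.
    """
    by_pathway: dict[str, list[EnrichmentRecord]] = {}
    for rec in records:
        by_pathway.setdefault(rec.pathway, []).append(rec)

    patterns: dict[frozenset[str], dict[str, int]] = {}
    for pathway, recs in by_pathway.items():
        diseases = frozenset(r.disease for r in recs)
        common: set[str] = set.intersection(*(set(r.leading_edge) for r in recs))
        patterns.setdefault(diseases, {})[pathway] = len(common)
    return [
        SignatureGroup(diseases=diseases, shared_items=pathways)
        for diseases, pathways in sorted(patterns.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0])))
    ]


def tf_pathway_intersection_clusters(
    records: Sequence[EnrichmentRecord],
) -> list[SignatureGroup]:
    """Clusters of diseases sharing (pathway, TF) enrichment with common drivers.

    For each (pathway, TF) significant in >= 1 disease, the member diseases
    form a cluster only when the intersection of their leading edges is
    non-empty; the shared item is the (pathway, tf, common driving genes)
    triple.  Clusters with the same disease set are merged.
    """
    by_pair: dict[tuple[str, str], list[EnrichmentRecord]] = {}
    for rec in records:
        if rec.tf is None:
            raise ValueError("regulation-battery records require a TF")
        by_pair.setdefault((rec.pathway, rec.tf), []).append(rec)

    patterns: dict[frozenset[str], list[tuple[str, str, frozenset[str]]]] = {}
    for (pathway, tf), recs in sorted(by_pair.items()):
        diseases = frozenset(r.disease for r in recs)
        common = frozenset(set.intersection(*(set(r.leading_edge) for r in recs)))
        if not common:  # rule (iii): at least one common driving gene
            continue
        patterns.setdefault(diseases, []).append((pathway, tf, common))
    return [
        SignatureGroup(diseases=diseases, shared_items=triples)
        for diseases, triples in sorted(patterns.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0])))
    ]


def annotate_targets(
    groups: Iterable[SignatureGroup],
    annotation_table: Mapping[str, Sequence[str]] | pd.DataFrame,
) -> list[SignatureGroup]:
    """Decorate shared items with user-supplied gene/TF annotations.

    ``annotation_table`` maps an id to its annotations (e.g. disease
    associations or drug flags), either as a mapping id -> list or a
    two-column DataFrame (id, annotation).  Unannotated items pass through
    unchanged; annotations live in ``group.annotations`` so stripping them
    restores the original groups.
    """
    if isinstance(annotation_table, pd.DataFrame):
        if annotation_table.shape[1] < 2:
            raise ValueError("annotation table needs (id, annotation) columns")
        ids = annotation_table.iloc[:, 0]
        if ids.isna().any():
            raise ValueError("annotation table has missing ids")
        lookup: dict[str, list[str]] = {}
        for key, sub in annotation_table.groupby(ids.name or annotation_table.columns[0], sort=False):
            lookup[str(key)] = [str(v) for v in sub.iloc[:, 1]]
    else:
        lookup = {str(k): list(v) for k, v in annotation_table.items()}

    out = []
    for g in groups:
        items = _item_ids(g.shared_items)
        notes = {i: lookup[i] for i in items if i in lookup}
        out.append(SignatureGroup(diseases=g.diseases, shared_items=g.shared_items, annotations=notes))
    return out


def _item_ids(shared_items) -> list[str]:
    if isinstance(shared_items, Mapping):
        return list(shared_items)
    ids: list[str] = []
    for item in shared_items:
        if isinstance(item, tuple):  # (pathway, tf, common genes)
            pathway, tf, genes = item
            ids.extend([pathway, tf, *genes])
        else:
            ids.append(item)
    return ids


def groups_to_frame(groups: Sequence[SignatureGroup]) -> pd.DataFrame:
    """Flatten signature groups into a report table."""
    rows = []
    for g in groups:
        diseases = ",".join(sorted(g.diseases))
        if isinstance(g.shared_items, Mapping):
            for pathway, n_common in sorted(g.shared_items.items()):
                rows.append({"diseases": diseases, "item": pathway, "detail": str(n_common)})
        else:
            for item in sorted(g.shared_items, key=str):
                if isinstance(item, tuple):
                    pathway, tf, genes = item
                    rows.append({"diseases": diseases, "item": f"{pathway}|{tf}", "detail": ";".join(sorted(genes))})
                else:
                    rows.append({"diseases": diseases, "item": item, "detail": ""})
    return pd.DataFrame(rows, columns=["diseases", "item", "detail"])
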