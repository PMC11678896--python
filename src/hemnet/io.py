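"""Readers and writers for the pipeline's tab-separated formats.

All tables are TSV with a fixed column order; floats are written with 17
significant digits, the shortest fixed precision that round-trips any
double exactly, so every writer/reader pair is lossless.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionCohort,
    GeneSetCollection,
    RegulatoryNetwork,
    ScoreTable,
)

FLOAT_FMT = "%.17g"


def read_expression_table(path: str, labels_path: str) -> ExpressionCohort:
    """Load a genes x subjects TSV plus a subject -> disease labels TSV.

    The expression file has gene ids in the first column and subject ids in
    the header; the labels file has two columns (subject, disease) with a
    header row.  TFs are not encoded in these files; callers designate them
    afterwards or via :func:`read_tf_list`.
    """
    values = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    bad = values.columns[values.dtypes == object]
    if len(bad):
        col = bad[0]
        row = values.index[values[col].map(lambda v: not _is_number(v))][0]
        raise ValueError(f"non-numeric expression value at gene {row!r}, subject {col!r}")
    labels = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
    missing = values.columns.difference(labels.index)
    if len(missing):
        raise ValueError(f"subject missing a disease label: {missing[0]!r}")
    return ExpressionCohort(values=values.astype(float), disease_of=labels, tf_ids=[])


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_expression_table(cohort: ExpressionCohort, path: str, labels_path: str) -> None:
    cohort.values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")
    cohort.disease_of.rename("disease").to_csv(labels_path, sep="\t", index_label="subject")


def read_tf_list(path: str) -> list[str]:
    with open(path) as fh:
        tfs = [line.strip() for line in fh if line.strip()]
    if len(tfs) != len(set(tfs)):
        raise ValueError("duplicate entries in TF list")
    return tfs


def write_tf_list(tfs: list[str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(tfs) + "\n")


def read_gmt(path: str) -> GeneSetCollection:
    """Parse a GMT file: one set per line, name TAB description TAB members."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = set(m for m in members if m)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_network(net: RegulatoryNetwork, path: str) -> None:
    """Write a network as a dense TSV edge list: tf, gene, weight, disease."""
    long = net.weights.stack(future_stack=True).reset_index()
    long.columns = ["tf", "gene", "weight"]
    long["disease"] = net.disease
    long.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_network(path: str) -> RegulatoryNetwork:
    long = pd.read_csv(path, sep="\t", float_precision="round_trip")
    diseases = long["disease"].unique() if len(long) else np.array(["?"])
    if len(diseases) > 1:
        raise ValueError(f"network file mixes diseases: {sorted(diseases)}")
    if len(long) == 0:
        return RegulatoryNetwork(weights=pd.DataFrame(), disease=str(diseases[0]))
    wide = long.pivot(index="tf", columns="gene", values="weight")
    # restore first-appearance order lost by pivot's sorting
    wide = wide.loc[list(dict.fromkeys(long["tf"])), list(dict.fromkeys(long["gene"]))]
    return RegulatoryNetwork(weights=wide, disease=str(diseases[0]))


def read_prior_matrix(path: str) -> pd.DataFrame:
    """Dense TSV prior (motif TF x gene, or TF-TF) with row/column ids."""
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_prior_matrix(prior: pd.DataFrame, path: str, index_label: str = "id") -> None:
    prior.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)


def write_score_table(table: ScoreTable, path: str) -> None:
    out = table.table.copy()
    if "specific" in out:
        mult = table.multiplicity()
        out["multiplicity"] = out["feature"].map(mult)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_score_table(path: str) -> ScoreTable:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "specific" in table:
        table["specific"] = table["specific"].astype(bool)
    return ScoreTable(table=table.drop(columns=["multiplicity"], errors="ignore"))


def write_enrichment_records(records, path: str) -> None:
    rows = [
        {
            "disease": r.disease,
            "tf": r.tf if r.tf is not None else "",
            "pathway": r.pathway,
            "es": r.es,
            "p_value": r.p_value,
            "p_adjusted": r.p_adjusted,
            "n_leading": r.driving_gene_count,
            "leading_edge": ";".join(r.leading_edge),
        }
        for r in records
    ]
    cols = ["disease", "tf", "pathway", "es", "p_value", "p_adjusted", "n_leading", "leading_edge"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_enrichment_records(path: str):
    from .datamodel import EnrichmentRecord

    df = pd.read_csv(path, sep="\t", keep_default_na=False, float_precision="round_trip")
    records = []
    for row in df.itertuples(index=False):
        le = tuple(g for g in str(row.leading_edge).split(";") if g)
        records.append(
            EnrichmentRecord(
                disease=row.disease,
                tf=row.tf or None,
                pathway=row.pathway,
                es=float(row.es),
                p_value=float(row.p_value),
                p_adjusted=float(row.p_adjusted),
                leading_edge=le,
            )
        )
    return records


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
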