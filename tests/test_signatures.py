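import numpy as np
import pandas as pd
import pytest

from hemnet.datamodel import EnrichmentRecord, ScoreTable, SignatureGroup
from hemnet.signatures import (
    annotate_targets,
    groups_to_frame,
    shared_overexpression_groups,
    shared_pathway_groups,
    tf_pathway_intersection_clusters,
)


def score_table_from_flags(flags: dict[str, set[str]], diseases) -> ScoreTable:
    rows = []
    for gene, flagged in flags.items():
        for d in diseases:
            rows.append(
                {
                    "feature": gene,
                    "disease": d,
                    "score": 3.0 if d in flagged else 0.0,
                    "p_value": 1e-5 if d in flagged else 0.5,
                    "p_adjusted": 1e-4 if d in flagged else 0.8,
                    "specific": d in flagged,
                }
            )
    return ScoreTable(table=pd.DataFrame(rows))


def rec(disease, pathway, leading, tf=None, p_adj=1e-3):
    return EnrichmentRecord(
        disease=disease,
        pathway=pathway,
        es=0.7,
        p_value=p_adj / 10,
        p_adjusted=p_adj,
        leading_edge=tuple(leading),
        tf=tf,
    )


class TestSharedOverexpression:
    def test_no_multi_flag_genes_no_multi_groups(self):
        table = score_table_from_flags({"g1": {"A"}, "g2": {"B"}}, ["A", "B", "C"])
        groups = shared_overexpression_groups(table)
        assert all(len(g.diseases) == 1 for g in groups)

    def test_three_disease_pattern_recovered(self):
        table = score_table_from_flags(
            {"g1": {"HL", "MZLs", "PTCL"}, "g2": {"HL"}}, ["HL", "MZLs", "PTCL", "BL"]
        )
        groups = shared_overexpression_groups(table)
        triple = [g for g in groups if len(g.diseases) == 3]
        assert len(triple) == 1
        assert triple[0].diseases == frozenset({"HL", "MZLs", "PTCL"})
        assert triple[0].shared_items == {"g1"}

    def test_planted_pair_plus_singletons(self):
        table = score_table_from_flags(
            {"ga": {"D1", "D2"}, "gb": {"D1", "D2"}, "gc": {"D3"}}, ["D1", "D2", "D3"]
        )
        groups = shared_overexpression_groups(table)
        pair = [g for g in groups if g.diseases == frozenset({"D1", "D2"})]
        assert pair and pair[0].shared_items == {"ga", "gb"}
        single = [g for g in groups if g.diseases == frozenset({"D3"})]
        assert single and single[0].shared_items == {"gc"}

    def test_groups_match_brute_force_flag_scan(self, rng):
        """Every emitted disease set is the exact flag pattern of >= 1 gene."""
        diseases = [f"D{i}" for i in range(6)]
        flags = {}
        for gi in range(40):
            chosen = set(rng.choice(diseases, size=int(rng.integers(0, 4)), replace=False))
            flags[f"g{gi}"] = chosen
        table = score_table_from_flags(flags, diseases)
        groups = shared_overexpression_groups(table)
        expected_patterns = {frozenset(v) for v in flags.values() if v}
        assert {g.diseases for g in groups} == expected_patterns
        for g in groups:
            assert g.shared_items == {
                gene for gene, fl in flags.items() if frozenset(fl) == g.diseases
            }


class TestSharedPathways:
    def test_single_disease_specificity_entry(self):
        groups = shared_pathway_groups([rec("ALL", "Lysosome", [f"g{i}" for i in range(41)])])
        assert groups[0].diseases == frozenset({"ALL"})
        assert groups[0].shared_items == {"Lysosome": 41}

    def test_disjoint_leading_edges_zero_common(self):
        groups = shared_pathway_groups(
            [rec("A", "P1", ["g1", "g2"]), rec("B", "P1", ["g3", "g4"])]
        )
        assert groups[0].diseases == frozenset({"A", "B"})
        assert groups[0].shared_items == {"P1": 0}

    def test_planted_battery_groups(self):
        records = [
            rec("A", "P1", ["g1", "g2", "g3"]),
            rec("B", "P1", ["g2", "g3", "g4"]),
            rec("A", "P2", ["g9"]),
            rec("B", "P2", ["g9", "g8"]),
            rec("C", "P3", ["g5"]),
        ]
        groups = shared_pathway_groups(records)
        ab = [g for g in groups if g.diseases == frozenset({"A", "B"})]
        assert ab and ab[0].shared_items == {"P1": 2, "P2": 1}
        c = [g for g in groups if g.diseases == frozenset({"C"})]
        assert c and c[0].shared_items == {"P3": 1}


class TestTfPathwayClusters:
    def test_five_disease_cluster_with_common_drivers(self):
        diseases = ["AML", "CLL", "HL", "MCL", "PTCL"]
        drivers = [f"ABC{i}" for i in range(15)]
        records = [rec(d, "ABC TRANSPORTERS", drivers, tf="CEBPB") for d in diseases]
        clusters = tf_pathway_intersection_clusters(records)
        assert len(clusters) == 1
        assert clusters[0].diseases == frozenset(diseases)
        pathway, tf, common = next(iter(clusters[0].shared_items))
        assert (pathway, tf) == ("ABC TRANSPORTERS", "CEBPB")
        assert common == frozenset(drivers)

    def test_empty_common_drivers_drops_cluster(self):
        records = [
            rec("A", "P1", ["g1"], tf="T1"),
            rec("B", "P1", ["g2"], tf="T1"),
        ]
        assert tf_pathway_intersection_clusters(records) == []

    def test_planted_three_disease_cluster_recovered(self):
        """Same TF drives the same pathway in 3 diseases -> 3-disease cluster."""
        records = [
            rec("D1", "PATH", ["g1", "g2", "g5"], tf="T7"),
            rec("D2", "PATH", ["g2", "g5", "g9"], tf="T7"),
            rec("D3", "PATH", ["g5", "g2"], tf="T7"),
            # decoys: same pathway different TF, same TF different pathway
            rec("D1", "PATH", ["g1"], tf="T8"),
            rec("D4", "OTHER", ["g1"], tf="T7"),
        ]
        clusters = tf_pathway_intersection_clusters(records)
        triple = [g for g in clusters if g.diseases == frozenset({"D1", "D2", "D3"})]
        assert len(triple) == 1
        assert ("PATH", "T7", frozenset({"g2", "g5"})) in triple[0].shared_items

    def test_record_order_invariance(self, rng):
        records = [
            rec(f"D{i}", p, [f"g{j}" for j in rng.integers(0, 9, size=4)], tf=t)
            for i in range(4)
            for p in ["P1", "P2"]
            for t in ["T1", "T2"]
        ]
        base = tf_pathway_intersection_clusters(records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        perm = tf_pathway_intersection_clusters(shuffled)
        assert {(g.diseases, frozenset(g.shared_items)) for g in base} == {
            (g.diseases, frozenset(g.shared_items)) for g in perm
        }

    def test_missing_tf_rejected(self):
        with pytest.raises(ValueError, match="TF"):
            tf_pathway_intersection_clusters([rec("A", "P", ["g1"])])


class TestAnnotateTargets:
    def make_groups(self):
        return [
            SignatureGroup(diseases=frozenset({"A", "B"}), shared_items={"CEBPB", "g2"}),
        ]

    def test_empty_table_unchanged(self):
        groups = self.make_groups()
        out = annotate_targets(groups, {})
        assert out[0].shared_items == groups[0].shared_items
        assert out[0].annotations == {}

    def test_drug_flag_propagated(self):
        out = annotate_targets(self.make_groups(), {"CEBPB": ["druggable"]})
        assert out[0].annotations == {"CEBPB": ["druggable"]}

    def test_dataframe_input_and_strip_round_trip(self):
        table = pd.DataFrame({"id": ["CEBPB"], "annotation": ["drug:STL"]})
        annotated = annotate_targets(self.make_groups(), table)
        stripped = [
            SignatureGroup(diseases=g.diseases, shared_items=g.shared_items) for g in annotated
        ]
        assert stripped == self.make_groups()

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError):
            annotate_targets(self.make_groups(), pd.DataFrame({"id": ["x"]}))


class TestReportFrame:
    def test_flatten_shapes(self):
        groups = [
            SignatureGroup(diseases=frozenset({"A"}), shared_items={"g1", "g2"}),
            SignatureGroup(diseases=frozenset({"A", "B"}), shared_items={"P1": 3}),
            SignatureGroup(
                diseases=frozenset({"A", "B"}),
                shared_items=[("P1", "T1", frozenset({"g1"}))],
            ),
        ]
        frame = groups_to_frame(groups)
        assert list(frame.columns) == ["diseases", "item", "detail"]
        assert len(frame) == 4
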