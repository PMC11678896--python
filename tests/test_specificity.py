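import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from hemnet.config import PipelineConfig
from hemnet.datamodel import NullModel, RegulatoryNetwork
from hemnet.specificity import (
    benjamini_hochberg,
    call_specific,
    compute_multiplicity,
    compute_scores,
    fit_empirical_null,
    score_cohort,
    score_networks,
    score_pvalues,
)
from oracles import bh_stepup


def one_feature(values, groups):
    feats = pd.DataFrame([values], index=["f"], columns=[f"s{i}" for i in range(len(values))], dtype=float)
    grouping = pd.Series(groups, index=feats.columns)
    return compute_scores(feats, grouping).table.set_index("disease")["score"]


class TestComputeScores:
    def test_hand_computed_eight_value_example(self):
        """{1..8} split in half: pooled med 4.5, IQR 3.5, scores -/+ 4/7."""
        s = one_feature([1, 2, 3, 4, 5, 6, 7, 8], ["A"] * 4 + ["B"] * 4)
        assert s["A"] == pytest.approx(-2.0 / 3.5)
        assert s["B"] == pytest.approx(+2.0 / 3.5)
        assert s["A"] == -s["B"]  # mirrored split is exactly antisymmetric

    def test_zero_when_disease_median_equals_pooled(self):
        s = one_feature([1, 5, 9, 1, 5, 9], ["A"] * 3 + ["B"] * 3)
        assert s["A"] == 0 and s["B"] == 0

    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.01, 100),
    )
    def test_location_scale_invariance(self, shift, scale):
        base = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 12.0, 13.0, 15.0])
        groups = ["A"] * 4 + ["B"] * 4
        s0 = one_feature(base, groups)
        s1 = one_feature(base * scale + shift, groups)
        np.testing.assert_allclose(s1.to_numpy(), s0.to_numpy(), rtol=1e-9, atol=1e-9)

    def test_zero_iqr_flagged_undefined(self):
        s = one_feature([5, 5, 5, 5, 5, 5, 5, 9], ["A"] * 4 + ["B"] * 4)
        assert s.isna().all()

    def test_single_disease_rejected(self):
        with pytest.raises(ValueError, match="2 diseases"):
            one_feature([1, 2, 3], ["A", "A", "A"])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_scores(pd.DataFrame(columns=["s1", "s2"]), pd.Series({"s1": "A", "s2": "B"}))


class TestEmpiricalNull:
    def test_standard_normal_sample_recovered(self, rng):
        null = fit_empirical_null(rng.normal(0, 1, 100_000))
        assert -0.02 <= null.mu <= 0.02
        assert 0.98 <= null.sigma <= 1.02

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_empirical_null(np.ones(100))

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError, match="30"):
            fit_empirical_null(np.arange(10))


class TestPvalues:
    @pytest.fixture
    def scored(self):
        table = compute_scores(
            pd.DataFrame(
                [[0.0, 0.0, 1.0, 3.0]] * 2, index=["f1", "f2"], columns=["s1", "s2", "s3", "s4"]
            ),
            pd.Series({"s1": "A", "s2": "A", "s3": "B", "s4": "B"}),
        )
        return table

    def test_score_at_mu_gives_half(self, scored):
        out = score_pvalues(scored, NullModel(mu=0.5, sigma=1.0, n_scores=100)).table
        row = out[np.isclose(out["score"], 0.5)]
        assert (row["p_value"] == pytest.approx(0.5)).all()

    def test_two_sigma_tail(self):
        null = NullModel(mu=0.0, sigma=0.5, n_scores=100)
        table = compute_scores(
            pd.DataFrame([[0, 0, 0, 4.0]], index=["f"], columns=["s1", "s2", "s3", "s4"]),
            pd.Series({"s1": "A", "s2": "A", "s3": "B", "s4": "B"}),
        )
        out = score_pvalues(table, null).table.set_index("disease")
        score_b = out.loc["B", "score"]
        expected = stats.norm.sf((score_b - null.mu) / null.sigma)
        assert out.loc["B", "p_value"] == pytest.approx(expected)
        # reference point: a score at mu + 2 sigma has p ~ 0.02275
        assert stats.norm.sf(2.0) == pytest.approx(0.02275, abs=1e-5)

    def test_monotone_decreasing_in_score(self, rng):
        scores = rng.normal(0, 1, 500)
        null = NullModel(mu=0.0, sigma=1.0, n_scores=500)
        p = stats.norm.sf((scores - null.mu) / null.sigma)
        order = np.argsort(scores)
        assert (np.diff(p[order]) <= 0).all()


class TestBenjaminiHochberg:
    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.03] * 5), [0.03] * 5)

    def test_worked_examples(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(benjamini_hochberg([0.001, 1.0]), [0.002, 1.0])

    def test_against_brute_force_oracle(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(benjamini_hochberg(p), bh_stepup(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_order_preserving(self, rng):
        p = rng.random(200)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all()
        assert (np.diff(adj[np.argsort(p, kind="stable")]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestCallsAndMultiplicity:
    def make_table(self, rows):
        df = pd.DataFrame(rows, columns=["feature", "disease", "score", "p_value", "p_adjusted"])
        from hemnet.datamodel import ScoreTable

        return ScoreTable(table=df)

    def test_call_rules(self):
        table = self.make_table(
            [
                ["g1", "A", 2.5, 0.0005, 0.001],  # passes both
                ["g1", "B", 2.5, 0.01, 0.02],  # p too large
                ["g2", "A", 1.9, 1e-7, 1e-6],  # score too small
            ]
        )
        out = call_specific(table, PipelineConfig()).table
        assert list(out["specific"]) == [True, False, False]

    def test_raw_p_switch(self):
        table = self.make_table([["g1", "A", 2.5, 0.001, 0.5]])
        assert not call_specific(table, PipelineConfig()).table["specific"].item()
        raw_cfg = PipelineConfig(use_adjusted_p=False)
        assert call_specific(table, raw_cfg).table["specific"].item()

    def test_multiplicity_counts_diseases(self):
        table = self.make_table(
            [
                ["g1", "A", 3.0, 1e-5, 1e-4],
                ["g1", "B", 3.0, 1e-5, 1e-4],
                ["g1", "C", 0.0, 0.5, 0.9],
                ["g2", "A", 0.0, 0.5, 0.9],
            ]
        )
        mult = compute_multiplicity(call_specific(table, PipelineConfig()))
        assert mult["g1"] == 2  # flagged in exactly two diseases
        assert mult["g2"] == 0


class TestNullCalibration:
    def test_pure_null_p_criterion_rate(self):
        """Without planted effects, the raw p<alpha rate matches the nominal level."""
        from hemnet.synthetic import SimConfig, generate_cohort

        cfg = SimConfig(
            n_genes=400, n_tfs=5, diseases={f"D{i:02d}": 40 for i in range(1, 14)}, seed=5
        )
        cohort, _ = generate_cohort(cfg)
        table = score_cohort(cohort, PipelineConfig())
        frac = (table.table["p_value"] < 0.05).mean()
        n = len(table.table)
        # scores within a feature are weakly dependent; allow 5 binomial sigmas
        assert abs(frac - 0.05) <= 5 * np.sqrt(0.05 * 0.95 / n)


class TestEdgeVariant:
    def test_each_disease_contributes_one_observation(self, rng):
        tfs, genes = ["t1", "t2"], ["g1", "g2", "g3"]
        nets = [
            RegulatoryNetwork(
                weights=pd.DataFrame(rng.normal(0, 1, (2, 3)), index=tfs, columns=genes),
                disease=f"D{i}",
            )
            for i in range(8)
        ]
        table = score_networks(nets, PipelineConfig())
        assert len(table.table) == 6 * 8
        # check one edge by hand: disease value minus median over diseases, over IQR
        w = np.array([n.weights.loc["t1", "g2"] for n in nets])
        q1, q3 = np.quantile(w, [0.25, 0.75])
        expected = (w[0] - np.median(w)) / (q3 - q1)
        got = table.table.query("feature == 't1→g2' and disease == 'D0'")["score"].item()
        assert got == pytest.approx(expected)

    def test_mismatched_ids_rejected(self, rng):
        a = RegulatoryNetwork(
            weights=pd.DataFrame(rng.normal(0, 1, (1, 2)), index=["t1"], columns=["g1", "g2"]),
            disease="D1",
        )
        b = RegulatoryNetwork(
            weights=pd.DataFrame(rng.normal(0, 1, (1, 2)), index=["t1"], columns=["g2", "g1"]),
            disease="D2",
        )
        with pytest.raises(ValueError, match="identical"):
            score_networks([a, b])
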