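import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import oracles
from icibench import immune as imm
from icibench.simulate import (
    default_mcp_collection,
    default_notch_pathway,
    default_signature_collection,
)


def matrix(values, genes, samples, scale="linear"):
    return imm.ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale=scale)


TOY = matrix(
    [[9.0, 1.0], [7.0, 2.0], [5.0, 8.0], [3.0, 6.0], [1.0, 4.0]],
    ["G1", "G2", "G3", "G4", "G5"], ["S1", "S2"],
)


class TestExpressionMatrix:
    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            matrix([[1.0], [2.0]], ["G1", "G1"], ["S1"])

    def test_negative_linear_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            matrix([[-1.0]], ["G1"], ["S1"])

    def test_scale_conversion_round_trip(self):
        log = TOY.to_log2p1()
        back = log.to_linear()
        np.testing.assert_allclose(back.values.to_numpy(), TOY.values.to_numpy(), atol=1e-12)


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        coll = imm.GeneSetCollection(
            {"setA": ("g1", "g2"), "setB": ("g3",)}, {"setA": "activated"})
        path = tmp_path / "sets.gmt"
        imm.write_gmt(coll, path)
        loaded = imm.read_gmt(path)
        assert loaded.sets == {"setA": ("G1", "G2"), "setB": ("G3",)}
        assert loaded.directions == {"setA": "activated"}

    def test_bundled_collections_shape(self):
        assert len(default_signature_collection()) == 29
        assert len(default_mcp_collection()) == 10
        notch = default_notch_pathway()
        act = next(n for n in notch if notch.directions[n] == "activated")
        rep = next(n for n in notch if notch.directions[n] == "repressed")
        assert len(notch[act]) == 50 and len(notch[rep]) == 21

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\tdesc\n")
        with pytest.raises(ValueError, match="malformed"):
            imm.read_gmt(path)


class TestSsgsea:
    def test_running_sum_oracle_on_toy_matrix(self):
        sets = imm.GeneSetCollection({"s": ("G2", "G4")})
        res = imm.ssgsea(TOY, sets, alpha=0.25)
        for sample in ("S1", "S2"):
            expected = oracles.ssgsea_running_sum(
                TOY.values[sample].to_dict(), ["G2", "G4"], alpha=0.25)
            assert res.scores.loc["s", sample] == pytest.approx(expected, rel=1e-12)

    def test_identical_samples_identical_scores(self):
        m = matrix([[3.0, 3.0], [1.0, 1.0], [2.0, 2.0]], ["A", "B", "C"], ["S1", "S2"])
        res = imm.ssgsea(m, imm.GeneSetCollection({"s": ("A", "C")}))
        assert res.scores.loc["s", "S1"] == res.scores.loc["s", "S2"]

    @given(st.integers(0, 10_000))
    def test_rank_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((8, 3)) * 10
        genes = [f"G{i}" for i in range(8)]
        m1 = matrix(vals, genes, ["S1", "S2", "S3"])
        m2 = matrix(vals ** 3, genes, ["S1", "S2", "S3"])  # strictly increasing map
        sets = imm.GeneSetCollection({"s": tuple(genes[:3])})
        pd.testing.assert_frame_equal(imm.ssgsea(m1, sets).scores, imm.ssgsea(m2, sets).scores)

    def test_zero_overlap_set_reported_not_fatal(self):
        sets = imm.GeneSetCollection({"absent": ("ZZZ",), "ok": ("G1", "G2")})
        res = imm.ssgsea(TOY, sets)
        assert "absent" in res.errors
        assert np.isnan(res.scores.loc["absent"]).all()
        assert np.isfinite(res.scores.loc["ok"]).all()

    def test_whole_universe_set_degenerate(self):
        sets = imm.GeneSetCollection({"all": ("G1", "G2", "G3", "G4", "G5")})
        res = imm.ssgsea(TOY, sets)
        assert "complement" in res.errors["all"]

    def test_normalization_divides_by_range(self):
        sets = imm.GeneSetCollection({"s": ("G1", "G2"), "t": ("G4", "G5")})
        raw = imm.ssgsea(TOY, sets).scores
        norm = imm.ssgsea(TOY, sets, normalize=True).scores
        rng_ = raw.to_numpy().max() - raw.to_numpy().min()
        np.testing.assert_allclose(norm.to_numpy(), raw.to_numpy() / rng_)


class TestMcpScores:
    def test_single_marker_population(self):
        sets = imm.GeneSetCollection({"pop": ("G1",)})
        res = imm.mcp_scores(TOY, sets)
        assert res.scores.loc["pop", "S1"] == pytest.approx(np.log2(10.0))

    def test_all_zero_markers_score_zero(self):
        m = matrix([[0.0], [0.0]], ["G1", "G2"], ["S1"])
        res = imm.mcp_scores(m, imm.GeneSetCollection({"pop": ("G1", "G2")}))
        assert res.scores.loc["pop", "S1"] == 0.0

    def test_three_marker_mean(self):
        sets = imm.GeneSetCollection({"pop": ("G1", "G3", "G5")})
        res = imm.mcp_scores(TOY, sets)
        expected = np.mean([np.log2(9 + 1), np.log2(5 + 1), np.log2(1 + 1)])
        assert res.scores.loc["pop", "S1"] == pytest.approx(expected)

    def test_missing_population_reported(self):
        res = imm.mcp_scores(TOY, imm.GeneSetCollection({"gone": ("ZZZ",)}))
        assert "gone" in res.errors


class TestCytScore:
    def _expr(self, gzma, prf1):
        return matrix([[gzma], [prf1], [5.0]], ["GZMA", "PRF1", "OTHER"], ["S1"])

    def test_geometric_mean(self):
        assert imm.cyt_score(self._expr(4.0, 9.0))["S1"] == pytest.approx(6.0, abs=0.02)

    def test_equal_expression_fixed_point(self):
        assert imm.cyt_score(self._expr(7.0, 7.0))["S1"] == pytest.approx(7.01)

    def test_pseudocount_with_silent_gene(self):
        assert imm.cyt_score(self._expr(0.0, 100.0))["S1"] == pytest.approx(1.00005, rel=1e-6)

    def test_missing_gene_named(self):
        m = matrix([[1.0]], ["GZMA"], ["S1"])
        with pytest.raises(ValueError, match="PRF1"):
            imm.cyt_score(m)


class TestPathwayScore:
    def test_direct_arithmetic(self):
        m = matrix([[2.0], [4.0], [1.0], [3.0]], ["A1", "A2", "R1", "R2"],
                   ["S1"], scale="log2p1")
        score = imm.pathway_score(m, ["A1", "A2"], ["R1", "R2"])
        assert score["S1"] == pytest.approx(1.0)

    def test_identical_sets_cancel(self):
        m = TOY.to_log2p1()
        score = imm.pathway_score(m, ["G1", "G2"], ["G1", "G2"])
        assert np.allclose(score, 0.0)

    def test_bundled_sets_match_two_pass_mean(self, small_cohort):
        notch = default_notch_pathway()
        act = next(n for n in notch if notch.directions[n] == "activated")
        rep = next(n for n in notch if notch.directions[n] == "repressed")
        expr = small_cohort.expression
        score = imm.pathway_score(expr, notch[act], notch[rep])
        sample = expr.samples[0]
        col = expr.values[sample]
        act_present = [g for g in notch[act] if g in expr.genes]
        rep_present = [g for g in notch[rep] if g in expr.genes]
        expected = sum(col[g] for g in act_present) / len(act_present) \
            - sum(col[g] for g in rep_present) / len(rep_present)
        assert score[sample] == pytest.approx(expected, rel=1e-12)

    def test_zero_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            imm.pathway_score(TOY, ["ZZZ"], ["G1"])


class TestFractions:
    def _uniform(self):
        return pd.DataFrame(
            [[1 / 22] * 22], index=["S1"], columns=imm.CIBERSORT_CATEGORIES)

    def test_all_mass_on_cd8(self):
        df = pd.DataFrame(0.0, index=["S1"], columns=imm.CIBERSORT_CATEGORIES)
        df.loc["S1", "T cells CD8"] = 1.0
        assert imm.lymphocyte_fraction(df)["S1"] == 1.0

    def test_all_mass_on_neutrophils(self):
        df = pd.DataFrame(0.0, index=["S1"], columns=imm.CIBERSORT_CATEGORIES)
        df.loc["S1", "Neutrophils"] = 1.0
        assert imm.lymphocyte_fraction(df)["S1"] == 0.0

    def test_uniform_fractions_give_lymphoid_share(self):
        # 12 of the 22 CIBERSORT categories are lymphoid
        assert len(imm.LYMPHOCYTE_CATEGORIES) == 12
        assert imm.lymphocyte_fraction(self._uniform())["S1"] == pytest.approx(12 / 22)

    def test_missing_category_named(self):
        df = self._uniform().drop(columns=["Monocytes"])
        with pytest.raises(ValueError, match="Monocytes"):
            imm.lymphocyte_fraction(df)

    def test_nonunit_sum_rejected(self):
        df = self._uniform() * 2
        with pytest.raises(ValueError, match="sum to 1"):
            imm.lymphocyte_fraction(df)

    @pytest.mark.parametrize("leuk, lymph, expected", [
        (0.5, 0.4, 0.2), (0.0, 0.9, 0.0), (1.0, 0.37, 0.37)])
    def test_til_product(self, leuk, lymph, expected):
        assert imm.til_fraction(leuk, lymph) == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_til_commutative_and_bounded(self, a, b):
        t = imm.til_fraction(a, b)
        assert t == imm.til_fraction(b, a)
        assert t <= min(a, b) + 1e-15

    def test_til_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            imm.til_fraction(1.2, 0.5)


class TestCompareByArm:
    def _status(self, samples, mut_samples):
        return pd.DataFrame(
            {"status": ["MUT" if s in mut_samples else "WT" for s in samples]},
            index=pd.Index(samples, name="sample_id"))

    def test_identical_distributions_give_p_one(self):
        samples = [f"S{i}" for i in range(8)]
        scores = pd.DataFrame([[1, 2, 3, 4, 1, 2, 3, 4]], index=["f"], columns=samples,
                              dtype=float)
        res = imm.compare_by_arm(scores, self._status(samples, samples[:4]))
        assert res.loc["f", "p"] == pytest.approx(1.0)

    def test_shifted_feature_detected_and_ordered_first(self):
        rng = np.random.default_rng(0)
        samples = [f"S{i}" for i in range(60)]
        mut = samples[:30]
        shifted = np.concatenate([rng.normal(3, 1, 30), rng.normal(0, 1, 30)])
        flat = rng.normal(0, 1, 60)
        scores = pd.DataFrame([shifted, flat], index=["hot", "cold"], columns=samples)
        res = imm.compare_by_arm(scores, self._status(samples, mut))
        assert res.index[0] == "hot"
        assert res.loc["hot", "p"] < 1e-6
        assert res.loc["hot", "direction"] == "MUT"

    def test_single_sample_per_arm_rejected(self):
        samples = ["S0", "S1"]
        scores = pd.DataFrame([[1.0, 2.0]], index=["f"], columns=samples)
        with pytest.raises(ValueError, match=">= 2"):
            imm.compare_by_arm(scores, self._status(samples, ["S0"]))

    def test_constant_feature_flagged_degenerate(self):
        samples = [f"S{i}" for i in range(6)]
        scores = pd.DataFrame([[1.0] * 6], index=["flat"], columns=samples)
        res = imm.compare_by_arm(scores, self._status(samples, samples[:3]))
        assert bool(res.loc["flat", "degenerate"])
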