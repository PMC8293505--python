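import numpy as np
import pandas as pd
import pytest

from icibench import mutations as mut
from icibench.stats import fisher_exact


def records(rows):
    return pd.DataFrame(rows, columns=["sample_id", "gene", "variant_classification", "assay_id"])


class TestReadMaf:
    def test_count_preservation(self, toy_maf):
        recs = mut.read_maf(toy_maf, ["S1", "S2", "S3"])
        assert len(recs) == 5
        assert list(recs.columns) == ["sample_id", "gene", "variant_classification", "assay_id"]

    def test_missing_mandatory_column_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"Tumor_Sample_Barcode": ["S1"], "Hugo_Symbol": ["TP53"],
                      "Variant_Class": ["Silent"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="Variant_Classification"):
            mut.read_maf(path, ["S1"])

    def test_sample_outside_manifest_named(self, toy_maf):
        with pytest.raises(ValueError, match="S3"):
            mut.read_maf(toy_maf, ["S1", "S2"])

    def test_unknown_classification_rejected(self, tmp_path):
        path = tmp_path / "vocab.tsv"
        pd.DataFrame({"Tumor_Sample_Barcode": ["S1"], "Hugo_Symbol": ["TP53"],
                      "Variant_Classification": ["Radical_Change"]}).to_csv(
            path, sep="\t", index=False)
        with pytest.raises(ValueError, match="Radical_Change"):
            mut.read_maf(path, ["S1"])

    def test_column_order_independent(self, tmp_path):
        path = tmp_path / "shuffled.tsv"
        pd.DataFrame({"Variant_Classification": ["Missense_Mutation"],
                      "Hugo_Symbol": ["notch4"],
                      "Tumor_Sample_Barcode": ["S1"]}).to_csv(path, sep="\t", index=False)
        recs = mut.read_maf(path, ["S1"])
        assert recs.loc[0, "gene"] == "NOTCH4"  # case-normalized


class TestNonsynonymousFilter:
    @pytest.mark.parametrize(
        "classes, n_kept",
        [
            (["Missense_Mutation", "Silent", "Frame_Shift_Del"], 2),
            (["In_Frame_Del"], 0),
            ([], 0),
            (list(mut.NONSYNONYMOUS_CLASSES), len(mut.NONSYNONYMOUS_CLASSES)),
        ],
    )
    def test_keeps_exactly_the_six_classes(self, classes, n_kept):
        recs = records([("S1", "G1", c, "WES") for c in classes])
        assert len(mut.filter_nonsynonymous(recs)) == n_kept

    def test_idempotent_and_order_preserving(self):
        recs = records([
            ("S1", "A", "Missense_Mutation", "WES"),
            ("S1", "B", "Silent", "WES"),
            ("S2", "C", "Splice_Site", "WES"),
        ])
        once = mut.filter_nonsynonymous(recs)
        twice = mut.filter_nonsynonymous(once)
        pd.testing.assert_frame_equal(once, twice)
        assert list(once["gene"]) == ["A", "C"]


class TestGeneStatus:
    def test_multiplicity_ignored(self):
        recs = records([("S1", "NOTCH4", "Missense_Mutation", "WES")] * 3)
        status = mut.call_gene_status(recs, ["S1", "S2"], "notch4")
        assert status.loc["S1", "status"] == "MUT"
        assert status.loc["S1", "n_variants"] == 3
        assert status.loc["S2", "status"] == "WT"

    def test_absent_gene_all_wt(self):
        recs = records([("S1", "TP53", "Missense_Mutation", "WES")])
        status = mut.call_gene_status(recs, ["S1", "S2"], "NOTCH4")
        assert (status["status"] == "WT").all()

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError, match="manifest"):
            mut.call_gene_status(records([]), [], "NOTCH4")

    def test_counts_partition_manifest(self, small_cohort):
        nonsyn = mut.filter_nonsynonymous(small_cohort.mutations)
        status = mut.call_gene_status(nonsyn, small_cohort.manifest, "NOTCH4")
        assert len(status) == len(small_cohort.manifest)
        assert set(status["status"]) <= {"MUT", "WT"}


class TestGeneSetStatus:
    def test_union_rule(self):
        recs = records([("S1", "NOTCH2", "Missense_Mutation", "WES")])
        status = mut.call_geneset_status(recs, ["S1", "S2"], mut.NOTCH_FAMILY)
        assert status.loc["S1", "status"] == "MUT"
        assert status.loc["S2", "status"] == "WT"

    def test_unrelated_gene_does_not_alter(self):
        recs = records([("S1", "TP53", "Missense_Mutation", "WES")])
        status = mut.call_geneset_status(recs, ["S1"], mut.HOMOLOGOUS_REPAIR_GENES)
        assert status.loc["S1", "status"] == "WT"

    def test_singleton_set_reduces_to_gene_status(self):
        recs = records([
            ("S1", "ATM", "Nonsense_Mutation", "WES"),
            ("S2", "TP53", "Missense_Mutation", "WES"),
        ])
        manifest = ["S1", "S2", "S3"]
        pd.testing.assert_frame_equal(
            mut.call_geneset_status(recs, manifest, {"ATM"}),
            mut.call_gene_status(recs, manifest, "ATM"),
        )

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mut.call_geneset_status(records([]), ["S1"], set())


class TestTMB:
    def test_printed_denominators(self):
        wes = records([("S1", f"G{i}", "Missense_Mutation", "WES") for i in range(76)])
        assert mut.compute_tmb(wes, ["S1"])["S1"] == pytest.approx(2.0)
        panel = records([("S2", f"G{i}", "Missense_Mutation", "IMPACT468") for i in range(61)])
        assert mut.compute_tmb(panel, ["S2"])["S2"] == pytest.approx(50.0)

    def test_sample_without_records_gets_zero(self):
        recs = records([("S1", "G1", "Missense_Mutation", "WES")])
        assert mut.compute_tmb(recs, ["S1", "S2"])["S2"] == 0.0

    def test_linear_in_duplication_and_order_invariant(self):
        recs = records([("S1", f"G{i}", "Missense_Mutation", "WES") for i in range(10)])
        base = mut.compute_tmb(recs, ["S1"])["S1"]
        doubled = mut.compute_tmb(pd.concat([recs, recs], ignore_index=True), ["S1"])["S1"]
        shuffled = mut.compute_tmb(recs.sample(frac=1, random_state=0), ["S1"])["S1"]
        assert doubled == pytest.approx(2 * base)
        assert shuffled == pytest.approx(base)

    def test_mixed_assays_within_sample_rejected(self):
        recs = records([
            ("S1", "G1", "Missense_Mutation", "WES"),
            ("S1", "G2", "Missense_Mutation", "IMPACT468"),
        ])
        with pytest.raises(ValueError, match="mixed assay"):
            mut.compute_tmb(recs, ["S1"])

    def test_unknown_assay_rejected(self):
        recs = records([("S1", "G1", "Missense_Mutation", "PANEL99")])
        with pytest.raises(ValueError, match="PANEL99"):
            mut.compute_tmb(recs, ["S1"])

    def test_panel_spec_defaults(self):
        assert mut.PanelSpec.default("IMPACT341").exonic_coverage_mb == 0.98
        with pytest.raises(ValueError, match="unknown assay"):
            mut.PanelSpec.default("IMPACT999")


class TestCooccurrence:
    def _status(self, manifest, mut_samples):
        recs = records([(s, "X", "Missense_Mutation", "WES") for s in mut_samples])
        return mut.call_gene_status(recs, manifest, "X")

    def test_self_cooccurrence_diagonal(self):
        manifest = [f"S{i}" for i in range(10)]
        a = self._status(manifest, ["S0", "S1", "S2"])
        tab = mut.cooccurrence_table(a, a)
        assert (tab.b, tab.c) == (0, 0)
        assert (tab.a, tab.d) == (3, 7)

    def test_disjoint_mutant_sets(self):
        manifest = [f"S{i}" for i in range(10)]
        a = self._status(manifest, ["S0", "S1", "S2"])
        b = self._status(manifest, ["S3", "S4", "S5", "S6"])
        tab = mut.cooccurrence_table(a, b)
        assert [[tab.a, tab.b], [tab.c, tab.d]] == [[0, 3], [4, 3]]

    def test_universe_mismatch_rejected(self):
        a = self._status(["S0", "S1"], ["S0"])
        b = self._status(["S0", "S2"], ["S0"])
        with pytest.raises(ValueError, match="S1"):
            mut.cooccurrence_table(a, b)

    def test_null_rejection_rate_at_most_nominal(self):
        # independent binary statuses: discrete Fisher p is conservative,
        # so the rejection rate at alpha=0.05 must not exceed ~alpha
        rng = np.random.default_rng(123)
        manifest = [f"S{i}" for i in range(200)]
        rejections = 0
        n_seeds = 200
        for _ in range(n_seeds):
            a = self._status(manifest, [s for s in manifest if rng.random() < 0.2])
            b = self._status(manifest, [s for s in manifest if rng.random() < 0.3])
            tab = mut.cooccurrence_table(a, b)
            if fisher_exact(tab).p_value < 0.05:
                rejections += 1
        assert rejections / n_seeds <= 0.08
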