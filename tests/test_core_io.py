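"""Expression table I/O, sample-sheet validation and probe filtering."""

import json
from fractions import Fraction

import pandas as pd
import pytest

from hopstat import (
    ExpressionMatrix,
    Genotype,
    ReportBundle,
    SampleMetadata,
    Stage,
    filter_probe_sets,
    read_expression_table,
    read_metadata,
    read_report,
    write_expression_table,
    write_report,
)

from conftest import make_matrix, make_samples


class TestExpressionTableIO:
    def test_round_trip_identity(self, tmp_path):
        samples = make_samples()
        m = make_matrix(
            {"p1": [float(i) for i in range(1, 13)],
             "p2": [100.0] * 12,
             "p3": [0.5] * 12},
        )
        m.calls.loc["p2"] = "A"
        write_expression_table(m, tmp_path / "expr.tsv", tmp_path / "meta.tsv")
        back = read_expression_table(tmp_path / "expr.tsv", tmp_path / "meta.tsv")
        pd.testing.assert_frame_equal(back.intensity, m.intensity)
        pd.testing.assert_frame_equal(back.calls, m.calls)
        assert back.samples == samples

    def test_duplicate_probe_id_rejected(self, tmp_path):
        samples = make_samples(replicates=1)
        header = ["probe_id"]
        for s in samples:
            header += [s.sample_id, f"{s.sample_id}_call"]
        row = ["p1"] + ["1.0", "P"] * len(samples)
        (tmp_path / "expr.tsv").write_text(
            "\t".join(header) + "\n" + "\t".join(row) + "\n" + "\t".join(row) + "\n"
        )
        meta = "sample_id\tgenotype\tstage\treplicate\n" + "".join(
            f"{s.sample_id}\t{s.genotype.value}\t{s.stage.value}\t{s.replicate}\n"
            for s in samples
        )
        (tmp_path / "meta.tsv").write_text(meta)
        with pytest.raises(ValueError, match="p1"):
            read_expression_table(tmp_path / "expr.tsv", tmp_path / "meta.tsv")

    def test_missing_stage_matched_control_rejected(self, tmp_path):
        # JAK_GOF present but no WT at its stage (only WT at E1_2)
        meta = (
            "sample_id\tgenotype\tstage\treplicate\n"
            "wt1\tWT\tE1_2\t1\n"
            "gof1\tJAK_GOF\tE0_12\t1\n"
        )
        (tmp_path / "meta.tsv").write_text(meta)
        with pytest.raises(ValueError, match="stage-matched WT"):
            read_metadata(tmp_path / "meta.tsv")

    def test_unknown_sample_named_in_error(self, tmp_path):
        samples = make_samples(replicates=1)
        m = make_matrix({"p1": [1.0] * len(samples)}, samples=samples)
        write_expression_table(m, tmp_path / "expr.tsv", tmp_path / "meta.tsv")
        df = pd.read_csv(tmp_path / "expr.tsv", sep="\t")
        df["rogue"] = 1.0
        df.to_csv(tmp_path / "expr.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="rogue"):
            read_expression_table(tmp_path / "expr.tsv", tmp_path / "meta.tsv")

    def test_non_numeric_intensity_located(self, tmp_path):
        samples = make_samples(replicates=1)
        m = make_matrix({"p1": [1.0] * len(samples)}, samples=samples)
        write_expression_table(m, tmp_path / "expr.tsv", tmp_path / "meta.tsv")
        df = pd.read_csv(tmp_path / "expr.tsv", sep="\t", dtype=str)
        df.loc[0, samples[0].sample_id] = "oops"
        df.to_csv(tmp_path / "expr.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match=samples[0].sample_id):
            read_expression_table(tmp_path / "expr.tsv", tmp_path / "meta.tsv")


class TestSampleMetadata:
    def test_mutant_stage_mismatch_rejected(self):
        with pytest.raises(ValueError, match="E1_2"):
            SampleMetadata("x", Genotype.STAT_MATNULL, Stage.E0_12, 1)

    def test_replicate_must_be_positive(self):
        with pytest.raises(ValueError, match="replicate"):
            SampleMetadata("x", Genotype.WT, Stage.E0_12, 0)


class TestFilterProbeSets:
    def _calls_matrix(self, gof_calls: str, wt_calls: str):
        """One probe; set calls for JAK_GOF samples and E0_12 WT samples."""
        samples = make_samples()
        m = make_matrix({"p": [50.0] * len(samples)}, samples=samples)
        for s in samples:
            if s.genotype is Genotype.JAK_GOF:
                m.calls.loc["p", s.sample_id] = gof_calls[s.replicate - 1]
            elif s.genotype is Genotype.WT and s.stage is Stage.E0_12:
                m.calls.loc["p", s.sample_id] = wt_calls[s.replicate - 1]
        return m

    def test_control_probe_removed_despite_present_calls(self):
        samples = make_samples()
        m = make_matrix(
            {"AFFX-Dros5S": [500.0] * len(samples), "p1": [500.0] * len(samples)},
            samples=samples,
        )
        out = filter_probe_sets(m, Genotype.JAK_GOF)
        assert out.probe_ids == ["p1"]

    def test_all_absent_in_wt_and_mutant_removed(self):
        m = self._calls_matrix("AA", "AA")
        assert filter_probe_sets(m, Genotype.JAK_GOF).probe_ids == []

    def test_single_present_call_retains(self):
        m = self._calls_matrix("PA", "AA")
        assert filter_probe_sets(m, Genotype.JAK_GOF).probe_ids == ["p"]

    def test_marginal_counts_as_detected(self):
        m = self._calls_matrix("MA", "AA")
        assert filter_probe_sets(m, Genotype.JAK_GOF).probe_ids == ["p"]

    def test_idempotent_and_never_adds(self):
        m = self._calls_matrix("PA", "AA")
        once = filter_probe_sets(m, Genotype.JAK_GOF)
        twice = filter_probe_sets(once, Genotype.JAK_GOF)
        assert twice.probe_ids == once.probe_ids
        assert set(once.probe_ids) <= set(m.probe_ids)

    def test_depends_only_on_mutant_and_matched_wt(self):
        m = self._calls_matrix("AA", "AA")
        # a Present call in an unrelated genotype must not rescue the probe
        m2 = self._calls_matrix("AA", "AA")
        for s in m2.samples:
            if s.genotype is Genotype.STAT_MATNULL:
                m2.calls.loc["p", s.sample_id] = "P"
        assert (
            filter_probe_sets(m, Genotype.JAK_GOF).probe_ids
            == filter_probe_sets(m2, Genotype.JAK_GOF).probe_ids
        )

    def test_wt_not_a_valid_target(self, toy_matrix):
        with pytest.raises(ValueError, match="mutant"):
            filter_probe_sets(toy_matrix, Genotype.WT)


def _minimal_bundle(contingency=None) -> ReportBundle:
    a, b = (70, 188)
    c, d = (156, 253)
    if contingency is not None:
        (a, b), (c, d) = contingency
    return ReportBundle(
        parameters={"cutoff_log2": 1.0},
        directional_counts={"JAK_GOF": {"up": 1, "down": 0}},
        venn_summaries=[],
        classification_counts={"canonical": a + b, "non_canonical": c + d},
        quadrant_counts={},
        heterochromatin_fractions={
            "canonical": {"combined": f"{a}/{a + b}"},
            "non_canonical": {"combined": f"{c}/{c + d}"},
        },
        contingency_table=[[a, b], [c, d]],
        odds_ratio=1.0,
        p_two_tailed=0.5,
    )


class TestReportBundle:
    def test_round_trip(self, tmp_path):
        bundle = _minimal_bundle()
        write_report(bundle, tmp_path / "report.json")
        back = read_report(tmp_path / "report.json")
        assert back.to_dict() == bundle.to_dict()

    def test_headline_fractions_at_three_decimals(self, tmp_path):
        bundle = _minimal_bundle([[70, 188], [156, 253]])
        write_report(bundle, tmp_path / "report.json")
        data = json.loads((tmp_path / "report.json").read_text())
        fr = data["heterochromatin_fractions"]
        assert round(float(Fraction(fr["canonical"]["combined"])), 3) == 0.271
        assert round(float(Fraction(fr["non_canonical"]["combined"])), 3) == 0.381

    def test_missing_field_named(self):
        data = _minimal_bundle().to_dict()
        del data["contingency_table"]
        with pytest.raises(ValueError, match="contingency_table"):
            ReportBundle.from_dict(data)

    def test_inconsistent_margin_rejected(self, tmp_path):
        bundle = _minimal_bundle()
        bundle.classification_counts["canonical"] += 1
        with pytest.raises(ValueError, match="margin"):
            write_report(bundle, tmp_path / "report.json")
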