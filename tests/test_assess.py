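"""Standardized bias/MSE assessment: anchors, identities, conditioning."""

import math

import numpy as np
import pandas as pd
import pytest

import enrichsel as es


class TestStandardizationAnchor:
    def test_unconditional_single_stage_bias_zero_rmse_one(
            self, ps3, eff3, design2_records):
        # Without selection or stopping the MLE is exactly normal with
        # SD 1/I, so the z-scored residual has mean 0 and RMS 1.
        for lab in ps3.member_labels:
            row = es.standardized_assessment(design2_records, ps3, eff3,
                                             lab, "none")
            n = row.n_cell
            assert row.bias_over_se == pytest.approx(0.0,
                                                     abs=3 / math.sqrt(n))
            assert row.rmse_over_se == pytest.approx(
                1.0, abs=3 / math.sqrt(2 * n))


class TestExactIdentities:
    def test_familywise_is_selection_weighted_average(self, ps3, eff3,
                                                      design2_records):
        fw = es.familywise_assessment(design2_records, ps3, eff3, "selected")
        weighted = 0.0
        for lab in ps3.member_labels:
            row = es.standardized_assessment(design2_records, ps3, eff3,
                                             lab, "selected")
            weighted += row.bias_over_se * row.proportion_pct / 100.0
        assert fw.bias_over_se == pytest.approx(weighted, abs=1e-10)

    def test_overall_is_stage_proportion_mixture(self, ps3, eff3,
                                                 design4_records):
        overall = es.standardized_assessment(design4_records, ps3, eff3,
                                             "S1", "selected", None)
        parts_bias = 0.0
        parts_msq = 0.0
        for k in (1, 2):
            row = es.standardized_assessment(design4_records, ps3, eff3,
                                             "S1", "selected", k)
            share = row.proportion_pct / overall.proportion_pct
            parts_bias += row.bias_over_se * share
            parts_msq += row.rmse_over_se ** 2 * share
        assert overall.bias_over_se == pytest.approx(parts_bias, abs=1e-10)
        assert overall.rmse_over_se == pytest.approx(math.sqrt(parts_msq),
                                                     abs=1e-10)

    def test_rmse_dominates_absolute_bias(self, ps3, eff3, design2_records):
        for cond in ("selected", "selected-rejected"):
            for lab in ps3.member_labels:
                row = es.standardized_assessment(design2_records, ps3, eff3,
                                                 lab, cond)
                assert row.rmse_over_se >= abs(row.bias_over_se)


class TestReportingBiasAmplification:
    def test_reporting_exceeds_selection_bias_under_null(self, ps2):
        # Conditioning additionally on a significant test can only pull
        # the estimator further into the tail under the global null.
        null = es.EffectConfig((0.0, 0.0))
        c = 2.178272
        b = es.Boundaries((c,), (c,))
        cfg = es.SimulationConfig(ps2, null, b, (400,), n_reps=400_000,
                                  seed=31)
        rec = es.simulate_trials(cfg)
        for lab in ps2.member_labels:
            sel = es.standardized_assessment(rec, ps2, null, lab, "selected")
            rep = es.standardized_assessment(rec, ps2, null, lab,
                                             "selected-rejected")
            assert abs(rep.bias_over_se) >= abs(sel.bias_over_se)

    def test_familywise_bias_vanishes_under_null_without_conditioning(
            self, ps2):
        null = es.EffectConfig((0.0, 0.0))
        b = es.Boundaries((2.178272,), (2.178272,))
        cfg = es.SimulationConfig(ps2, null, b, (400,), n_reps=400_000,
                                  seed=32)
        rec = es.simulate_trials(cfg)
        fw = es.familywise_assessment(rec, ps2, null, "none")
        assert fw.bias_over_se != 0.0  # a Monte-Carlo estimate, not a constant
        assert abs(fw.bias_over_se) <= 3 / math.sqrt(len(rec))


class TestEmptyCells:
    def test_empty_cell_yields_missing_row(self, ps2):
        rec = pd.DataFrame({
            "rep": [0, 1], "W": [1, 1], "M": [1, 1],
            "rejected": [True, False],
            "mle": [0.2, 0.1], "info_final": [5.0, 5.0],
            "mle_S1": [0.3, 0.2], "info_S1": [3.5, 3.5],
            "frozen_S1": [False, False],
            "mle_F": [0.2, 0.1], "info_F": [5.0, 5.0],
            "frozen_F": [False, False],
        })
        eff = es.EffectConfig((0.5, 0.0))
        row = es.standardized_assessment(rec, ps2, eff, "S1", "selected")
        assert row.n_cell == 0
        assert row.proportion_pct == 0.0
        assert math.isnan(row.bias_over_se) and math.isnan(row.rmse_over_se)

    def test_unknown_conditioning_rejected(self, ps2, eff_asthma):
        with pytest.raises(ValueError):
            es.standardized_assessment(pd.DataFrame(), ps2, eff_asthma,
                                       "S1", "sometimes")


class TestAssessmentTable:
    def test_single_stage_layout(self, ps3, eff3, design2_records):
        table = es.assessment_table(design2_records.head(10_000), ps3, eff3)
        # three conditioning rows per population plus two family-wise rows
        assert len(table) == 3 * 3 + 2
        assert list(table["population"].unique()) == ["S1", "S1+2", "F", "FW"]
        assert set(table["stage"]) == {"overall"}

    def test_two_stage_layout_has_stage_blocks(self, ps3, eff3,
                                               design4_records):
        table = es.assessment_table(design4_records.head(10_000), ps3, eff3)
        assert set(table["stage"]) == {1, 2, "overall"}
        assert len(table) == (3 * 3 + 2) * 3
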