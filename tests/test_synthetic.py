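"""Generator contracts: determinism, conservation, calibration, and the
expected statistical structure of every simulated input."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dflashkit import (SimConfig, PlacementError, fourpl, hts_layout,
                       plate_qc, simulate_dose_response,
                       simulate_flow_events, simulate_image_field,
                       simulate_kinetics, simulate_plate, simulate_screen)
from dflashkit.synthetic import _induction_course


class TestImageField:
    def test_mask_labels_and_truth_rows_in_bijection(self, default_cfg):
        field, truth = simulate_image_field(default_cfg, seed=3)
        labels = np.unique(truth.label_mask)
        labels = labels[labels > 0]
        assert list(labels) == list(range(1, len(truth.table) + 1))
        assert set(labels) == set(truth.table["id"])

    def test_planted_truth_equals_mask_mean(self, clean_cfg):
        cfg = dataclasses.replace(clean_cfg, n_nuclei_per_field=5)
        field, truth = simulate_image_field(cfg, induced=False, seed=1)
        assert truth.label_mask.max() == 5
        for row in truth.table.itertuples():
            mask = truth.label_mask == row.id
            egfp = field.egfp[mask].mean() - cfg.background_level
            tom = field.tom[mask].mean() - cfg.background_level
            assert egfp == pytest.approx(row.true_egfp, rel=0.02)
            assert tom == pytest.approx(row.true_tom, rel=0.02)

    def test_empty_field(self, clean_cfg):
        cfg = dataclasses.replace(clean_cfg, n_nuclei_per_field=0)
        field, truth = simulate_image_field(cfg, seed=0)
        assert truth.label_mask.max() == 0
        assert len(truth.table) == 0
        assert np.allclose(field.egfp, cfg.background_level)

    def test_bit_identical_for_same_config_and_seed(self, default_cfg):
        a_field, a_truth = simulate_image_field(default_cfg, True, seed=9)
        b_field, b_truth = simulate_image_field(default_cfg, True, seed=9)
        assert np.array_equal(a_field.egfp, b_field.egfp)
        assert np.array_equal(a_field.tom, b_field.tom)
        assert np.array_equal(a_truth.label_mask, b_truth.label_mask)
        pd.testing.assert_frame_equal(a_truth.table, b_truth.table)

    def test_induction_multiplies_responder_tomato(self, clean_cfg):
        cfg = dataclasses.replace(clean_cfg, n_nuclei_per_field=200,
                                  field_shape=(512, 512))
        _, off = simulate_image_field(cfg, induced=False, seed=5)
        _, on = simulate_image_field(cfg, induced=True, seed=5)
        assert on.table["induced_flag"].all()
        ratio = on.table["true_tom"].mean() / off.table["true_tom"].mean()
        assert ratio == pytest.approx(cfg.induction_fold, rel=0.15)

    def test_overcrowded_field_raises_placement_error(self, clean_cfg):
        cfg = dataclasses.replace(clean_cfg, field_shape=(48, 48),
                                  n_nuclei_per_field=50)
        with pytest.raises(PlacementError, match="48x48"):
            simulate_image_field(cfg, seed=0)

    def test_lognormal_calibration_over_1000_nuclei(self, clean_cfg):
        """Empirical EGFP mean/CV match the configured lognormal moments
        within 3 Monte-Carlo standard errors."""
        cfg = dataclasses.replace(clean_cfg, n_nuclei_per_field=150,
                                  field_shape=(640, 640))
        draws = []
        for seed in range(7):
            _, truth = simulate_image_field(cfg, seed=seed)
            draws.append(truth.table["true_egfp"].to_numpy())
        x = np.concatenate(draws)
        assert x.size >= 1000
        mean_expect = cfg.egfp_mean
        cv_expect = np.sqrt(np.exp(cfg.egfp_sigma ** 2) - 1.0)
        se_mean = x.std(ddof=1) / np.sqrt(x.size)
        assert abs(x.mean() - mean_expect) < 3 * se_mean
        cv_emp = x.std(ddof=1) / x.mean()
        # SE of the CV of a lognormal is approximately cv/sqrt(2n)
        assert abs(cv_emp - cv_expect) < 3 * cv_expect / np.sqrt(2 * x.size)


class TestPlate:
    def test_positive_to_vehicle_fold_matches_config(self, default_cfg):
        layout = hts_layout(n_plates=10, n_positive=6, n_vehicle=6)
        wells, _ = simulate_plate(default_cfg, layout, "tabular", seed=0)
        pos = wells[wells["role"] == "positive"]["ratio"].mean()
        veh = wells[wells["role"] == "vehicle"]["ratio"].mean()
        assert pos / veh == pytest.approx(default_cfg.induction_fold, abs=2)

    def test_zero_variance_limit_gives_exact_plates(self):
        cfg = SimConfig(well_cv=0.0, noise_sd=0.0)
        layout = hts_layout(n_plates=2, n_positive=4, n_vehicle=4)
        wells, _ = simulate_plate(cfg, layout, "tabular", seed=1)
        veh = wells[wells["role"] == "vehicle"]
        assert veh["ratio"].nunique() == 1
        assert veh["egfp_mean"].nunique() == 1
        for qc in plate_qc(wells):
            assert qc.zprime == 1.0
            assert qc.fold_change == pytest.approx(cfg.induction_fold)

    def test_unknown_role_rejected(self, default_cfg):
        layout = hts_layout(n_plates=1)
        layout.loc[0, "role"] = "mystery"
        with pytest.raises(ValueError, match="mystery"):
            simulate_plate(default_cfg, layout, "tabular", seed=0)

    def test_tabular_deterministic(self, default_cfg):
        layout = hts_layout(n_plates=3)
        a, _ = simulate_plate(default_cfg, layout, "tabular", seed=7)
        b, _ = simulate_plate(default_cfg, layout, "tabular", seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_image_mode_yields_fields_per_well(self, clean_cfg):
        cfg = dataclasses.replace(clean_cfg, n_nuclei_per_field=10,
                                  field_shape=(128, 128))
        layout = hts_layout(n_plates=1, n_positive=2, n_vehicle=2)
        fields, _ = simulate_plate(cfg, layout, "image", seed=0,
                                   n_fields_per_well=2)
        assert len(fields) == 4
        for well_fields in fields.values():
            assert len(well_fields) == 2
            for field, truth in well_fields:
                assert truth.label_mask.max() == len(truth.table) == 10


class TestScreen:
    def test_proportions_over_one_rejected(self, default_cfg):
        with pytest.raises(ValueError, match="> 1"):
            simulate_screen(default_cfg, 100, {"activator": 0.7,
                                               "inhibitor": 0.7})

    def test_truth_class_counts_sum_to_library(self, default_cfg):
        _, _, truth = simulate_screen(
            default_cfg, 500, {"activator": 0.02, "inhibitor": 0.04},
            seed=0)
        assert truth.class_counts().sum() == 500
        assert truth.class_counts()["activator"] == 10
        assert truth.class_counts()["inhibitor"] == 20

    def test_phase_tables_cover_library_once(self, default_cfg):
        p1, p2, truth = simulate_screen(default_cfg, 200, {}, seed=1)
        for table in p1 + p2:
            comp = table[table["role"] == "compound"]
            assert len(comp) == 200
            assert comp["compound_id"].is_unique

    def test_control_well_counts_per_phase(self, default_cfg):
        p1, p2, _ = simulate_screen(default_cfg, 84, {}, seed=2)
        c1 = p1[0]["role"].value_counts()
        c2 = p2[0]["role"].value_counts()
        assert (c1["vehicle"], c1["positive"]) == (4, 4)
        assert (c2["vehicle"], c2["positive"]) == (4, 8)

    def test_replicates_share_effects_with_independent_noise(
            self, default_cfg):
        p1, _, truth = simulate_screen(
            default_cfg, 300, {"activator": 0.1}, seed=3,
            effect_folds={"activator": 1.5})
        a = p1[0][p1[0]["role"] == "compound"].set_index("compound_id")
        b = p1[1][p1[1]["role"] == "compound"].set_index("compound_id")
        act = truth.table.loc[truth.table["true_class"] == "activator",
                              "compound_id"]
        assert (a.loc[act, "ratio"].mean()
                > 1.3 * a.drop(act)["ratio"].mean())
        # same planted effect, different noise
        assert not np.allclose(a["ratio"], b.loc[a.index, "ratio"])


class TestKinetics:
    def test_logistic_course_flat_then_plateau(self, default_cfg):
        t = np.arange(0.0, 38.1, 2.0)
        course = _induction_course(default_cfg, t)
        assert course[t < 6].max() < 1.1  # within noise of vehicle
        assert course[-1] == pytest.approx(default_cfg.kinetics_plateau,
                                           rel=0.01)

    def test_infinite_rate_is_step_at_onset(self, default_cfg):
        cfg = dataclasses.replace(default_cfg, kinetics_rate=np.inf)
        t = np.array([9.99, 10.0, 10.01])
        course = _induction_course(cfg, t)
        assert course[0] == 1.0
        assert course[1] == course[2] == cfg.kinetics_plateau

    def test_empty_or_unordered_timepoints_rejected(self, default_cfg):
        with pytest.raises(ValueError, match="non-empty"):
            simulate_kinetics(default_cfg, timepoints_h=[])
        with pytest.raises(ValueError, match="ascending"):
            simulate_kinetics(default_cfg, timepoints_h=[0, 4, 2])

    def test_reproducible_for_same_seed(self, default_cfg):
        a = simulate_kinetics(default_cfg, seed=8)
        b = simulate_kinetics(default_cfg, seed=8)
        pd.testing.assert_frame_equal(a, b)


class TestDoseResponse:
    def test_half_maximal_at_true_ec50_without_noise(self, default_cfg):
        cfg = dataclasses.replace(default_cfg, dr_noise_cv=0.0)
        table = simulate_dose_response(cfg, doses=[cfg.ec50_true],
                                       n_reps=3, seed=0)
        assert (table["response"] == 0.5).all()

    def test_response_tends_to_floor_at_low_dose(self, default_cfg):
        cfg = dataclasses.replace(default_cfg, dr_noise_cv=0.0)
        table = simulate_dose_response(cfg, doses=[1e-16], n_reps=1, seed=0)
        assert table["response"].iloc[0] == pytest.approx(0.0, abs=1e-4)

    def test_default_grid_has_72_rows(self, default_cfg):
        table = simulate_dose_response(default_cfg, n_reps=8, seed=0)
        assert len(table) == 72
        assert table["dose_molar"].nunique() == 9

    def test_nonpositive_dose_rejected(self, default_cfg):
        with pytest.raises(ValueError, match="> 0"):
            simulate_dose_response(default_cfg, doses=[0.0, 1e-9])


class TestFlowEvents:
    def test_null_treated_matches_control(self, default_cfg):
        events = simulate_flow_events(default_cfg, 10_000,
                                      responder_fraction=0.0, seed=1)
        control = events[events["sample"] == "control"]["tomato"]
        treated = events[events["sample"] == "treated"]["tomato"]
        assert stats.ks_2samp(control, treated).pvalue > 0.01

    def test_full_response_scales_median_by_fold(self, default_cfg):
        events = simulate_flow_events(default_cfg, 10_000,
                                      responder_fraction=1.0, seed=2)
        control = events[events["sample"] == "control"]["tomato"]
        treated = events[events["sample"] == "treated"]["tomato"]
        assert (treated.median() / control.median()
                == pytest.approx(default_cfg.induction_fold, rel=0.05))

    def test_default_event_count_is_10000_per_sample(self, default_cfg):
        events = simulate_flow_events(default_cfg, seed=0)
        assert (events["sample"].value_counts() == 10_000).all()

    def test_invalid_event_count_rejected(self, default_cfg):
        with pytest.raises(ValueError, match=">= 1"):
            simulate_flow_events(default_cfg, n_events=0)


def test_fourpl_midpoint_identity():
    assert fourpl(0.2e-9, 0.0, 1.0, 1.7, 0.2e-9) == pytest.approx(0.5)
    assert fourpl(3.0, -1.0, 5.0, -2.0, 3.0) == pytest.approx(2.0)
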