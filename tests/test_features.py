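"""Feature encoding: checkpoints, last-value selection, discretization, assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import akicausal as ak
from akicausal.features import (
    VITAL_BINS,
    UNKNOWN,
    bin_vital,
    categorize_lab,
    checkpoint_time,
    control_checkpoint,
    encode_binary,
    last_value_before,
    read_matrix,
    vital_states,
    write_matrix,
)

DAY = 24.0


class TestCheckpoint:
    def test_case_checkpoint_one_day_before_onset(self):
        assert checkpoint_time(0.0, 5 * DAY) == 4 * DAY

    def test_control_inherits_case_offset(self):
        # case admitted day 0, onset day 5 -> offset 4 days onto the control
        assert control_checkpoint(0.0, 10 * DAY, 4 * DAY) == 4 * DAY

    def test_control_checkpoint_capped_at_discharge(self):
        assert control_checkpoint(0.0, 3 * DAY, 4 * DAY) == 3 * DAY

    def test_checkpoint_before_admission_rejected(self):
        with pytest.raises(ValueError):
            checkpoint_time(0.0, 12.0)  # onset 12 h in: checkpoint would be negative

    def test_timestamp_arithmetic(self):
        adm = pd.Timestamp("2021-02-03 08:00")
        onset = adm + pd.Timedelta(days=5)
        assert checkpoint_time(adm, onset) == adm + pd.Timedelta(days=4)


class TestLastValueBefore:
    def test_latest_event_wins(self):
        assert last_value_before([(1.0, 98.6), (3.0, 101.0)], 4.0) == 101.0

    def test_absent_when_no_earlier_event(self):
        assert last_value_before([(5.0, 98.6)], 4.0) is None

    def test_boundary_is_strict(self):
        assert last_value_before([(3.999, 1.0), (4.0, 2.0)], 4.0) == 1.0


class TestLabCategorization:
    def test_in_range_is_normal(self):
        assert categorize_lab(7.0, (4.0, 11.0)) == "present-normal"

    def test_out_of_range_is_abnormal(self):
        assert categorize_lab(15.2, (4.0, 11.0)) == "present-abnormal"

    def test_missing_is_unknown(self):
        assert categorize_lab(None, (4.0, 11.0)) == "unknown"
        assert categorize_lab(float("nan"), (4.0, 11.0)) == "unknown"

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_lab(5.0, (11.0, 4.0))


class TestVitalBinning:
    @pytest.mark.parametrize(
        "name, value, expected",
        [
            ("bmi", 26.0, "[25.0-29.9]"),
            ("pulse", 50.0, "[50-65]"),
            ("diastolic_bp", 99.5, "[90-99]"),  # half-open [90, 100)
            ("diastolic_bp", 100.0, "> 100"),
            ("temperature", 99.5, "[99.5-104.0]"),
            ("systolic_bp", 119.9, "< 120"),
        ],
    )
    def test_bin_examples(self, name, value, expected):
        assert bin_vital(name, value) == expected

    def test_missing_maps_to_unknown(self):
        assert bin_vital("bmi", None) == UNKNOWN

    def test_unknown_vital_rejected(self):
        with pytest.raises(KeyError):
            bin_vital("heart_girth", 10.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        name=st.sampled_from(sorted(VITAL_BINS)),
        value=st.floats(min_value=0.0, max_value=300.0,
                        allow_nan=False, allow_infinity=False),
    )
    def test_bins_tile_the_real_line(self, name, value):
        # Every finite value maps to exactly one non-Unknown bin.
        label = bin_vital(name, value)
        assert label in vital_states(name)
        assert label != UNKNOWN


class TestBinaryEncoding:
    def test_event_before_checkpoint_is_yes(self):
        assert encode_binary([2 * DAY], 4 * DAY) == "yes"

    def test_event_after_checkpoint_is_no(self):
        assert encode_binary([5 * DAY], 4 * DAY) == "no"

    def test_time_independent_counts_regardless(self):
        assert encode_binary([5 * DAY], 4 * DAY, time_dependent=False) == "yes"

    def test_no_events_is_no(self):
        assert encode_binary([], 4 * DAY) == "no"


class TestAssembly:
    def test_matrix_shape_and_outcome(self, small_cohort):
        matrix = small_cohort["matrix"]
        spec = small_cohort["spec"]
        assert matrix.n == len(small_cohort["cohort"])
        assert len(matrix.features) == spec.n_features
        assert matrix.y.sum() == spec.n_cases

    def test_cells_match_generating_truth(self, small_cohort):
        matrix = small_cohort["matrix"]
        truth = small_cohort["truth"].feature_states.loc[matrix.encounter_ids]
        frame = matrix.to_frame(labels=True)
        assert list(frame.columns) == list(truth.columns)
        assert (frame == truth).all().all()

    def test_no_null_cells_and_valid_state_indices(self, small_cohort):
        matrix = small_cohort["matrix"]
        for j, feat in enumerate(matrix.features):
            col = matrix.cells[:, j]
            assert col.min() >= 0 and col.max() < feat.m

    def test_row_order_invariance(self, small_cohort):
        shuffled = small_cohort["cohort"].sample(frac=1.0, random_state=5)
        matrix2, _ = ak.assemble_matrix(shuffled, small_cohort["encounters"],
                                        small_cohort["events"])
        assert matrix2.encounter_ids == small_cohort["matrix"].encounter_ids
        assert np.array_equal(matrix2.cells, small_cohort["matrix"].cells)

    def test_empty_cohort_yields_empty_matrix(self, small_cohort):
        empty = small_cohort["cohort"].iloc[0:0]
        matrix, log = ak.assemble_matrix(empty, small_cohort["encounters"],
                                         small_cohort["events"])
        assert matrix.n == 0

    def test_matrix_roundtrip_through_csv(self, small_cohort, tmp_path):
        matrix = small_cohort["matrix"]
        write_matrix(matrix, tmp_path / "cells.csv", tmp_path / "dict.csv")
        back = read_matrix(tmp_path / "cells.csv", tmp_path / "dict.csv")
        assert back.encounter_ids == matrix.encounter_ids
        assert [f.name for f in back.features] == [f.name for f in matrix.features]
        assert np.array_equal(back.cells, matrix.cells)
        assert np.array_equal(back.y, matrix.y)

    def test_duplicate_feature_across_categories_rejected(self, small_cohort):
        events = small_cohort["events"]
        med = events[events["category"] == "medication"].iloc[[0]]
        clash = med.assign(category="history")
        events = pd.concat([events, clash], ignore_index=True)
        with pytest.raises(ValueError, match="multiple categories"):
            ak.assemble_matrix(small_cohort["cohort"], small_cohort["encounters"], events)
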