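"""Cohort rules: baseline SCr, KDIGO staging, exclusions, matching."""

import numpy as np
import pandas as pd
import pytest

from akicausal.cohort import (
    AkiStage,
    BaselineScr,
    UMOL_PER_MGDL,
    apply_exclusions,
    compute_baseline,
    match_controls,
    stage_aki,
)

ADM = 0.0  # hours; the staging functions accept numeric hours or Timestamps


def brute_force_stage(values, baseline):
    """Independent transcription of the KDIGO creatinine criteria."""
    per_measurement = []
    for v in values:
        met = 0
        if v - baseline > 0.3 or v / baseline >= 1.5:
            met = 1
        if 2.0 <= v / baseline < 3.0:
            met = 2
        if v / baseline >= 3.0 or v > 4.0:
            met = 3
        per_measurement.append(met)
    return max(per_measurement, default=0)


class TestBaseline:
    def test_pre_admission_window_takes_priority(self):
        base = compute_baseline([-30.0, 2.0], [1.1, 0.9], ADM)
        assert base.value == 1.1
        assert base.source == "pre-admission-window"

    def test_single_inpatient_value(self):
        base = compute_baseline([1.0], [0.8], ADM)
        assert base.value == 0.8
        assert base.source == "first-inpatient"

    def test_stale_pre_admission_value_is_ignored(self):
        # -60 h is outside the 48 h window; first inpatient value wins.
        base = compute_baseline([-60.0, 5.0], [1.4, 1.0], ADM)
        assert base.value == 1.0
        assert base.source == "first-inpatient"

    def test_timestamp_inputs(self):
        adm = pd.Timestamp("2020-05-01 08:00")
        times = [adm - pd.Timedelta(hours=30), adm + pd.Timedelta(hours=2)]
        base = compute_baseline(times, [1.1, 0.9], adm)
        assert base.value == 1.1

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            compute_baseline([], [], ADM)

    def test_non_increasing_timestamps_rejected(self):
        with pytest.raises(ValueError):
            compute_baseline([2.0, 2.0], [1.0, 1.1], ADM)


class TestStaging:
    @pytest.mark.parametrize(
        "baseline, peak, expected",
        [
            (1.0, 3.1, 3),   # 3x baseline
            (1.0, 1.25, 0),  # increase 0.25 <= 0.3 and ratio < 1.5
            (0.8, 1.15, 1),  # absolute increase 0.35 > 0.3
            (1.0, 2.0, 2),   # ratio exactly 2.0 opens the stage-2 band
            (1.0, 1.5, 1),   # ratio exactly 1.5 opens the stage-1 band
            (1.0, 4.05, 3),  # absolute value above 4.0 mg/dL
        ],
    )
    def test_threshold_cases(self, baseline, peak, expected):
        result = stage_aki([1.0, 10.0], [baseline, peak], BaselineScr(baseline, "first-inpatient"))
        assert result.stage == expected

    def test_onset_is_first_qualifying_measurement(self):
        base = BaselineScr(1.0, "first-inpatient")
        result = stage_aki([1.0, 5.0, 9.0, 20.0], [1.0, 3.2, 3.6, 2.0], base)
        assert result.stage == 3
        assert result.onset_time == 5.0

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(9)
        base = BaselineScr(1.0, "first-inpatient")
        for _ in range(200):
            values = np.round(rng.uniform(0.3, 5.0, size=rng.integers(1, 8)), 2)
            times = np.arange(1.0, len(values) + 1)
            got = stage_aki(times, values, base)
            assert got.stage == brute_force_stage(values, 1.0)

    def test_unit_coherence_umol_vs_mgdl(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            values = rng.uniform(0.4, 5.0, size=5)
            times = np.arange(1.0, 6.0)
            base = BaselineScr(float(values[0]), "first-inpatient")
            direct = stage_aki(times, values, base)
            converted = stage_aki(times, values * UMOL_PER_MGDL / UMOL_PER_MGDL, base)
            assert direct.stage == converted.stage

    def test_raising_a_measurement_never_lowers_the_stage(self):
        rng = np.random.default_rng(11)
        base = BaselineScr(1.0, "first-inpatient")
        for _ in range(100):
            values = list(rng.uniform(0.4, 4.5, size=5))
            before = stage_aki(np.arange(5.0), values, base).stage
            i = rng.integers(0, 5)
            values[i] += float(rng.uniform(0.1, 2.0))
            after = stage_aki(np.arange(5.0), values, base).stage
            assert after >= before

    def test_stage_zero_has_no_onset(self):
        result = stage_aki([1.0], [1.0], BaselineScr(1.0, "first-inpatient"))
        assert result == AkiStage(stage=0, onset_time=None)


def _encounters(rows):
    return pd.DataFrame(rows, columns=["encounter_id", "age", "gender", "race",
                                       "admission", "discharge", "egfr_admission"])


def _scr(rows):
    return pd.DataFrame(rows, columns=["encounter_id", "time", "scr_mgdl"])


class TestExclusions:
    ADM = pd.Timestamp("2020-01-01 08:00")

    def _enc(self, eid, egfr=85.0, stay_days=5):
        return [eid, 60.0, "F", "white", self.ADM, self.ADM + pd.Timedelta(days=stay_days), egfr]

    def test_single_scr_measurement_excluded(self):
        enc = _encounters([self._enc("e1")])
        scr = _scr([["e1", self.ADM + pd.Timedelta(hours=2), 1.0]])
        kept, log = apply_exclusions(enc, scr)
        assert kept.empty
        assert log.iloc[0]["reason"] == "insufficient_scr"

    def test_abnormal_admission_scr_excluded(self):
        enc = _encounters([self._enc("e1")])
        scr = _scr([["e1", self.ADM + pd.Timedelta(hours=6), 1.4],
                    ["e1", self.ADM + pd.Timedelta(hours=48), 1.0]])
        kept, log = apply_exclusions(enc, scr)
        assert log.iloc[0]["reason"] == "abnormal_admission_scr"

    def test_low_egfr_excluded(self):
        enc = _encounters([self._enc("e1", egfr=45.0)])
        scr = _scr([["e1", self.ADM + pd.Timedelta(hours=2), 1.0],
                    ["e1", self.ADM + pd.Timedelta(hours=30), 1.1]])
        _, log = apply_exclusions(enc, scr)
        assert log.iloc[0]["reason"] == "low_egfr"

    def test_normal_encounter_retained(self):
        enc = _encounters([self._enc("e1", egfr=75.0)])
        scr = _scr([["e1", self.ADM + pd.Timedelta(hours=2), 1.0],
                    ["e1", self.ADM + pd.Timedelta(hours=30), 1.1],
                    ["e1", self.ADM + pd.Timedelta(hours=60), 0.9]])
        kept, log = apply_exclusions(enc, scr)
        assert list(kept["encounter_id"]) == ["e1"]
        assert log.empty


def _people(rows):
    return pd.DataFrame(rows, columns=["encounter_id", "age", "gender", "race"])


class TestMatching:
    def test_nearest_age_control_wins(self):
        cases = _people([["c1", 60.0, "F", "white"]])
        controls = _people([["k1", 58.0, "F", "white"], ["k2", 70.0, "F", "white"]])
        res = match_controls(cases, controls, caliper_years=15.0)
        assert list(res.pairs["control_id"]) == ["k1"]

    def test_exact_gender_race_required(self):
        cases = _people([["c1", 40.0, "M", "asian"]])
        controls = _people([["k1", 40.0, "F", "asian"], ["k2", 40.0, "F", "white"]])
        res = match_controls(cases, controls)
        assert res.pairs.empty
        assert res.unmatched_cases == ["c1"]

    def test_caliper_excludes_distant_ages(self):
        cases = _people([["c1", 60.0, "F", "white"]])
        controls = _people([["k1", 70.0, "F", "white"]])
        res = match_controls(cases, controls, caliper_years=5.0)
        assert res.unmatched_cases == ["c1"]

    def test_age_gap_ties_break_on_lowest_control_id(self):
        cases = _people([["c1", 60.0, "F", "white"]])
        controls = _people([["k2", 62.0, "F", "white"], ["k1", 58.0, "F", "white"]])
        res = match_controls(cases, controls)
        assert list(res.pairs["control_id"]) == ["k1"]

    def test_invariant_to_control_row_order(self):
        rng = np.random.default_rng(3)
        cases = _people([[f"c{i}", 50.0 + i, "F", "white"] for i in range(5)])
        controls = _people([[f"k{i}", 50.0 + i + 0.4, "F", "white"] for i in range(8)])
        res1 = match_controls(cases, controls)
        shuffled = controls.sample(frac=1.0, random_state=int(rng.integers(1000)))
        res2 = match_controls(cases, shuffled)
        assert res1.pairs.equals(res2.pairs)

    def test_positive_caliper_required(self):
        with pytest.raises(ValueError):
            match_controls(_people([]), _people([]), caliper_years=0.0)
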