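"""Generator contracts: determinism, planted truth, staging consistency."""

import numpy as np
import pandas as pd
import pytest

import akicausal as ak
from akicausal.synthetic import SpecError, generate_anm_instance


class TestSpecValidation:
    def test_negative_arm_rejected(self):
        with pytest.raises(SpecError, match="n_cases"):
            ak.SyntheticSpec(n_cases=-1).validate()

    def test_flip_probability_range(self):
        with pytest.raises(SpecError, match="noise_flip_prob"):
            ak.SyntheticSpec(noise_flip_prob=0.5).validate()

    def test_cyclic_confounders_rejected(self):
        spec = ak.SyntheticSpec(confounder_edges=(("a", "b"), ("b", "a")))
        with pytest.raises(SpecError, match="confounder_edges"):
            spec.validate()

    def test_state_counts_minimum(self):
        with pytest.raises(SpecError, match="state_counts"):
            ak.SyntheticSpec(state_counts={"noise_0001": 1}).validate()


class TestDeterminism:
    def test_equal_seeds_equal_tables(self):
        spec = ak.SyntheticSpec(n_cases=10, n_controls=10, n_features=40, seed=7)
        first = ak.generate_cohort(spec)
        second = ak.generate_cohort(spec)
        for a, b in zip(first[:3], second[:3]):
            pd.testing.assert_frame_equal(a, b)
        assert first[3].feature_states.equals(second[3].feature_states)

    def test_different_seeds_differ(self):
        a = ak.generate_cohort(ak.SyntheticSpec(n_cases=10, n_controls=10, n_features=40, seed=1))
        b = ak.generate_cohort(ak.SyntheticSpec(n_cases=10, n_controls=10, n_features=40, seed=2))
        assert not a[1].equals(b[1])


class TestCohortTruth:
    def test_empty_case_arm(self):
        spec = ak.SyntheticSpec(n_cases=0, n_controls=10, n_features=40, seed=3)
        encounters, _scr, _events, truth = ak.generate_cohort(spec)
        assert len(encounters) == 10
        assert set(truth.intended_stage.values()) == {0}

    def test_truth_records_planted_causes(self):
        spec = ak.SyntheticSpec(n_cases=15, n_controls=15, n_features=50, seed=4)
        *_tables, truth = ak.generate_cohort(spec)
        assert truth.planted_causes == [c.name for c in spec.planted_causes]
        assert len(truth.planted_causes) == 4

    def test_independent_restaging_recovers_intended_stage(self, small_cohort):
        """Applying the staging engine to the generated SCr series must
        reproduce the generator's intended stage and onset for every
        encounter."""
        truth = small_cohort["truth"]
        staged = ak.stage_cohort(small_cohort["encounters"], small_cohort["scr"])
        for row in staged.itertuples(index=False):
            assert row.stage == truth.intended_stage[row.encounter_id]
            if row.stage == 3:
                assert row.onset_time == truth.intended_onset[row.encounter_id]

    def test_all_generated_encounters_survive_exclusions(self, small_cohort):
        assert small_cohort["exclusions"].empty

    def test_full_matching_by_construction(self, small_cohort):
        assert len(small_cohort["match"].pairs) == small_cohort["spec"].n_cases


class TestNetworkTruth:
    def test_chain_markov_blanket(self):
        spec = ak.SyntheticSpec(
            n_features=10, n_samples=200, seed=1,
            planted_causes=(ak.PlantedCause("A", {"yes": 4.0}, 0.4),),
            outcome_children=(("B", None),), outcome_model="logistic", base_rate=0.2)
        _m, _y, truth = ak.generate_discrete_network(spec)
        assert truth.markov_blanket == {"A", "B"}
        assert set(truth.graph.predecessors("y")) == {"A"}
        assert set(truth.graph.successors("y")) == {"B"}

    def test_parents_children_spouses_blanket(self):
        spec = ak.SyntheticSpec(
            n_features=12, n_samples=200, seed=1,
            planted_causes=(ak.PlantedCause("A", {"yes": 4.0}, 0.4),
                            ak.PlantedCause("B", {"yes": 4.0}, 0.4)),
            outcome_children=(("C", "S"),), outcome_model="logistic", base_rate=0.2)
        _m, _y, truth = ak.generate_discrete_network(spec)
        assert truth.markov_blanket == {"A", "B", "C", "S"}

    def test_planted_cause_has_positive_marginal_odds_ratio(self):
        spec = ak.SyntheticSpec(
            n_features=6, n_samples=2000, seed=1, outcome_model="logistic",
            planted_causes=tuple(ak.PlantedCause(f"c{i}", {"yes": 3.0}, 0.3) for i in range(4)),
            base_rate=0.15)
        matrix, y, truth = ak.generate_discrete_network(spec)
        for name in truth.planted_causes:
            x = matrix.column(name)
            a = np.sum((x == 1) & (y == 1)); b = np.sum((x == 1) & (y == 0))
            c = np.sum((x == 0) & (y == 1)); d = np.sum((x == 0) & (y == 0))
            assert (a * d) / (b * c) > 1.0

    def test_unit_multiplier_means_no_signal(self):
        spec = ak.SyntheticSpec(
            n_features=6, n_samples=5000, seed=2, outcome_model="logistic",
            planted_causes=tuple(ak.PlantedCause(f"c{i}", {"yes": 1.0}, 0.3) for i in range(4)),
            base_rate=0.15)
        matrix, y, _truth = ak.generate_discrete_network(spec)
        x = matrix.column("c0")
        a = np.sum((x == 1) & (y == 1)); b = np.sum((x == 1) & (y == 0))
        c = np.sum((x == 0) & (y == 1)); d = np.sum((x == 0) & (y == 0))
        assert abs(np.log((a * d) / (b * c))) < 0.35


class TestEvents:
    def test_decoy_medication_events_fall_after_checkpoints(self, small_cohort):
        events = small_cohort["events"]
        enc = small_cohort["encounters"].set_index("encounter_id")
        meds = events[(events["category"] == "medication") & events["time"].notna()]
        offsets = [
            (row.time - enc.loc[row.encounter_id, "admission"]) / pd.Timedelta(hours=1)
            for row in meds.itertuples(index=False)
        ]
        # events are either early (2-40 h, before any checkpoint >= 52 h)
        # or decoys on day 7+ (after any checkpoint <= 116 h)
        assert all(h <= 40.0 or h >= 168.0 for h in offsets)


class TestAnmInstance:
    def test_noise_is_independent_by_construction(self):
        cols, y, f_table = generate_anm_instance(500, seed=1)
        assert set(np.unique(y)) <= {0, 1, 2}
        assert len(f_table) == 6

    def test_deterministic(self):
        a = generate_anm_instance(200, seed=9)
        b = generate_anm_instance(200, seed=9)
        assert np.array_equal(a[1], b[1])
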