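import pytest

import akicausal as ak


@pytest.fixture(scope="session")
def small_cohort():
    """A small generated cohort with everything downstream computed once."""
    spec = ak.SyntheticSpec(n_cases=30, n_controls=30, n_features=60, seed=11)
    encounters, scr, events, truth = ak.generate_cohort(spec)
    cohort, exclusions, match = ak.build_matched_cohort(encounters, scr)
    matrix, drop_log = ak.assemble_matrix(cohort, encounters, events)
    return {
        "spec": spec,
        "encounters": encounters,
        "scr": scr,
        "events": events,
        "truth": truth,
        "cohort": cohort,
        "exclusions": exclusions,
        "match": match,
        "matrix": matrix,
        "drop_log": drop_log,
    }


@pytest.fixture(scope="session")
def mb_network():
    """A network with a size-4 Markov blanket: two parents, child, spouse."""
    spec = ak.SyntheticSpec(
        n_features=104,
        n_samples=3000,
        seed=7,
        planted_causes=(
            ak.PlantedCause("par_a", {"yes": 8.0}, 0.4),
            ak.PlantedCause("par_b", {"yes": 8.0}, 0.4),
        ),
        outcome_children=(("child_c", "spouse_s"),),
        base_rate=0.15,
        outcome_model="logistic",
    )
    matrix, y, truth = ak.generate_discrete_network(spec)
    return matrix, truth
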