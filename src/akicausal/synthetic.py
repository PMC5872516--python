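"""Synthetic EHR cohorts with a known planted causal structure.

Two generators share one discrete causal model:

``generate_discrete_network``
    Samples a flat feature matrix + outcome from a discrete Bayesian network
    (planted cause -> outcome edges, optional outcome children with spouses,
    optional confounder edges among features).  Ground truth — the generating
    graph and the outcome's Markov blanket — is returned alongside, so
    structure- and direction-learning can be scored exactly.

``generate_cohort``
    Wraps the same model in EHR-shaped long tables: an encounters table with
    demographics and admission eGFR, a serum-creatinine table whose
    trajectories realize each encounter's intended KDIGO stage (stage 3 for
    cases, stage 0 for controls), and a feature-event table that the feature
    builder can re-code back into the generating states.

The outcome mechanism is table-parameterized through per-cause odds
multipliers.  In ``"logistic"`` mode the outcome is Bernoulli with
logit = logit(base_rate) + sum of log-multipliers.  In the default ``"anm"``
mode the outcome is the thresholded logistic table XOR a constant flip noise
(``noise_flip_prob``) — i.e. an exact discrete additive-noise mechanism,
which is the data-generating assumption of the direction-learning phase.
Either way the planted signal vanishes as multipliers -> 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .features import (
    AGE_BAND_LABELS,
    BINARY_STATES,
    DEFAULT_LAB_RANGES,
    GENDER_STATES,
    LAB_STATES,
    RACE_STATES,
    UNKNOWN,
    VITAL_BINS,
    VITAL_NAMES,
    age_band,
    vital_states,
)

__all__ = [
    "SpecError",
    "PlantedCause",
    "DemographicsModel",
    "ScrModel",
    "SyntheticSpec",
    "NetworkTruth",
    "CohortTruth",
    "generate_discrete_network",
    "generate_cohort",
]

EPOCH = pd.Timestamp("2015-01-01 08:00:00")


class SpecError(ValueError):
    """Invalid synthetic specification; names the offending field."""

    def __init__(self, fld: str, message: str):
        self.field = fld
        super().__init__(f"{fld}: {message}")


@dataclass(frozen=True)
class PlantedCause:
    """A binary cause of the outcome with per-state odds multipliers."""

    name: str
    multipliers: Mapping[str, float] = field(default_factory=lambda: {"yes": 6.0})
    prevalence: float = 0.2


@dataclass(frozen=True)
class DemographicsModel:
    age_mean: float = 60.0
    age_sd: float = 12.0
    age_min: float = 22.0
    age_max: float = 90.0
    gender_probs: tuple[float, ...] = (0.5, 0.5)          # F, M
    race_probs: tuple[float, ...] = (0.1, 0.2, 0.1, 0.6)  # asian, black, other, white


@dataclass(frozen=True)
class ScrModel:
    """Baseline SCr distribution (mg/dL) and per-stage trajectory shape."""

    baseline_mean: float = 0.85
    baseline_sd: float = 0.12
    baseline_low: float = 0.6
    baseline_high: float = 1.1
    onset_ratio: float = 3.3   # ratio at the intended stage-3 onset measurement
    peak_ratio: float = 3.5    # strictly inside the stage-3 region, below 4.0 mg/dL absolute
    control_jitter: float = 0.08


def _default_causes() -> tuple[PlantedCause, ...]:
    return tuple(PlantedCause(f"med_{i:04d}") for i in range(1, 5))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic run.

    Defaults mirror the target regime: 179 stage-3 cases matched 1:1 to
    never-AKI controls, ~200 categorical features, four planted medication
    causes.  ``n_samples`` applies only to flat network generation.
    """

    n_cases: int = 179
    n_controls: int = 179
    n_features: int = 200
    planted_causes: tuple[PlantedCause, ...] = field(default_factory=_default_causes)
    confounder_edges: tuple[tuple[str, str], ...] = ()
    state_counts: Mapping[str, int] = field(default_factory=dict)
    noise_flip_prob: float = 0.08
    base_rate: float = 0.08
    outcome_model: str = "anm"  # "anm" | "logistic"
    outcome_children: tuple[tuple[str, Optional[str]], ...] = ()
    demographics: DemographicsModel = field(default_factory=DemographicsModel)
    scr: ScrModel = field(default_factory=ScrModel)
    n_samples: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0:
            raise SpecError("n_cases", "must be >= 0")
        if self.n_controls < 0:
            raise SpecError("n_controls", "must be >= 0")
        if not 0.0 <= self.noise_flip_prob < 0.5:
            raise SpecError("noise_flip_prob", "must be in [0, 0.5)")
        if not 0.0 < self.base_rate < 1.0:
            raise SpecError("base_rate", "must be in (0, 1)")
        if self.outcome_model not in ("anm", "logistic"):
            raise SpecError("outcome_model", "must be 'anm' or 'logistic'")
        names = [c.name for c in self.planted_causes]
        if len(set(names)) != len(names):
            raise SpecError("planted_causes", "duplicate cause names")
        for c in self.planted_causes:
            if not 0.0 < c.prevalence < 1.0:
                raise SpecError("planted_causes", f"{c.name}: prevalence must be in (0, 1)")
            if any(m <= 0 for m in c.multipliers.values()):
                raise SpecError("planted_causes", f"{c.name}: multipliers must be positive")
        for name, m in self.state_counts.items():
            if m < 2:
                raise SpecError("state_counts", f"{name}: every m_i must be >= 2")
        g = nx.DiGraph(list(self.confounder_edges))
        if not nx.is_directed_acyclic_graph(g):
            raise SpecError("confounder_edges", "must form a DAG")
        if self.n_samples < 1:
            raise SpecError("n_samples", "must be >= 1")


# ---------------------------------------------------------------------------
# Shared causal model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _FeatureDef:
    name: str
    category: str
    states: tuple[str, ...]
    probs: tuple[float, ...]  # base (root) distribution over states


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _sample_features(
    defs: Sequence[_FeatureDef],
    edges: Sequence[tuple[str, str]],
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample feature columns (int state codes) in topological order.

    A confounder edge u -> v (binary v) shifts v's log-odds by +1.2 when u
    is in its last ("yes"/highest) state.
    """
    by_name = {d.name: d for d in defs}
    graph = nx.DiGraph()
    graph.add_nodes_from(by_name)
    graph.add_edges_from(edges)
    data: dict[str, np.ndarray] = {}
    for name in nx.lexicographical_topological_sort(graph):
        d = by_name[name]
        parents = sorted(graph.predecessors(name))
        if not parents:
            data[name] = rng.choice(len(d.states), size=n, p=np.asarray(d.probs))
        else:
            if len(d.states) != 2:
                raise SpecError("confounder_edges", f"target {name!r} must be binary")
            logit0 = _logit(min(max(d.probs[1], 1e-6), 1 - 1e-6))
            shift = np.zeros(n)
            for p in parents:
                pd_def = by_name[p]
                shift += 1.2 * (data[p] == len(pd_def.states) - 1)
            data[name] = (rng.random(n) < _sigmoid(logit0 + shift)).astype(np.int64)
    return pd.DataFrame({d.name: data[d.name] for d in defs})


def _outcome(spec: SyntheticSpec, defs: Sequence[_FeatureDef], frame: pd.DataFrame,
             rng: np.random.Generator,
             flips: tuple[float, float] | None = None) -> np.ndarray:
    """Sample the outcome from its planted parents (vectorized).

    ``flips`` overrides the constant flip probability with separate rates
    for f=0 and f=1 rows (used for case-control noise calibration).
    """
    by_name = {d.name: d for d in defs}
    logit = np.full(len(frame), _logit(spec.base_rate))
    for cause in spec.planted_causes:
        states = by_name[cause.name].states
        mult = np.asarray([float(cause.multipliers.get(s, 1.0)) for s in states])
        logit = logit + np.log(mult)[frame[cause.name].to_numpy()]
    p = _sigmoid(logit)
    if spec.outcome_model == "logistic":
        return (rng.random(len(p)) < p).astype(np.int8)
    f = (p > 0.5).astype(np.int8)
    if flips is None:
        rate = np.full(len(p), spec.noise_flip_prob)
    else:
        rate = np.where(f == 1, flips[1], flips[0])
    noise = (rng.random(len(p)) < rate).astype(np.int8)
    return f ^ noise


def _calibrate_case_control_flips(spec: SyntheticSpec) -> tuple[float, float]:
    """Population flip rates that leave the matched sample an exact ANM.

    Sampling equal numbers of cases and controls multiplies every state's
    outcome odds by the constant (1-P(y))/P(y).  A population-constant flip
    probability therefore becomes state-dependent after balancing and the
    noise would no longer be independent of the causes *in the analysis
    sample*.  This solves for per-f flip rates (a for f=0 states, b for f=1)
    such that the balanced sample's conditional outcome probabilities are
    exactly ``noise_flip_prob`` and ``1 - noise_flip_prob``.
    """
    delta = spec.noise_flip_prob
    if delta == 0.0 or not spec.planted_causes:
        return (delta, delta)
    # P(f = 1) by exact enumeration over the joint cause states (causes are
    # binary roots in cohort mode).
    pi1 = 0.0
    k = len(spec.planted_causes)
    for states in itertools.product((0, 1), repeat=k):
        prob, logit = 1.0, _logit(spec.base_rate)
        for s, cause in zip(states, spec.planted_causes):
            prob *= cause.prevalence if s else 1.0 - cause.prevalence
            logit += float(np.log(cause.multipliers.get(BINARY_STATES[s], 1.0)))
        if logit > 0.0:
            pi1 += prob
    if pi1 <= 0.0 or pi1 >= 1.0:
        return (delta, delta)  # constant f: nothing to calibrate

    a, b = delta, delta
    for _ in range(500):
        p_y = (1.0 - pi1) * a + pi1 * (1.0 - b)
        r = p_y / (1.0 - p_y)  # inverse of the balancing odds shift
        odds0 = delta / (1.0 - delta) * r
        odds1 = (1.0 - delta) / delta * r
        a_new = odds0 / (1.0 + odds0)
        b_new = 1.0 - odds1 / (1.0 + odds1)
        if abs(a_new - a) + abs(b_new - b) < 1e-12:
            a, b = a_new, b_new
            break
        a, b = a_new, b_new
    return (a, b)


# ---------------------------------------------------------------------------
# Flat network generation
# ---------------------------------------------------------------------------

@dataclass
class NetworkTruth:
    graph: nx.DiGraph
    planted_causes: list[str]
    markov_blanket: set[str]


def _network_defs(spec: SyntheticSpec, rng: np.random.Generator) -> list[_FeatureDef]:
    defs: list[_FeatureDef] = []
    for cause in spec.planted_causes:
        defs.append(_FeatureDef(cause.name, "cause", BINARY_STATES,
                                (1.0 - cause.prevalence, cause.prevalence)))
    named = {d.name for d in defs}
    spouses = [s for _, s in spec.outcome_children if s is not None and s not in named]
    for s in spouses:
        defs.append(_FeatureDef(s, "spouse", BINARY_STATES, (0.5, 0.5)))
        named.add(s)

    n_noise = spec.n_features - len(named) - len(spec.outcome_children)
    if n_noise < 0:
        raise SpecError("n_features", "fewer features than planted structure requires")
    for i in range(1, n_noise + 1):
        name = f"noise_{i:04d}"
        m = int(spec.state_counts.get(name, 2))
        if m == 2:
            p1 = float(rng.uniform(0.1, 0.5))
            defs.append(_FeatureDef(name, "noise", BINARY_STATES, (1.0 - p1, p1)))
        else:
            w = rng.uniform(0.5, 1.5, size=m)
            states = tuple(f"s{j}" for j in range(m))
            defs.append(_FeatureDef(name, "noise", states, tuple(w / w.sum())))
    return defs


def generate_discrete_network(spec: SyntheticSpec):
    """Sample n_samples rows of (features, outcome) from the planted network.

    Returns (FeatureMatrix, outcome vector, truth).  The truth graph
    contains cause->y, y->child, spouse->child, and confounder edges; the
    recorded Markov blanket of y is parents ∪ children ∪ spouses.
    """
    spec.validate()
    rng_def = np.random.default_rng([spec.seed, 101])
    rng_data = np.random.default_rng([spec.seed, 102])
    defs = _network_defs(spec, rng_def)
    names = {d.name for d in defs}
    for u, v in spec.confounder_edges:
        if u not in names or v not in names:
            raise SpecError("confounder_edges", f"unknown feature in edge ({u}, {v})")

    n = spec.n_samples
    frame = _sample_features(defs, spec.confounder_edges, n, rng_data)
    y = _outcome(spec, defs, frame, rng_data)

    # Children of the outcome (with optional spouse co-parents).
    for child, spouse in spec.outcome_children:
        logit = -1.2 + 2.5 * y.astype(float)
        if spouse is not None:
            logit = logit + 2.5 * (frame[spouse].to_numpy() == 1)
        frame[child] = (rng_data.random(n) < _sigmoid(logit)).astype(np.int64)

    graph = nx.DiGraph()
    graph.add_nodes_from(list(frame.columns) + ["y"])
    graph.add_edges_from(spec.confounder_edges)
    for cause in spec.planted_causes:
        graph.add_edge(cause.name, "y")
    mb = {c.name for c in spec.planted_causes}
    for child, spouse in spec.outcome_children:
        graph.add_edge("y", child)
        mb.add(child)
        if spouse is not None:
            graph.add_edge(spouse, child)
            mb.add(spouse)
    truth = NetworkTruth(graph=graph, planted_causes=[c.name for c in spec.planted_causes],
                         markov_blanket=mb)

    from .features import CategoricalFeature, FeatureMatrix  # local: avoid cycle at import time

    states_of = {d.name: d.states for d in defs}
    for child, _spouse in spec.outcome_children:
        states_of[child] = BINARY_STATES
    feats = [CategoricalFeature(name, "network", tuple(states_of[name]))
             for name in frame.columns]
    matrix = FeatureMatrix(
        encounter_ids=[f"row_{i + 1:05d}" for i in range(n)],
        features=feats,
        cells=frame.to_numpy(dtype=np.int16),
        y=np.asarray(y, dtype=np.int8),
    )
    return matrix, y, truth


def generate_anm_instance(
    n: int,
    seed: int,
    component_m: Sequence[int] = (2, 3),
    m_y: int = 3,
    noise_prob: float = 0.2,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """A planted many-to-one discrete additive-noise instance.

    Components are independent categorical variables; the effect is
    y = (f(x̄) + N) mod m_y with a random non-constant state map f and noise
    N in {-1, 0, +1} (P(±1) = noise_prob/2 each), independent of x̄ by
    construction.  Returns (component columns, y, f table indexed by the
    1-based converted state).
    """
    rng = np.random.default_rng([seed, 301])
    cols = []
    for m in component_m:
        w = rng.uniform(0.6, 1.4, size=m)
        cols.append(rng.choice(m, size=n, p=w / w.sum()))
    m_bar = int(np.prod(component_m))
    f_table = rng.integers(0, m_y, size=m_bar)
    while len(np.unique(f_table)) < 2:
        f_table = rng.integers(0, m_y, size=m_bar)
    xbar = np.zeros(n, dtype=np.int64)
    for col, m in zip(cols, component_m):
        xbar = xbar * m + col
    noise = rng.choice([-1, 0, 1], size=n,
                       p=[noise_prob / 2, 1.0 - noise_prob, noise_prob / 2])
    y = np.mod(f_table[xbar] + noise, m_y)
    return cols, y.astype(np.int64), f_table


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortTruth:
    """Ground truth for one generated cohort."""

    planted_causes: list[str]
    graph_edges: list[tuple[str, str]]
    intended_stage: dict[str, int]
    intended_onset: dict[str, object]       # case encounter -> onset timestamp
    feature_states: pd.DataFrame            # intended state labels incl. demographics
    y: pd.Series

    def to_manifest(self) -> dict:
        return {
            "planted_causes": list(self.planted_causes),
            "graph_edges": [list(e) for e in self.graph_edges],
            "n_encounters": int(len(self.feature_states)),
            "intended_stage": {k: int(v) for k, v in sorted(self.intended_stage.items())},
        }


def _cohort_defs(spec: SyntheticSpec, rng: np.random.Generator) -> list[_FeatureDef]:
    """EHR-shaped feature roster: vitals, labs, and binary clinical variables.

    Demographics (3) are carried on the encounters table; the roster covers
    the remaining n_features - 3 columns.  Planted causes must be medication
    variables and are placed first among the medications.
    """
    n_clinical = spec.n_features - 3 - len(VITAL_NAMES) - len(DEFAULT_LAB_RANGES)
    if n_clinical < len(spec.planted_causes):
        raise SpecError("n_features", "too small for vitals, labs and planted causes")

    defs: list[_FeatureDef] = []
    for name in VITAL_NAMES:
        states = vital_states(name)
        w = rng.uniform(0.5, 1.5, size=len(states) - 1)
        probs = np.append(w / w.sum() * 0.9, 0.1)  # 10% Unknown
        defs.append(_FeatureDef(name, "vitals", states, tuple(probs)))
    for name in sorted(DEFAULT_LAB_RANGES):
        p_norm = float(rng.uniform(0.55, 0.75))
        p_abn = float(rng.uniform(0.1, 0.25))
        defs.append(_FeatureDef(name, "lab", LAB_STATES, (p_norm, p_abn, 1.0 - p_norm - p_abn)))

    cause_names = {c.name for c in spec.planted_causes}
    n_med = max(len(cause_names), round(0.60 * n_clinical))
    n_hx = round(0.20 * n_clinical)
    n_cmb = round(0.12 * n_clinical)
    n_adx = n_clinical - n_med - n_hx - n_cmb
    if n_adx < 0:
        raise SpecError("n_features", "allocation across binary categories failed")

    for cause in spec.planted_causes:
        defs.append(_FeatureDef(cause.name, "medication", BINARY_STATES,
                                (1.0 - cause.prevalence, cause.prevalence)))
    counters = {"medication": len(cause_names)}
    for category, prefix, count in (
        ("medication", "med", n_med - len(cause_names)),
        ("history", "hx", n_hx),
        ("comorbidity", "cmb", n_cmb),
        ("admission_dx", "adx", n_adx),
    ):
        start = counters.get(category, 0)
        for i in range(start + 1, start + count + 1):
            name = f"{prefix}_{i:04d}"
            if name in cause_names:
                raise SpecError("planted_causes", f"cause name {name!r} collides with roster")
            p1 = float(rng.uniform(0.05, 0.4))
            defs.append(_FeatureDef(name, category, BINARY_STATES, (1.0 - p1, p1)))
    return defs


def _sample_case_control(spec: SyntheticSpec, defs: Sequence[_FeatureDef],
                         rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Rejection-sample rows until the case and control arms are filled."""
    flips = _calibrate_case_control_flips(spec) if spec.outcome_model == "anm" else None
    need_cases, need_controls = spec.n_cases, spec.n_controls
    got_cases: list[pd.DataFrame] = []
    got_controls: list[pd.DataFrame] = []
    n_case, n_ctrl = 0, 0
    batch = max(1000, 2 * (need_cases + need_controls))
    for _ in range(400):
        if n_case >= need_cases and n_ctrl >= need_controls:
            break
        frame = _sample_features(defs, spec.confounder_edges, batch, rng)
        y = _outcome(spec, defs, frame, rng, flips=flips)
        if n_case < need_cases:
            got_cases.append(frame[y == 1])
            n_case += int((y == 1).sum())
        if n_ctrl < need_controls:
            got_controls.append(frame[y == 0])
            n_ctrl += int((y == 0).sum())
    if n_case < need_cases or n_ctrl < need_controls:
        raise SpecError("base_rate", "could not fill both study arms; outcome rate too extreme")

    cases = pd.concat(got_cases).head(need_cases) if got_cases else pd.DataFrame(columns=[d.name for d in defs])
    controls = pd.concat(got_controls).head(need_controls) if got_controls else pd.DataFrame(columns=[d.name for d in defs])
    frame = pd.concat([cases, controls]).reset_index(drop=True)
    y = np.concatenate([np.ones(need_cases, dtype=np.int8), np.zeros(need_controls, dtype=np.int8)])
    return frame, y


def _vital_representatives(name: str) -> list[float]:
    edges, _labels = VITAL_BINS[name]
    reps = [edges[0] - 2.0]
    reps += [(a + b) / 2.0 for a, b in zip(edges, edges[1:])]
    reps.append(edges[-1] + 2.0)
    return reps


def _lab_representatives(name: str) -> tuple[float, float]:
    low, high = DEFAULT_LAB_RANGES[name]
    return (low + high) / 2.0, high + 0.5 * (high - low) + 0.01


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Generate (encounters, scr_measurements, feature_events, truth).

    Case encounters carry SCr trajectories that KDIGO staging classifies as
    stage 3 (onset at the intended time); controls classify as stage 0.  All
    encounters pass the exclusion rules by construction.  For every case a
    demographically compatible control (same gender/race, age within 2 y) is
    generated so that 1:1 matching can succeed.
    """
    spec.validate()
    cause_names = {c.name for c in spec.planted_causes}
    for _u, v in spec.confounder_edges:
        if v in cause_names:
            raise SpecError("confounder_edges",
                            "planted causes must be root features in cohort mode")
    rng_def = np.random.default_rng([spec.seed, 201])
    rng_data = np.random.default_rng([spec.seed, 202])
    rng_demo = np.random.default_rng([spec.seed, 203])
    rng_scr = np.random.default_rng([spec.seed, 204])
    rng_event = np.random.default_rng([spec.seed, 205])

    defs = _cohort_defs(spec, rng_def)
    frame, y = _sample_case_control(spec, defs, rng_data)
    n = len(frame)
    ids = [f"enc_{i + 1:05d}" for i in range(n)]

    # --- demographics: controls 1..n_cases mirror the cases so matching works
    dm = spec.demographics
    ages = np.clip(rng_demo.normal(dm.age_mean, dm.age_sd, size=n), dm.age_min, dm.age_max)
    genders = rng_demo.choice(list(GENDER_STATES), size=n, p=np.asarray(dm.gender_probs))
    races = rng_demo.choice(list(RACE_STATES), size=n, p=np.asarray(dm.race_probs))
    mirror = min(spec.n_cases, spec.n_controls)
    for j in range(mirror):
        c, k = j, spec.n_cases + j
        genders[k] = genders[c]
        races[k] = races[c]
        ages[k] = ages[c]  # exact-age mirror: a perfect 1:1 matching always exists
    ages = np.round(ages, 1)

    # --- admission calendar
    adm_days = rng_demo.integers(0, 2000, size=n)
    admissions = [EPOCH + pd.Timedelta(days=int(d)) for d in adm_days]
    stay_h = rng_demo.uniform(8 * 24, 12 * 24, size=n)
    discharges = [a + pd.Timedelta(hours=float(h)) for a, h in zip(admissions, stay_h)]
    onset_h = rng_demo.uniform(76.0, 140.0, size=n)  # cases only

    encounters = pd.DataFrame(
        {
            "encounter_id": ids,
            "age": ages,
            "gender": genders,
            "race": races,
            "admission": admissions,
            "discharge": discharges,
            "egfr_admission": np.round(np.clip(rng_demo.normal(92.0, 8.0, size=n), 65.0, 130.0), 1),
        }
    )

    # --- serum creatinine trajectories realizing the intended stage
    sm = spec.scr
    baselines = np.round(np.clip(rng_scr.normal(sm.baseline_mean, sm.baseline_sd, size=n),
                                 sm.baseline_low, sm.baseline_high), 2)
    has_pre = rng_scr.random(n) < 0.5
    scr_rows: list[tuple[str, pd.Timestamp, float]] = []
    intended_stage: dict[str, int] = {}
    intended_onset: dict[str, object] = {}
    for i, eid in enumerate(ids):
        adm, b = admissions[i], float(baselines[i])
        pts: list[tuple[float, float]] = [(-30.0, b)] if has_pre[i] else []
        if y[i] == 1:
            t_on = float(onset_h[i])
            pts += [(2.0, b), (18.0, round(1.05 * b, 3)), (t_on - 30.0, round(1.3 * b, 3)),
                    (t_on, round(sm.onset_ratio * b, 3)), (t_on + 24.0, round(sm.peak_ratio * b, 3)),
                    (stay_h[i] - 12.0, round(2.0 * b, 3))]
            intended_stage[eid] = 3
            intended_onset[eid] = adm + pd.Timedelta(hours=t_on)
        else:
            j1, j2, j3 = rng_scr.uniform(0.0, sm.control_jitter, size=3)
            pts += [(2.0, b), (30.0, round(b * (1 + j1), 3)), (80.0, round(b * (1 - j2), 3)),
                    (130.0, round(b * (1 + j3), 3))]
            intended_stage[eid] = 0
        scr_rows += [(eid, adm + pd.Timedelta(hours=t), v) for t, v in pts]
    scr = pd.DataFrame(scr_rows, columns=["encounter_id", "time", "scr_mgdl"])

    # --- long-format feature events consistent with the sampled states
    events = _emit_events(defs, frame, ids, admissions, rng_event)

    # --- ground truth, including the demographic columns the builder derives
    truth_states = {
        "age_band": [age_band(a) for a in ages],
        "gender": list(genders),
        "race": list(races),
    }
    for d in defs:
        col = frame[d.name].to_numpy()
        truth_states[d.name] = [d.states[s] for s in col]
    feature_states = pd.DataFrame(truth_states, index=pd.Index(ids, name="encounter_id"))
    # Match the feature builder's column convention: demographics, vitals,
    # labs (sorted), then binary clinical features sorted by name.
    binary_names = sorted(d.name for d in defs if d.category not in ("vitals", "lab"))
    ordered = (["age_band", "gender", "race"] + list(VITAL_NAMES)
               + sorted(DEFAULT_LAB_RANGES) + binary_names)
    feature_states = feature_states[ordered]

    graph_edges = [(c.name, "y") for c in spec.planted_causes] + list(spec.confounder_edges)
    truth = CohortTruth(
        planted_causes=[c.name for c in spec.planted_causes],
        graph_edges=graph_edges,
        intended_stage=intended_stage,
        intended_onset=intended_onset,
        feature_states=feature_states,
        y=pd.Series(y, index=feature_states.index, name="y"),
    )
    return encounters, scr, events, truth


def _emit_events(defs: Sequence[_FeatureDef], frame: pd.DataFrame, ids: Sequence[str],
                 admissions: Sequence[pd.Timestamp], rng: np.random.Generator) -> pd.DataFrame:
    """Write the sampled states out as timestamped raw events.

    Time-dependent events land 2-40 h after admission — before any possible
    checkpoint (>= 48 h) — so the feature builder recovers the intended
    states exactly.  A fraction of negative medications get a decoy dispense
    on day 7, after every possible checkpoint, to exercise the time cut.
    """
    n = len(ids)
    rows: list[tuple] = []
    adm_arr = np.asarray(admissions, dtype=object)
    for d in defs:
        col = frame[d.name].to_numpy()
        hours = rng.uniform(2.0, 40.0, size=n)
        if d.category == "vitals":
            reps = _vital_representatives(d.name)
            for i in np.flatnonzero(col < len(d.states) - 1):  # last state = Unknown
                rows.append((ids[i], adm_arr[i] + pd.Timedelta(hours=float(hours[i])),
                             d.name, d.category, reps[col[i]]))
        elif d.category == "lab":
            rep_norm, rep_abn = _lab_representatives(d.name)
            for i in np.flatnonzero(col != 2):  # state 2 = unknown
                value = rep_norm if col[i] == 0 else rep_abn
                rows.append((ids[i], adm_arr[i] + pd.Timedelta(hours=float(hours[i])),
                             d.name, d.category, value))
        else:
            time_dep = d.category in ("medication", "history")
            decoy = (col == 0) & (rng.random(n) < 0.1) if d.category == "medication" else np.zeros(n, dtype=bool)
            for i in np.flatnonzero(col == 1):
                t = adm_arr[i] + pd.Timedelta(hours=float(hours[i])) if time_dep else pd.NaT
                rows.append((ids[i], t, d.name, d.category, 1.0))
            for i in np.flatnonzero(decoy):
                t = adm_arr[i] + pd.Timedelta(hours=float(168.0 + hours[i]))
                rows.append((ids[i], t, d.name, d.category, 1.0))
    events = pd.DataFrame(rows, columns=["encounter_id", "time", "feature", "category", "value"])
    return events.sort_values(["encounter_id", "feature", "time"], kind="stable").reset_index(drop=True)
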