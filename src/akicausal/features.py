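"""Categorical feature-matrix construction.

Clinical predictors are frozen at a per-encounter *checkpoint* — 24 h before
stage-3 AKI onset for cases, with the same admission-relative offset
transferred to the matched control — and every variable is coded into a small
categorical alphabet:

* medications / history / comorbidities / admission diagnoses: ``yes``/``no``
* laboratory tests: ``present-normal`` / ``present-abnormal`` / ``unknown``
  against a configurable reference range
* vital signs: the standard clinical bins (plus ``Unknown``)
* demographics: gender, race, and age discretized into decade bands

Missingness is never left as a null cell: it always resolves to an explicit
``unknown``/``Unknown`` state, so the matrix is fully observed and every
downstream contingency-table computation is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CategoricalFeature",
    "FeatureMatrix",
    "BINARY_STATES",
    "LAB_STATES",
    "VITAL_BINS",
    "AGE_BAND_EDGES",
    "AGE_BAND_LABELS",
    "DEFAULT_LAB_RANGES",
    "checkpoint_time",
    "control_checkpoint",
    "last_value_before",
    "categorize_lab",
    "bin_vital",
    "encode_binary",
    "age_band",
    "assemble_matrix",
]

# ---------------------------------------------------------------------------
# State vocabularies
# ---------------------------------------------------------------------------

BINARY_STATES: tuple[str, ...] = ("no", "yes")
LAB_STATES: tuple[str, ...] = ("present-normal", "present-abnormal", "unknown")
UNKNOWN = "Unknown"

# Vital-sign bins. Printed bin labels leave gaps at their boundaries (e.g.
# diastolic "[90-99]" vs "> 100"); bins are implemented as a left-closed
# right-open tiling of the real line whose internal edges are the lower bounds
# of the printed bins, so every finite value maps to exactly one bin.
VITAL_BINS: dict[str, tuple[tuple[float, ...], tuple[str, ...]]] = {
    "bmi": ((18.5, 25.0, 30.0), ("< 18.5", "[18.5-24.9]", "[25.0-29.9]", "> 30.0")),
    "diastolic_bp": ((80.0, 90.0, 100.0), ("< 80", "[80-89]", "[90-99]", "> 100")),
    "systolic_bp": ((120.0, 140.0, 160.0), ("< 120", "[120-139]", "[140-159]", "> 160")),
    "pulse": ((50.0, 66.0, 81.0, 100.0), ("< 50", "[50-65]", "[66-80]", "[81-100]", "> 100")),
    "temperature": (
        (95.0, 97.7, 99.5, 104.0),
        ("< 95.0", "[95.0-97.6]", "[97.7-99.5]", "[99.5-104.0]", "> 104.0"),
    ),
}

VITAL_NAMES: tuple[str, ...] = tuple(VITAL_BINS)

# Age is discretized into decade bands so that, like every other predictor,
# it enters the analysis as a small categorical variable.
AGE_BAND_EDGES: tuple[float, ...] = (30.0, 40.0, 50.0, 60.0, 70.0, 80.0)
AGE_BAND_LABELS: tuple[str, ...] = (
    "< 30", "[30-39]", "[40-49]", "[50-59]", "[60-69]", "[70-79]", ">= 80",
)

GENDER_STATES: tuple[str, ...] = ("F", "M")
RACE_STATES: tuple[str, ...] = ("asian", "black", "other", "white")

# Default reference ranges for the shipped laboratory panel (standard adult
# ranges; all configurable through `assemble_matrix(lab_ranges=...)`).
DEFAULT_LAB_RANGES: dict[str, tuple[float, float]] = {
    "albumin": (3.5, 5.0),        # g/dL
    "alt": (7.0, 56.0),           # U/L
    "ast": (10.0, 40.0),          # U/L
    "ammonia": (15.0, 45.0),      # µg/dL
    "bilirubin": (0.1, 1.2),      # mg/dL
    "bun": (7.0, 20.0),           # mg/dL
    "calcium": (8.5, 10.2),       # mg/dL
    "ck": (22.0, 198.0),          # U/L
    "ck_mb": (0.0, 5.0),          # ng/mL
    "glucose": (70.0, 140.0),     # mg/dL
    "lipase": (0.0, 160.0),       # U/L
    "platelets": (150.0, 400.0),  # 10^3/µL
    "troponin": (0.0, 0.04),      # ng/mL
    "wbc": (4.0, 11.0),           # 10^3/µL
}

#: Categories whose variables are binary yes/no.
BINARY_CATEGORIES: tuple[str, ...] = ("medication", "history", "comorbidity", "admission_dx")
#: Categories that ignore the checkpoint (available at admission).
TIME_INDEPENDENT_CATEGORIES: tuple[str, ...] = ("comorbidity", "admission_dx", "demographics")

CHECKPOINT_LEAD_HOURS = 24.0  # prediction point: one day before stage-3 onset


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoricalFeature:
    """One column of the feature matrix with its ordered state alphabet."""

    name: str
    category: str
    states: tuple[str, ...]
    time_dependent: bool = True

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError(f"feature {self.name!r} needs >= 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"feature {self.name!r} has duplicate state labels")

    @property
    def m(self) -> int:
        """Number of states of this feature."""
        return len(self.states)

    def index_of(self, label: str) -> int:
        return self.states.index(label)


@dataclass
class FeatureMatrix:
    """Encounters x categorical features, cells as state indices, binary outcome."""

    encounter_ids: list[str]
    features: list[CategoricalFeature]
    cells: np.ndarray  # (n, p) int16 state indices
    y: np.ndarray      # (n,) int {0, 1}
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {f.name: j for j, f in enumerate(self.features)}
        if len(self._index) != len(self.features):
            raise ValueError("duplicate feature names in matrix")
        n, p = self.cells.shape
        if n != len(self.encounter_ids) or p != len(self.features):
            raise ValueError("cell block shape does not match ids/features")
        for j, f in enumerate(self.features):
            col = self.cells[:, j]
            if n and (col.min() < 0 or col.max() >= f.m):
                raise ValueError(f"state index out of range for feature {f.name!r}")

    @property
    def n(self) -> int:
        return len(self.encounter_ids)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def feature(self, name: str) -> CategoricalFeature:
        return self.features[self._index[name]]

    def column(self, name: str) -> np.ndarray:
        """Integer-coded column for one feature."""
        return self.cells[:, self._index[name]]

    def to_frame(self, labels: bool = True) -> pd.DataFrame:
        """Matrix as a DataFrame (state labels by default, indices otherwise)."""
        if labels:
            data = {
                f.name: np.asarray(f.states, dtype=object)[self.cells[:, j]]
                for j, f in enumerate(self.features)
            }
        else:
            data = {f.name: self.cells[:, j] for j, f in enumerate(self.features)}
        return pd.DataFrame(data, index=pd.Index(self.encounter_ids, name="encounter_id"))

    def feature_dictionary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [f.name for f in self.features],
                "category": [f.category for f in self.features],
                "states": ["|".join(f.states) for f in self.features],
                "m": [f.m for f in self.features],
                "time_dependent": [f.time_dependent for f in self.features],
            }
        )


# ---------------------------------------------------------------------------
# Elementary coding operations
# ---------------------------------------------------------------------------

def checkpoint_time(admission, onset_time):
    """Prediction point of a case encounter: 24 h before stage-3 onset.

    Raises ``ValueError`` if the checkpoint would precede admission (such
    encounters are dropped, with a log entry, at matrix-assembly level).
    """
    cp = onset_time - _delta_hours(CHECKPOINT_LEAD_HOURS, onset_time)
    if cp < admission:
        raise ValueError("checkpoint precedes admission")
    return cp


def control_checkpoint(admission, discharge, case_offset):
    """Prediction point of a matched control.

    The matched case's admission-to-checkpoint offset is applied to the
    control's own admission, capped at the control's discharge.
    """
    cp = admission + case_offset
    return min(cp, discharge)


def _delta_hours(hours: float, like):
    """A duration of `hours`, as a Timedelta when timestamps are datetimes."""
    if isinstance(like, (pd.Timestamp, np.datetime64)):
        return pd.Timedelta(hours=hours)
    return hours


def last_value_before(events: Iterable[tuple], checkpoint):
    """Latest (timestamp, value) event strictly before the checkpoint, or None."""
    best_t, best_v = None, None
    for t, v in events:
        if t < checkpoint and (best_t is None or t > best_t):
            best_t, best_v = t, v
    return best_v


def categorize_lab(value, reference_range: tuple[float, float]) -> str:
    """Three-state lab coding: present-normal / present-abnormal / unknown."""
    low, high = reference_range
    if not low < high:
        raise ValueError(f"inverted reference range ({low}, {high})")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    return "present-normal" if low <= value <= high else "present-abnormal"


def bin_vital(name: str, value) -> str:
    """Map a vital-sign value to its categorical bin (missing -> Unknown)."""
    if name not in VITAL_BINS:
        raise KeyError(f"unknown vital {name!r}")
    edges, labels = VITAL_BINS[name]
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNKNOWN
    return labels[int(np.searchsorted(edges, value, side="right"))]


def encode_binary(event_times: Iterable, checkpoint, time_dependent: bool = True) -> str:
    """yes/no coding: yes iff a qualifying event exists at/before the checkpoint.

    Time-independent categories (comorbidities, admission diagnoses) count
    events regardless of timing.
    """
    for t in event_times:
        if not time_dependent or _is_na(t) or t <= checkpoint:
            return "yes"
    return "no"


def age_band(age: float) -> str:
    """Decade band of an age in years."""
    return AGE_BAND_LABELS[int(np.searchsorted(AGE_BAND_EDGES, age, side="right"))]


def _is_na(t) -> bool:
    return t is None or (isinstance(t, float) and np.isnan(t)) or t is pd.NaT


def vital_states(name: str) -> tuple[str, ...]:
    """Full ordered alphabet of a vital feature (bins then Unknown)."""
    return VITAL_BINS[name][1] + (UNKNOWN,)


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

def _checkpoints(cohort: pd.DataFrame, encounters: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Per-encounter checkpoints with offset transfer to matched controls.

    Returns (checkpoints indexed by encounter_id, log of dropped encounters).
    """
    enc = encounters.set_index("encounter_id")
    cp: dict[str, object] = {}
    dropped: list[dict] = []
    offsets: dict[str, object] = {}  # pair id -> case admission->checkpoint offset

    cases = cohort[cohort["stage"] == 3]
    for row in cases.itertuples(index=False):
        adm = enc.loc[row.encounter_id, "admission"]
        try:
            point = checkpoint_time(adm, row.onset_time)
        except ValueError:
            dropped.append({"encounter_id": row.encounter_id, "reason": "checkpoint_before_admission"})
            continue
        cp[row.encounter_id] = point
        offsets[row.matched_pair_id] = point - adm

    controls = cohort[cohort["stage"] != 3]
    for row in controls.itertuples(index=False):
        if row.matched_pair_id not in offsets:
            dropped.append({"encounter_id": row.encounter_id, "reason": "case_checkpoint_missing"})
            continue
        adm = enc.loc[row.encounter_id, "admission"]
        dis = enc.loc[row.encounter_id, "discharge"]
        cp[row.encounter_id] = control_checkpoint(adm, dis, offsets[row.matched_pair_id])

    log = pd.DataFrame(dropped, columns=["encounter_id", "reason"])
    return pd.Series(cp, name="checkpoint"), log


def assemble_matrix(
    cohort: pd.DataFrame,
    encounters: pd.DataFrame,
    events: pd.DataFrame,
    lab_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Build the encounters x features categorical matrix.

    Parameters
    ----------
    cohort : DataFrame with encounter_id, stage, onset_time, matched_pair_id.
    encounters : DataFrame with encounter_id, age, gender, race, admission, discharge.
    events : long-format DataFrame with encounter_id, time, feature, category, value.
    lab_ranges : reference ranges per lab; defaults to the shipped panel.

    Returns
    -------
    (FeatureMatrix, drop log) — the log lists encounters removed because no
    valid checkpoint existed.
    """
    lab_ranges = dict(lab_ranges if lab_ranges is not None else DEFAULT_LAB_RANGES)
    for name, (low, high) in lab_ranges.items():
        if not low < high:
            raise ValueError(f"inverted reference range for lab {name!r}")

    checkpoints, drop_log = _checkpoints(cohort, encounters)
    kept = cohort[cohort["encounter_id"].isin(checkpoints.index)].copy()
    kept = kept.sort_values("encounter_id", kind="stable").reset_index(drop=True)
    ids = kept["encounter_id"].tolist()
    y = (kept["stage"] == 3).to_numpy(dtype=np.int8)

    if kept.empty:
        return FeatureMatrix(encounter_ids=[], features=_demographic_features(), cells=np.zeros((0, 3), dtype=np.int16), y=y), drop_log

    enc = encounters.set_index("encounter_id").loc[ids]

    ev = events[events["encounter_id"].isin(ids)].copy()
    ev["checkpoint"] = ev["encounter_id"].map(checkpoints)
    time_na = ev["time"].isna()
    before_strict = ev["time"] < ev["checkpoint"]
    at_or_before = ev["time"] <= ev["checkpoint"]

    features: list[CategoricalFeature] = _demographic_features()
    columns: list[np.ndarray] = [
        _codes_from_labels([age_band(a) for a in enc["age"]], AGE_BAND_LABELS),
        _codes_from_labels(list(enc["gender"]), GENDER_STATES),
        _codes_from_labels(list(enc["race"]), RACE_STATES),
    ]

    row_of = {eid: i for i, eid in enumerate(ids)}
    n = len(ids)

    # Vitals: last strictly-before-checkpoint value, binned; missing -> Unknown.
    for name in VITAL_NAMES:
        states = vital_states(name)
        values = _last_numeric(ev, name, before_strict, row_of, n)
        labels = [bin_vital(name, v) for v in values]
        features.append(CategoricalFeature(name, "vitals", states, time_dependent=True))
        columns.append(_codes_from_labels(labels, states))

    # Labs: last strictly-before-checkpoint value vs reference range.
    for name in sorted(lab_ranges):
        values = _last_numeric(ev, name, before_strict, row_of, n)
        labels = [categorize_lab(v, lab_ranges[name]) for v in values]
        features.append(CategoricalFeature(name, "lab", LAB_STATES, time_dependent=True))
        columns.append(_codes_from_labels(labels, LAB_STATES))

    # Binary categories: yes iff a qualifying event exists. Time-independent
    # categories ignore the checkpoint entirely.
    binary = ev[ev["category"].isin(BINARY_CATEGORIES)]
    names = binary[["feature", "category"]].drop_duplicates()
    dup = names["feature"].duplicated()
    if dup.any():
        raise ValueError(f"feature(s) in multiple categories: {sorted(names['feature'][dup])}")
    for feat_name, category in sorted(names.itertuples(index=False)):
        time_dep = category not in TIME_INDEPENDENT_CATEGORIES
        sel = binary["feature"] == feat_name
        qualifying = sel & (time_na | at_or_before) if time_dep else sel
        yes_rows = {row_of[e] for e in binary.loc[qualifying, "encounter_id"]}
        col = np.zeros(n, dtype=np.int16)
        col[list(yes_rows)] = 1
        features.append(CategoricalFeature(feat_name, category, BINARY_STATES, time_dependent=time_dep))
        columns.append(col)

    cells = np.column_stack(columns).astype(np.int16)
    matrix = FeatureMatrix(encounter_ids=ids, features=features, cells=cells, y=y)
    return matrix, drop_log


def _demographic_features() -> list[CategoricalFeature]:
    return [
        CategoricalFeature("age_band", "demographics", AGE_BAND_LABELS, time_dependent=False),
        CategoricalFeature("gender", "demographics", GENDER_STATES, time_dependent=False),
        CategoricalFeature("race", "demographics", RACE_STATES, time_dependent=False),
    ]


def _codes_from_labels(labels: Sequence[str], states: Sequence[str]) -> np.ndarray:
    lut = {s: i for i, s in enumerate(states)}
    try:
        return np.asarray([lut[v] for v in labels], dtype=np.int16)
    except KeyError as err:
        raise ValueError(f"state label {err.args[0]!r} not in alphabet {tuple(states)}") from None


def write_matrix(matrix: FeatureMatrix, cells_path, dict_path) -> None:
    """Persist a FeatureMatrix as two CSVs: label cells (+outcome) and the
    feature dictionary."""
    frame = matrix.to_frame(labels=True)
    frame["y"] = matrix.y
    frame.to_csv(cells_path)
    matrix.feature_dictionary().to_csv(dict_path, index=False)


def read_matrix(cells_path, dict_path) -> FeatureMatrix:
    """Load a FeatureMatrix written by :func:`write_matrix`."""
    dictionary = pd.read_csv(dict_path)
    frame = pd.read_csv(cells_path, index_col="encounter_id", dtype=str)
    y = frame.pop("y").astype(int).to_numpy(dtype=np.int8)
    features = [
        CategoricalFeature(
            name=row.feature,
            category=row.category,
            states=tuple(str(row.states).split("|")),
            time_dependent=bool(row.time_dependent),
        )
        for row in dictionary.itertuples(index=False)
    ]
    columns = [
        _codes_from_labels(list(frame[f.name]), f.states) for f in features
    ]
    cells = np.column_stack(columns).astype(np.int16) if features else np.zeros((len(frame), 0), dtype=np.int16)
    return FeatureMatrix(encounter_ids=list(frame.index), features=features, cells=cells, y=y)


def _last_numeric(ev: pd.DataFrame, feature: str, mask: pd.Series, row_of: Mapping[str, int], n: int) -> list:
    """Per-row last recorded numeric value of one feature (NaN when absent)."""
    sub = ev[(ev["feature"] == feature) & mask]
    out = [np.nan] * n
    if not sub.empty:
        sub = sub.sort_values("time", kind="stable")
        last = sub.groupby("encounter_id", sort=False).tail(1)
        for eid, val in zip(last["encounter_id"], last["value"]):
            out[row_of[eid]] = float(val)
    return out
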