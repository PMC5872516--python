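"""Cohort construction: baseline creatinine, KDIGO staging, exclusions, matching.

AKI severity is staged from serum creatinine (SCr) alone, using the KDIGO
creatinine criteria:

* stage 1 — increase > 0.3 mg/dL over baseline, or 1.5-1.9x baseline
* stage 2 — 2.0-2.9x baseline
* stage 3 — >= 3x baseline, or SCr above 4.0 mg/dL

Thresholds are canonical in mg/dL; µmol/L inputs are converted (/88.4) before
comparison.  The printed ratio bands are implemented as half-open intervals
[1.5, 2.0), [2.0, 3.0), [3.0, inf) so they tile the line with no gaps.

Baseline SCr is the last measurement inside the 2-day window before
admission, falling back to the first inpatient measurement.  Cases (stage 3)
are matched 1:1 to never-AKI controls on exact gender and race with a
nearest-age caliper, most-constrained case first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "BaselineScr",
    "AkiStage",
    "MatchResult",
    "MGDL_PER_UMOL",
    "compute_baseline",
    "stage_aki",
    "umol_to_mgdl",
    "apply_exclusions",
    "stage_cohort",
    "match_controls",
    "build_matched_cohort",
]

UMOL_PER_MGDL = 88.4
MGDL_PER_UMOL = 1.0 / UMOL_PER_MGDL

STAGE1_ABS_INCREASE = 0.3   # mg/dL, strict
STAGE1_RATIO = 1.5
STAGE2_RATIO = 2.0
STAGE3_RATIO = 3.0
STAGE3_ABS_VALUE = 4.0      # mg/dL, strict
BASELINE_WINDOW_HOURS = 48.0
ADMISSION_SCR_LIMIT = 1.3   # mg/dL within 24 h of admission
ADMISSION_WINDOW_HOURS = 24.0
EGFR_LIMIT = 60.0           # mL/min/1.73 m^2
MIN_STAY_DAYS = 2.0
MIN_AGE_YEARS = 18.0
DEFAULT_CALIPER_YEARS = 5.0


@dataclass(frozen=True)
class BaselineScr:
    """Baseline serum creatinine (mg/dL) and which rule produced it."""

    value: float
    source: str  # "pre-admission-window" | "first-inpatient"

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("baseline SCr must be positive")


@dataclass(frozen=True)
class AkiStage:
    """Maximum KDIGO stage reached during the stay, with its onset time."""

    stage: int
    onset_time: Optional[object] = None  # first time the maximal stage's criterion held

    def __post_init__(self) -> None:
        if self.stage not in (0, 1, 2, 3):
            raise ValueError("stage must be 0..3")
        if (self.stage == 0) != (self.onset_time is None):
            raise ValueError("onset_time present iff stage > 0")


def umol_to_mgdl(value_umol: float) -> float:
    """Convert serum creatinine from µmol/L to the canonical mg/dL scale."""
    return value_umol * MGDL_PER_UMOL


def _delta_hours(hours: float, like):
    if isinstance(like, (pd.Timestamp, np.datetime64)):
        return pd.Timedelta(hours=hours)
    return hours


def compute_baseline(times, values, admission) -> BaselineScr:
    """Baseline SCr: last value in [admission - 48 h, admission), else first
    value at/after admission.

    ``times`` must be strictly increasing; ``values`` in mg/dL.
    """
    times, values = list(times), [float(v) for v in values]
    if not times:
        raise ValueError("empty SCr series")
    if any(not v > 0 for v in values):
        raise ValueError("SCr values must be positive")
    if any(not a < b for a, b in zip(times, times[1:])):
        raise ValueError("SCr timestamps must be strictly increasing")

    window_start = admission - _delta_hours(BASELINE_WINDOW_HOURS, admission)
    pre = [(t, v) for t, v in zip(times, values) if window_start <= t < admission]
    if pre:
        return BaselineScr(value=pre[-1][1], source="pre-admission-window")
    post = [(t, v) for t, v in zip(times, values) if t >= admission]
    if post:
        return BaselineScr(value=post[0][1], source="first-inpatient")
    raise ValueError("no SCr measurement in the pre-admission window or after admission")


def _measurement_stage(value: float, baseline: float) -> int:
    """KDIGO stage criterion met by a single measurement (0 if none)."""
    ratio = value / baseline
    if value > STAGE3_ABS_VALUE or ratio >= STAGE3_RATIO:
        return 3
    if ratio >= STAGE2_RATIO:
        return 2
    if value - baseline > STAGE1_ABS_INCREASE or ratio >= STAGE1_RATIO:
        return 1
    return 0


def stage_aki(times, values, baseline: BaselineScr, admission=None, discharge=None) -> AkiStage:
    """Maximum KDIGO stage over the inpatient SCr series.

    Measurements are restricted to [admission, discharge] when those bounds
    are given.  The onset time is the first measurement satisfying the
    maximal stage's criterion.  Stage 0 (no criterion met) is a valid result.
    """
    pairs = list(zip(times, values))
    if admission is not None:
        pairs = [(t, v) for t, v in pairs if t >= admission]
    if discharge is not None:
        pairs = [(t, v) for t, v in pairs if t <= discharge]

    stages = [_measurement_stage(float(v), baseline.value) for _, v in pairs]
    top = max(stages, default=0)
    if top == 0:
        return AkiStage(stage=0, onset_time=None)
    onset = next(t for (t, _), s in zip(pairs, stages) if s == top)
    return AkiStage(stage=top, onset_time=onset)


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(encounters: pd.DataFrame, scr: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the inclusion/exclusion rules; one reason code per removal.

    Rules, in priority order: adult (> 18 y), stay of at least 2 days, at
    least two SCr measurements, admission eGFR >= 60 mL/min/1.73 m^2, and no
    SCr > 1.3 mg/dL within 24 h of admission.  eGFR arrives as the
    precomputed ``egfr_admission`` column of the encounters table.
    """
    counts = scr.groupby("encounter_id").size()
    scr_by_enc = dict(tuple(scr.groupby("encounter_id", sort=False)))

    retained, excluded = [], []
    for row in encounters.itertuples(index=False):
        reason = None
        stay = row.discharge - row.admission
        stay_days = stay / pd.Timedelta(days=1) if isinstance(stay, pd.Timedelta) else stay / 24.0
        if not row.age > MIN_AGE_YEARS:
            reason = "underage"
        elif stay_days < MIN_STAY_DAYS:
            reason = "short_stay"
        elif counts.get(row.encounter_id, 0) < 2:
            reason = "insufficient_scr"
        elif row.egfr_admission < EGFR_LIMIT:
            reason = "low_egfr"
        else:
            sub = scr_by_enc[row.encounter_id]
            end = row.admission + _delta_hours(ADMISSION_WINDOW_HOURS, row.admission)
            early = sub[(sub["time"] >= row.admission) & (sub["time"] <= end)]
            if (early["scr_mgdl"] > ADMISSION_SCR_LIMIT).any():
                reason = "abnormal_admission_scr"
        if reason is None:
            retained.append(row.encounter_id)
        else:
            excluded.append({"encounter_id": row.encounter_id, "reason": reason})

    log = pd.DataFrame(excluded, columns=["encounter_id", "reason"])
    return encounters[encounters["encounter_id"].isin(retained)].copy(), log


def stage_cohort(encounters: pd.DataFrame, scr: pd.DataFrame) -> pd.DataFrame:
    """Baseline + KDIGO stage for every encounter; one row per encounter."""
    out = []
    groups = dict(tuple(scr.groupby("encounter_id", sort=False)))
    for row in encounters.itertuples(index=False):
        sub = groups[row.encounter_id].sort_values("time", kind="stable")
        times, values = list(sub["time"]), list(sub["scr_mgdl"])
        base = compute_baseline(times, values, row.admission)
        result = stage_aki(times, values, base, admission=row.admission, discharge=row.discharge)
        out.append(
            {
                "encounter_id": row.encounter_id,
                "baseline_scr": base.value,
                "baseline_source": base.source,
                "stage": result.stage,
                "onset_time": result.onset_time,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Demographic matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    pairs: pd.DataFrame       # case_id, control_id, matched_pair_id, age_gap
    unmatched_cases: list[str]


def match_controls(cases: pd.DataFrame, controls: pd.DataFrame,
                   caliper_years: float = DEFAULT_CALIPER_YEARS) -> MatchResult:
    """1:1 exact match on gender and race, nearest age within a caliper.

    Greedy, most-constrained case first (fewest eligible controls); ties on
    eligibility broken by case id, ties on age gap by lowest control id —
    fully deterministic without a seed.
    """
    if not caliper_years > 0:
        raise ValueError("caliper must be positive")

    ctrl = controls[["encounter_id", "age", "gender", "race"]].copy()
    eligible: dict[str, list[tuple[float, str]]] = {}
    for row in cases.itertuples(index=False):
        ok = ctrl[(ctrl["gender"] == row.gender) & (ctrl["race"] == row.race)
                  & ((ctrl["age"] - row.age).abs() <= caliper_years)]
        eligible[row.encounter_id] = [
            (abs(a - row.age), cid) for cid, a in zip(ok["encounter_id"], ok["age"])
        ]

    order = sorted(eligible, key=lambda cid: (len(eligible[cid]), cid))
    used: set[str] = set()
    pairs, unmatched = [], []
    for case_id in order:
        options = sorted((gap, cid) for gap, cid in eligible[case_id] if cid not in used)
        if not options:
            unmatched.append(case_id)
            continue
        gap, control_id = options[0]
        used.add(control_id)
        pairs.append({"case_id": case_id, "control_id": control_id, "age_gap": gap})

    pairs_df = pd.DataFrame(pairs, columns=["case_id", "control_id", "age_gap"])
    pairs_df = pairs_df.sort_values("case_id", kind="stable").reset_index(drop=True)
    pairs_df["matched_pair_id"] = [f"pair_{i + 1:04d}" for i in range(len(pairs_df))]
    return MatchResult(pairs=pairs_df, unmatched_cases=sorted(unmatched))


def build_matched_cohort(
    encounters: pd.DataFrame,
    scr: pd.DataFrame,
    caliper_years: float = DEFAULT_CALIPER_YEARS,
) -> tuple[pd.DataFrame, pd.DataFrame, MatchResult]:
    """Full cohort construction: exclusions -> staging -> case/control matching.

    Cases are stage-3 encounters; the control pool is stage-0 (never-AKI)
    encounters.  Returns (cohort table, exclusion log, match result); the
    cohort table has one row per matched encounter with stage, onset,
    baseline and pair id.
    """
    retained, exclusion_log = apply_exclusions(encounters, scr)
    staged = stage_cohort(retained, scr).merge(
        retained[["encounter_id", "age", "gender", "race"]], on="encounter_id"
    )

    cases = staged[staged["stage"] == 3]
    controls = staged[staged["stage"] == 0]
    match = match_controls(cases, controls, caliper_years=caliper_years)

    pair_of = {}
    for row in match.pairs.itertuples(index=False):
        pair_of[row.case_id] = row.matched_pair_id
        pair_of[row.control_id] = row.matched_pair_id

    cohort = staged[staged["encounter_id"].isin(pair_of)].copy()
    cohort["matched_pair_id"] = cohort["encounter_id"].map(pair_of)
    cohort = cohort.sort_values(["matched_pair_id", "stage"],
                                ascending=[True, False], kind="stable").reset_index(drop=True)
    cols = ["encounter_id", "stage", "onset_time", "baseline_scr", "baseline_source", "matched_pair_id"]
    return cohort[cols], exclusion_log, match
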