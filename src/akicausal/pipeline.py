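"""End-to-end orchestration with config, logging and reproducible seeds.

Stage order: simulate (optional) -> cohort -> features -> structure ->
direction -> association -> evaluation.  Every stage reads only files
written by earlier stages into the run's output directory and writes its own
outputs there, so a run can be resumed or audited stage by stage.  All
output CSV/JSON files are byte-deterministic for a fixed configuration and
seed; per-stage wall-clock goes to a separate ``timings.txt`` so the
manifest itself stays reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import anm, association, cohort as cohort_mod, evaluation, features as features_mod, markov, synthetic

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "STAGES"]

log = logging.getLogger("akicausal")

FLOAT_FORMAT = "%.10g"

STAGES = ("simulate", "cohort", "features", "structure", "direction", "associate", "evaluate")


class ConfigError(ValueError):
    """Invalid run configuration; names the offending field."""


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    Exactly one of ``synthetic`` (a generator spec) and ``inputs`` (paths to
    an encounters, SCr and feature-event CSV triple) must be present.
    """

    output_dir: str = "akicausal_run"
    seed: int = 0
    synthetic: Optional[synthetic.SyntheticSpec] = field(
        default_factory=synthetic.SyntheticSpec)
    inputs: Optional[dict] = None  # {"encounters":…, "scr":…, "events":…}
    alpha: float = 0.05
    max_cond_size: int = 3
    max_set_size: int = 4
    k_folds: int = 10
    caliper_years: float = 5.0
    exposure_mode: str = "exact"
    model_params: dict = field(default_factory=dict)
    models: tuple[str, ...] = evaluation.MODEL_NAMES

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'synthetic' and 'inputs' must be set")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha: must be in (0, 1)")
        if self.max_cond_size < 1:
            raise ConfigError("max_cond_size: must be >= 1")
        if self.max_set_size < 1:
            raise ConfigError("max_set_size: must be >= 1")
        if self.k_folds < 2:
            raise ConfigError("k_folds: must be >= 2")
        if not self.caliper_years > 0:
            raise ConfigError("caliper_years: must be positive")
        if self.exposure_mode not in ("exact", "at-least"):
            raise ConfigError("exposure_mode: must be 'exact' or 'at-least'")
        unknown = set(self.models) - set(evaluation.MODEL_NAMES)
        if unknown:
            raise ConfigError(f"models: unknown {sorted(unknown)}")
        if self.inputs is not None:
            missing = {"encounters", "scr", "events"} - set(self.inputs)
            if missing:
                raise ConfigError(f"inputs: missing paths {sorted(missing)}")
        if self.synthetic is not None:
            spec = self.synthetic
            try:
                spec.validate()
            except synthetic.SpecError as err:
                raise ConfigError(f"synthetic.{err}") from err

    # -- (de)serialization ---------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        if self.synthetic is not None:
            doc["synthetic"] = _spec_to_dict(self.synthetic)
        doc["models"] = list(self.models)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "RunConfig":
        doc = dict(doc)
        if doc.get("synthetic") is not None:
            doc["synthetic"] = _spec_from_dict(doc["synthetic"])
        if doc.get("models") is not None:
            doc["models"] = tuple(doc["models"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg


def _spec_to_dict(spec: synthetic.SyntheticSpec) -> dict:
    doc = asdict(spec)
    doc["planted_causes"] = [
        {"name": c.name, "multipliers": dict(c.multipliers), "prevalence": c.prevalence}
        for c in spec.planted_causes
    ]
    doc["confounder_edges"] = [list(e) for e in spec.confounder_edges]
    doc["outcome_children"] = [list(e) for e in spec.outcome_children]
    doc["state_counts"] = dict(spec.state_counts)
    return doc


def _spec_from_dict(doc: Mapping) -> synthetic.SyntheticSpec:
    doc = dict(doc)
    if "planted_causes" in doc:
        doc["planted_causes"] = tuple(
            synthetic.PlantedCause(**c) for c in doc["planted_causes"]
        )
    if "confounder_edges" in doc:
        doc["confounder_edges"] = tuple(tuple(e) for e in doc["confounder_edges"])
    if "outcome_children" in doc:
        doc["outcome_children"] = tuple(
            (e[0], e[1] if len(e) > 1 else None) for e in doc["outcome_children"]
        )
    if "demographics" in doc and isinstance(doc["demographics"], Mapping):
        d = dict(doc["demographics"])
        for key in ("gender_probs", "race_probs"):
            if key in d:
                d[key] = tuple(d[key])
        doc["demographics"] = synthetic.DemographicsModel(**d)
    if "scr" in doc and isinstance(doc["scr"], Mapping):
        doc["scr"] = synthetic.ScrModel(**doc["scr"])
    return synthetic.SyntheticSpec(**doc)


# ---------------------------------------------------------------------------
# Stage implementations (file-to-file)
# ---------------------------------------------------------------------------

def _out(cfg: RunConfig) -> Path:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_csv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, index=index, float_format=FLOAT_FORMAT)


def stage_simulate(cfg: RunConfig) -> dict:
    """Generate the synthetic cohort tables and the ground-truth record."""
    if cfg.synthetic is None:
        raise ConfigError("simulate stage requires a synthetic spec")
    out = _out(cfg)
    spec = replace(cfg.synthetic, seed=cfg.seed)
    encounters, scr, events, truth = synthetic.generate_cohort(spec)
    _write_csv(encounters, out / "encounters.csv")
    _write_csv(scr, out / "scr_measurements.csv")
    _write_csv(events, out / "feature_events.csv")
    truth.feature_states.to_csv(out / "truth_matrix.csv")
    (out / "truth.json").write_text(json.dumps(truth.to_manifest(), indent=2, sort_keys=True))
    log.info("simulate: %d encounters, %d SCr rows, %d events",
             len(encounters), len(scr), len(events))
    return {"encounters": len(encounters), "scr_rows": len(scr), "events": len(events),
            "outputs": ["encounters.csv", "scr_measurements.csv", "feature_events.csv",
                        "truth_matrix.csv", "truth.json"]}


def _load_inputs(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    out = _out(cfg)
    if cfg.inputs is not None:
        paths = {k: Path(v) for k, v in cfg.inputs.items()}
    else:
        paths = {"encounters": out / "encounters.csv", "scr": out / "scr_measurements.csv",
                 "events": out / "feature_events.csv"}
    for name, p in paths.items():
        if not p.exists():
            raise ConfigError(f"missing input for stage: {name} ({p})")
    encounters = pd.read_csv(paths["encounters"], parse_dates=["admission", "discharge"])
    scr = pd.read_csv(paths["scr"], parse_dates=["time"])
    events = pd.read_csv(paths["events"], parse_dates=["time"])
    return encounters, scr, events


def stage_cohort(cfg: RunConfig) -> dict:
    """Exclusions, KDIGO staging and 1:1 demographic matching."""
    out = _out(cfg)
    encounters, scr, _events = _load_inputs(cfg)
    cohort, exclusions, match = cohort_mod.build_matched_cohort(
        encounters, scr, caliper_years=cfg.caliper_years)
    _write_csv(cohort, out / "cohort.csv")
    _write_csv(exclusions, out / "exclusion_log.csv")
    log.info("cohort: %d matched encounters (%d pairs), %d excluded, %d unmatched cases",
             len(cohort), len(match.pairs), len(exclusions), len(match.unmatched_cases))
    return {"encounters": len(cohort), "pairs": len(match.pairs),
            "excluded": len(exclusions), "unmatched_cases": match.unmatched_cases,
            "outputs": ["cohort.csv", "exclusion_log.csv"]}


def stage_features(cfg: RunConfig) -> dict:
    """Checkpointing and categorical matrix assembly."""
    out = _out(cfg)
    encounters, _scr, events = _load_inputs(cfg)
    cohort = pd.read_csv(out / "cohort.csv", parse_dates=["onset_time"])
    matrix, drop_log = features_mod.assemble_matrix(cohort, encounters, events)
    features_mod.write_matrix(matrix, out / "feature_matrix.csv", out / "feature_dict.csv")
    _write_csv(drop_log, out / "checkpoint_drop_log.csv")
    log.info("features: %d x %d matrix, %d dropped", matrix.n, len(matrix.features), len(drop_log))
    return {"rows": matrix.n, "features": len(matrix.features), "dropped": len(drop_log),
            "outputs": ["feature_matrix.csv", "feature_dict.csv", "checkpoint_drop_log.csv"]}


def _load_matrix(cfg: RunConfig) -> features_mod.FeatureMatrix:
    out = _out(cfg)
    return features_mod.read_matrix(out / "feature_matrix.csv", out / "feature_dict.csv")


def stage_structure(cfg: RunConfig) -> dict:
    """Markov-blanket discovery (dimensionality reduction)."""
    out = _out(cfg)
    matrix = _load_matrix(cfg)
    blanket = markov.learn_markov_blanket(matrix, alpha=cfg.alpha, max_cond_size=cfg.max_cond_size)
    _write_csv(pd.DataFrame({"feature": sorted(blanket.members)}), out / "blanket.csv")
    trace = pd.DataFrame(
        [
            {"action": ev.action, "feature": ev.feature, "cond_size": len(ev.test.z),
             "statistic": ev.test.statistic, "dof": ev.test.dof,
             "p_value": ev.test.p_value, "reliable": ev.test.reliable}
            for ev in blanket.trace
        ],
        columns=["action", "feature", "cond_size", "statistic", "dof", "p_value", "reliable"],
    )
    _write_csv(trace, out / "blanket_trace.csv")
    log.info("structure: blanket of %d features", len(blanket.members))
    return {"blanket_size": len(blanket.members), "outputs": ["blanket.csv", "blanket_trace.csv"]}


def stage_direction(cfg: RunConfig) -> dict:
    """Many-to-one ANM direction learning over blanket subsets."""
    out = _out(cfg)
    matrix = _load_matrix(cfg)
    members = pd.read_csv(out / "blanket.csv")["feature"].tolist() if (out / "blanket.csv").exists() else []
    blanket = markov.MarkovBlanket(target="y", members=set(members))
    result = anm.discover_causes(matrix, blanket, alpha=cfg.alpha, max_set_size=cfg.max_set_size)
    causes = pd.DataFrame(
        {"cause": list(result.causes),
         "forward_p": [result.forward_p] * len(result.causes),
         "backward_p": [result.backward_p] * len(result.causes),
         "accepted": [result.accepted] * len(result.causes)},
        columns=["cause", "forward_p", "backward_p", "accepted"],
    )
    _write_csv(causes, out / "causes.csv")
    search = pd.DataFrame(
        [
            {"subset": "+".join(e["subset"]), "m_bar": e["m_bar"],
             "forward_p": e.get("forward_p", float("nan")),
             "backward_p": e.get("backward_p", float("nan")),
             "admissible": e.get("admissible", False),
             "skipped": e.get("skipped", "")}
            for e in result.search_log
        ],
        columns=["subset", "m_bar", "forward_p", "backward_p", "admissible", "skipped"],
    )
    _write_csv(search, out / "direction_search.csv")
    log.info("direction: accepted=%s causes=%s", result.accepted, list(result.causes))
    return {"accepted": bool(result.accepted), "causes": list(result.causes),
            "outputs": ["causes.csv", "direction_search.csv"]}


def _load_causes(cfg: RunConfig) -> list[str]:
    out = _out(cfg)
    path = out / "causes.csv"
    if not path.exists():
        raise ConfigError("causes.csv missing; run the direction stage first")
    frame = pd.read_csv(path)
    return frame["cause"].tolist() if len(frame) else []


def stage_associate(cfg: RunConfig) -> dict:
    """Odds ratios of all non-empty cause combinations."""
    out = _out(cfg)
    matrix = _load_matrix(cfg)
    causes = _load_causes(cfg)
    rows = []
    if causes:
        for res in association.combination_table(matrix, causes, mode=cfg.exposure_mode):
            rows.append({"combination": res.label, "a": res.a, "b": res.b, "c": res.c,
                         "d": res.d, "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "haldane": res.haldane})
    table = pd.DataFrame(rows, columns=["combination", "a", "b", "c", "d", "odds_ratio",
                                        "ci_low", "ci_high", "haldane"])
    _write_csv(table, out / "odds_ratios.csv")
    log.info("associate: %d combination rows", len(table))
    return {"combinations": len(table), "outputs": ["odds_ratios.csv"]}


def stage_evaluate(cfg: RunConfig) -> dict:
    """Cross-validated predictive comparison of feature subsets."""
    out = _out(cfg)
    matrix = _load_matrix(cfg)
    causes = _load_causes(cfg)
    subsets: dict[str, list[str]] = {}
    if causes:
        subsets["discovered_causes"] = causes
    subsets["all_features"] = matrix.feature_names
    reports = evaluation.compare_feature_sets(
        matrix, subsets, models=cfg.models, k_folds=cfg.k_folds,
        seed=cfg.seed, model_params=cfg.model_params)

    rows = []
    for rep in reports:
        for metric in ("auc", "f_score", "recall", "precision"):
            lo, hi = rep.ci(metric)
            rows.append({
                "feature_set": rep.feature_set, "n_features": len(subsets[rep.feature_set]),
                "model": rep.model, "metric": metric, "mean": rep.mean(metric),
                "ci_low": lo, "ci_high": hi,
                "folds": "|".join(FLOAT_FORMAT % v for v in rep.fold_metrics[metric]),
            })
    table = pd.DataFrame(rows)
    _write_csv(table, out / "cv_metrics.csv")

    lines = ["feature set (# of variables)  model  AUC  F-score  Recall  Precision"]
    for rep in reports:
        lines.append(
            f"{rep.feature_set} ({len(subsets[rep.feature_set])})  {rep.model}  "
            f"{rep.auc:.3f}  {rep.f_score:.3f}  {rep.recall:.3f}  {rep.precision:.3f}"
        )
    (out / "cv_summary.txt").write_text("\n".join(lines) + "\n")
    log.info("evaluate: %d reports", len(reports))
    return {"reports": len(reports), "outputs": ["cv_metrics.csv", "cv_summary.txt"]}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "cohort": stage_cohort,
    "features": stage_features,
    "structure": stage_structure,
    "direction": stage_direction,
    "associate": stage_associate,
    "evaluate": stage_evaluate,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order and write the run manifest.

    The manifest records per-stage outputs and counts, the seed and package
    version; wall-clock per stage goes to ``timings.txt`` so the manifest is
    byte-identical across reruns with the same config.
    """
    cfg.validate()
    out = _out(cfg)
    stages = list(STAGES) if cfg.synthetic is not None else [s for s in STAGES if s != "simulate"]
    manifest: dict = {"seed": cfg.seed, "version": _version(), "stages": {}}
    timings = []
    for name in stages:
        t0 = time.perf_counter()
        try:
            info = _STAGE_FUNCS[name](cfg)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        timings.append((name, time.perf_counter() - t0))
        manifest["stages"][name] = info
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "timings.txt").write_text(
        "".join(f"{name}\t{sec:.2f}s\n" for name, sec in timings))
    return manifest


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("akicausal")
    except Exception:
        return "unknown"
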