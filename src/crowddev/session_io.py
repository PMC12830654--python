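"""Configuration, trial-log I/O and the end-to-end pipeline.

Every artifact is a plain-text table (CSV) or JSON/YAML document; a stored
configuration plus its seed reproduces every downstream file exactly.  The
root seed deterministically spawns per-participant random streams, so the
simulation of one participant never depends on how many others run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import METRIC_KINDS, ThresholdRecord, convert_to_study_metric, release_percentage
from .observer import CohortSpec, Participant, TrajectoryParams, generate_cohort, cohort_to_frame
from .psychfit import DEFAULT_BIN_WIDTH, DEFAULT_CRITERION, fit_thresholds
from .quest import QuestConfig, run_session
from .trajectory import bootstrap_trajectory, contrasts_by_group

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "SchemaError",
    "PipelineConfig",
    "read_trial_log",
    "write_trial_log",
    "simulate_cohort_trials",
    "run_full_pipeline",
]

log = logging.getLogger("crowddev")

TRIAL_LOG_COLUMNS: dict[str, type] = {
    "participant_id": str,
    "age_years": float,
    "condition": str,
    "block": int,
    "trial_index": int,
    "phase": str,
    "is_catch": bool,
    "nominal_estimate_arcmin": float,
    "presented_gap_arcmin": float,
    "correct": bool,
}


class SchemaError(ValueError):
    """A table does not match the documented trial-log schema."""


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    Required columns are coerced to their documented types; unknown columns
    are preserved.  Rows violating the schema are reported by (1-based data)
    row number.
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        raise SchemaError(f"{path}: empty trial log")
    missing = set(TRIAL_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    for col, typ in TRIAL_LOG_COLUMNS.items():
        try:
            if typ is bool:
                df[col] = df[col].map(_parse_bool)
            else:
                df[col] = df[col].astype(typ)
        except (ValueError, TypeError) as exc:
            bad = _first_bad_row(df[col], typ)
            raise SchemaError(f"{path}: column {col!r} row {bad}: {exc}") from exc
    bad_gap = df.index[df["presented_gap_arcmin"] <= 0]
    if len(bad_gap):
        raise SchemaError(f"{path}: non-positive presented_gap_arcmin at row {bad_gap[0] + 1}")
    return df


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


def _first_bad_row(series: pd.Series, typ) -> int:
    for i, v in enumerate(series, start=1):
        try:
            _parse_bool(v) if typ is bool else typ(v)
        except (ValueError, TypeError):
            return i
    return -1


def write_trial_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full simulated study."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    quest: QuestConfig = field(default_factory=QuestConfig)
    conditions: tuple[str, ...] = ("unflanked", "flanked_same", "flanked_different")
    child_blocks: int = 2
    adult_blocks: int = 3
    bin_width: float = DEFAULT_BIN_WIDTH
    criterion: float = DEFAULT_CRITERION
    metric_kinds: tuple[str, ...] = ("centre_to_centre", "flanked_over_unflanked")
    n_boot: int = 1000
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            for key in ("unflanked_params", "flanked_same_params", "flanked_different_params"):
                if c.get(key) is not None and isinstance(c[key], dict):
                    c[key] = TrajectoryParams(**c[key])
            if "groups" in c:
                c["groups"] = tuple(tuple(g) for g in c["groups"])
            d["cohort"] = CohortSpec(**c)
        if "quest" in d and isinstance(d["quest"], dict):
            q = dict(d["quest"])
            if "catch_schedule" in q:
                q["catch_schedule"] = tuple(q["catch_schedule"])
            d["quest"] = QuestConfig(**q)
        for key in ("conditions", "metric_kinds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate_cohort_trials(
    participants: Sequence[Participant], config: PipelineConfig
) -> pd.DataFrame:
    """Run every participant's session and concatenate the trial logs.

    Each participant gets an independent random stream spawned from the
    pipeline seed and the participant id, so logs are reproducible and
    insensitive to cohort ordering.
    """
    unknown = set(config.metric_kinds) - set(METRIC_KINDS)
    if unknown:
        raise ValueError(f"unknown metric kinds {sorted(unknown)}")
    frames = []
    for p in participants:
        blocks = config.adult_blocks if p.group == "adult" else config.child_blocks
        conds = [c for c in config.conditions if c in p.observers]
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1, int(p.id[1:]))))
        frames.append(run_session(p, conds, blocks, rng, config.quest))
    return pd.concat(frames, ignore_index=True)


def _metrics_table(thresholds: pd.DataFrame, kinds: Sequence[str]) -> pd.DataFrame:
    """Long-format per-participant metric table derived from thresholds."""
    wide = thresholds.pivot_table(
        index=["participant_id", "age_years"],
        columns="condition",
        values="threshold_gap_arcmin",
    )
    rows = []
    units = {
        "gap_acuity": "arcmin",
        "diameter": "arcmin",
        "centre_to_centre": "arcmin",
        "edge_to_edge": "arcmin",
        "flanked_over_unflanked": "ratio",
        "flanked_minus_unflanked": "arcmin",
    }
    for (pid, age), row in wide.iterrows():
        rec = ThresholdRecord(
            participant_id=str(pid), age=float(age), thresholds=row.dropna().to_dict()
        )
        for kind in kinds:
            try:
                value = convert_to_study_metric(rec, kind)
            except KeyError:
                continue
            rows.append(
                {
                    "participant_id": pid,
                    "age_years": age,
                    "metric_kind": kind,
                    "value": value,
                    "units": units[kind],
                }
            )
        if {"unflanked", "flanked_same", "flanked_different"} <= set(row.dropna().index):
            try:
                rel = release_percentage(
                    row["unflanked"], row["flanked_same"], row["flanked_different"]
                )
            except ValueError:
                rel = np.nan
            rows.append(
                {
                    "participant_id": pid,
                    "age_years": age,
                    "metric_kind": "release_pct",
                    "value": rel,
                    "units": "percent",
                }
            )
    return pd.DataFrame(rows)


def run_full_pipeline(config: PipelineConfig, out_dir) -> dict[str, Any]:
    """Cohort -> staircase sessions -> psychometric thresholds -> metrics ->
    trajectories + planned contrasts, written to ``out_dir`` with a manifest.

    Returns the manifest dict (paths, config hash, seed, stage timings).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "files": {},
    }

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage %s started", name)
        return t0

    def done(name, t0, **files):
        manifest["stages"][name] = round(time.perf_counter() - t0, 3)
        manifest["files"].update({k: str(v) for k, v in files.items()})
        log.info("stage %s finished in %.2fs", name, manifest["stages"][name])

    try:
        t0 = stage("cohort")
        participants = generate_cohort(config.cohort)
        cohort_path = out / "cohort.csv"
        cohort_to_frame(participants).to_csv(cohort_path, index=False)
        done("cohort", t0, cohort=cohort_path)

        t0 = stage("simulate")
        trials = simulate_cohort_trials(participants, config)
        trials_path = out / "trials.csv"
        write_trial_log(trials, trials_path)
        done("simulate", t0, trials=trials_path)

        t0 = stage("fit")
        thresholds = fit_thresholds(trials, bin_width=config.bin_width, criterion=config.criterion)
        thresholds_path = out / "thresholds.csv"
        thresholds.to_csv(thresholds_path, index=False)
        done("fit", t0, thresholds=thresholds_path)

        t0 = stage("metrics")
        metrics = _metrics_table(thresholds, config.metric_kinds)
        metrics_path = out / "metrics.csv"
        metrics.to_csv(metrics_path, index=False)
        done("metrics", t0, metrics=metrics_path)

        t0 = stage("trajectory")
        traj_out: dict[str, Any] = {}
        contrast_frames = []
        for cond, sub in thresholds.groupby("condition"):
            fit = bootstrap_trajectory(sub, n_boot=config.n_boot, seed=config.seed)
            traj_out[cond] = {
                "lower_asymptote": fit.lower_asymptote,
                "amplitude": fit.amplitude,
                "midpoint_age": fit.midpoint_age,
                "steepness": fit.steepness,
                "n_boot": fit.n_boot,
                "eval_ages": fit.eval_ages.tolist(),
                "band_low": fit.band_low.tolist(),
                "band_high": fit.band_high.tolist(),
            }
            contrast_frames.append(contrasts_by_group(sub).assign(condition=cond))
        traj_path = out / "trajectory.json"
        traj_path.write_text(json.dumps(traj_out, indent=1))
        contrasts = pd.concat(contrast_frames, ignore_index=True)
        contrasts_path = out / "contrasts.csv"
        contrasts.to_csv(contrasts_path, index=False)
        done("trajectory", t0, trajectory=traj_path, contrasts=contrasts_path)
    except Exception as exc:
        stage_name = next(reversed(manifest["stages"]), "cohort") if manifest["stages"] else "cohort"
        raise RuntimeError(f"pipeline failed after stage {stage_name!r}: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
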