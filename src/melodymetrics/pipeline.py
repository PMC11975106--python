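"""End-to-end pipeline: simulate -> score -> combine -> summarise.

Chains the synthetic cohort generator through both scoring suites and
the composite-score step, then summarises learning contrasts with
bootstrap evidence ratios. All outputs are versioned CSV/JSON with a
manifest listing file hashes and the measure constants used, so any
row is traceable to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from melodymetrics import improvisation, replication
from melodymetrics.combine import combine_replication, variance_sharing_combine
from melodymetrics.errors import DomainError
from melodymetrics.improvisation import (
    SCORETYPE_ORDER,
    TASK_SCORETYPE,
    score_improvisation,
)
from melodymetrics.inference import evidence_ratio
from melodymetrics.replication import ReplicationScores, score_replication
from melodymetrics.simulate import Cohort, SimulationDesign, generate_cohort

logger = logging.getLogger("melodymetrics")

_META_COLS = [
    "participant_id",
    "group",
    "session",
    "item",
    "instrument",
    "imprct",
    "repct",
    "nimptasks",
    "claimed_tasks",
]

CONSTANTS = {
    "COST_CAP": replication.COST_CAP,
    "MATCH_TOL": replication.MATCH_TOL,
    "JOINT_W_IOI": replication.JOINT_W_IOI,
    "JOINT_MATCH_TOL": replication.JOINT_MATCH_TOL,
    "KL_ALPHA": replication.KL_ALPHA,
    "RUN_MIN": improvisation.RUN_MIN,
    "VEL_MIN": improvisation.VEL_MIN,
    "ACCENT_DELTA": improvisation.ACCENT_DELTA,
    "ACCENT_WINDOW": improvisation.ACCENT_WINDOW,
    "PASSING_MAX_STEP": improvisation.PASSING_MAX_STEP,
    "IOI_WINDOW": improvisation.IOI_WINDOW,
    "PATTERN_MIN_LEN": improvisation.PATTERN_MIN_LEN,
}

# The 11 distinct scoretypes designated across the 14 methods.
TASK_SELECTIVE_SCORETYPES = sorted(set(TASK_SCORETYPE.values()))


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips through YAML.

    Unknown keys in a config file are rejected before any work runs.
    """

    out_dir: str = "melodymetrics_out"
    seed: int = 0
    n_participants: int = 68
    groups: int = 10
    replication_learning_rate: float = 0.5
    improv_base_intensity: float = 0.15
    improv_gain: float = 0.35
    reference_length: int = 15
    bootstrap_draws: int = 2000
    log_level: str = "INFO"
    constants: dict = field(default_factory=lambda: dict(CONSTANTS))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def design(self) -> SimulationDesign:
        return SimulationDesign(
            n_participants=self.n_participants,
            groups=self.groups,
            replication_learning_rate=self.replication_learning_rate,
            improv_base_intensity=self.improv_base_intensity,
            improv_gain=self.improv_gain,
            reference_length=self.reference_length,
            seed=self.seed,
        )


def _meta_dict(meta) -> dict:
    return {
        "participant_id": meta.participant_id,
        "group": meta.group,
        "session": meta.session,
        "item": meta.item,
        "instrument": meta.instrument,
        "imprct": meta.imprct,
        "repct": meta.repct,
        "nimptasks": meta.nimptasks,
        "claimed_tasks": ";".join(str(t) for t in meta.claimed_tasks),
    }


def replication_frame(cohort: Cohort) -> pd.DataFrame:
    """Score every replication record; one row per performance."""
    rows = []
    for rec in cohort.records:
        if rec.kind != "replication":
            continue
        scores = score_replication(rec.performance, rec.reference)
        rows.append({**_meta_dict(rec.metadata), **scores.as_dict()})
    return pd.DataFrame(rows, columns=_META_COLS + list(ReplicationScores.FIELDS))


def improvisation_frame(cohort: Cohort) -> pd.DataFrame:
    """Score every improvisation record; one row per performance."""
    rows = []
    for rec in cohort.records:
        if rec.kind != "improvisation":
            continue
        scores = score_improvisation(rec.performance)
        rows.append({**_meta_dict(rec.metadata), **scores.as_dict()})
    return pd.DataFrame(rows, columns=_META_COLS + list(SCORETYPE_ORDER))


def task_mapped_values(improv_df: pd.DataFrame) -> pd.DataFrame:
    """Designated-measure value for each claimed task, standardised.

    Explodes rows over their claimed tasks, looks up the task's
    designated scoretype, and z-scores values within scoretype so
    heterogeneous units are comparable (as when pooling per-task
    learning effects).
    """
    records = []
    for _, row in improv_df.iterrows():
        tasks = [int(t) for t in str(row["claimed_tasks"]).split(";") if t]
        for task in tasks:
            name = SCORETYPE_ORDER[TASK_SCORETYPE[task] - 1]
            records.append(
                {
                    "task": task,
                    "scoretype": name,
                    "value": row[name],
                    "imprct": row["imprct"],
                    "repct": row["repct"],
                    "session": row["session"],
                }
            )
    out = pd.DataFrame(records)
    if out.empty:
        return out
    def _z(series):
        sd = series.std(ddof=0)
        return (series - series.mean()) / sd if sd > 0 else series * 0.0
    out["z"] = out.groupby("scoretype")["value"].transform(_z)
    return out


def bootstrap_mean_contrast(hi, lo, n_draws: int, rng) -> np.ndarray:
    """Bootstrap draws of mean(hi) - mean(lo), ignoring missing values."""
    hi = np.asarray(pd.Series(hi).dropna(), float)
    lo = np.asarray(pd.Series(lo).dropna(), float)
    if hi.size < 2 or lo.size < 2:
        raise DomainError("contrast groups need >= 2 observations each")
    hi_draws = rng.choice(hi, size=(n_draws, hi.size)).mean(axis=1)
    lo_draws = rng.choice(lo, size=(n_draws, lo.size)).mean(axis=1)
    return hi_draws - lo_draws


def _write_csv(df: pd.DataFrame, path: Path, constants: dict) -> None:
    with open(path, "w", newline="") as fh:
        for key, value in constants.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def summarise(
    rep_df: pd.DataFrame,
    improv_df: pd.DataFrame,
    combined_rep: pd.Series,
    n_draws: int,
    rng,
) -> dict:
    """Per-session means plus bootstrap evidence ratios for the planted
    learning contrasts (more replication training -> higher replication
    scores; more improvisation training -> higher task-mapped measures)."""
    summary: dict = {
        "per_session_mean_pitchdtwladj": rep_df.groupby("session")["pitchdtwladj"]
        .mean()
        .to_dict(),
        "per_session_mean_combined_replication": combined_rep.groupby(
            rep_df["session"]
        )
        .mean()
        .to_dict(),
    }
    hi = rep_df.loc[rep_df["repct"] == 2, "pitchdtwladj"]
    lo = rep_df.loc[rep_df["repct"] == 0, "pitchdtwladj"]
    draws = bootstrap_mean_contrast(hi, lo, n_draws, rng)
    er = evidence_ratio(draws, "positive")
    summary["replication_repct2_vs_0"] = {
        "mean_difference": float(draws.mean()),
        "evidence_ratio": ("inf" if np.isinf(er) else float(er)),
    }
    mapped = task_mapped_values(improv_df)
    if not mapped.empty:
        hi = mapped.loc[mapped["imprct"] == 2, "z"]
        lo = mapped.loc[mapped["imprct"] == 0, "z"]
        draws = bootstrap_mean_contrast(hi, lo, n_draws, rng)
        er = evidence_ratio(draws, "positive")
        summary["improvisation_imprct2_vs_0"] = {
            "mean_difference": float(draws.mean()),
            "evidence_ratio": ("inf" if np.isinf(er) else float(er)),
        }
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> score -> combine -> summarise; returns the manifest.

    Produces replication_scores.csv, improvisation_scores.csv,
    combined_scores.csv, summary.json and manifest.json under
    ``config.out_dir``. Deterministic given the config seed.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("measure constants: %s", CONSTANTS)

    rng = np.random.default_rng(config.seed + 1)
    cohort = generate_cohort(config.design())
    logger.info("simulated %d performances", len(cohort.records))

    rep_df = replication_frame(cohort)
    improv_df = improvisation_frame(cohort)

    combined_rep = combine_replication(rep_df)
    improv_std = improv_df.copy()
    scoretype_cols = [SCORETYPE_ORDER[i - 1] for i in TASK_SELECTIVE_SCORETYPES]
    combined_improv = variance_sharing_combine(improv_df, scoretype_cols)
    combined_df = pd.concat(
        [
            rep_df[_META_COLS].assign(
                combined_replication=combined_rep, kind="replication"
            ),
            improv_std[_META_COLS].assign(
                combined_improvisation=combined_improv, kind="improvisation"
            ),
        ],
        ignore_index=True,
    )

    files = {
        "replication_scores.csv": lambda p: _write_csv(rep_df, p, config.constants),
        "improvisation_scores.csv": lambda p: _write_csv(
            improv_df, p, config.constants
        ),
        "combined_scores.csv": lambda p: _write_csv(combined_df, p, config.constants),
    }
    manifest: dict = {"config": asdict(config), "files": {}, "failed": []}
    for name, writer in files.items():
        path = out / name
        writer(path)
        manifest["files"][name] = _sha256(path)

    summary = summarise(rep_df, improv_df, combined_rep, config.bootstrap_draws, rng)
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=str))
    manifest["files"]["summary.json"] = _sha256(summary_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
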