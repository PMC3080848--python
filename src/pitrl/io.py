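"""Reading and writing datasets, truth tables and fit results.

Trial data travel as long-format CSV — one row per trial, absent values as
empty cells — with a YAML sidecar holding the task configuration.  Column
names and enum spellings are fixed so files round-trip bit-stably.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .fit import FitResult
from .task import SubjectDataset, TaskConfig, TrialRecord

__all__ = [
    "TRIAL_COLUMNS",
    "dataset_to_frame",
    "datasets_to_frame",
    "frame_to_datasets",
    "write_cohort",
    "read_cohort",
    "write_config",
    "read_config",
    "write_fit_result",
]

TRIAL_COLUMNS = [
    "subject_id",
    "block",
    "stage",
    "trial_index",
    "instrumental_stimulus",
    "pavlovian_stimulus",
    "action",
    "outcome",
    "correct_action",
]


def dataset_to_frame(dataset: SubjectDataset) -> pd.DataFrame:
    rows = [dataclasses.asdict(t) for t in dataset.trials]
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["outcome"] = df["outcome"].astype("Int64")
    return df


def datasets_to_frame(datasets: Sequence[SubjectDataset]) -> pd.DataFrame:
    return pd.concat([dataset_to_frame(d) for d in datasets], ignore_index=True)


def frame_to_datasets(df: pd.DataFrame, config: TaskConfig) -> list:
    """Rebuild per-subject datasets from a long-format trial table."""
    out = []
    for sid, sub in df.groupby("subject_id", sort=False):
        trials = []
        for row in sub.itertuples(index=False):
            trials.append(
                TrialRecord(
                    subject_id=str(row.subject_id),
                    block=str(row.block),
                    stage=str(row.stage),
                    trial_index=int(row.trial_index),
                    instrumental_stimulus=_opt_str(row.instrumental_stimulus),
                    pavlovian_stimulus=_opt_str(row.pavlovian_stimulus),
                    action=_opt_str(row.action),
                    outcome=_opt_int(row.outcome),
                    correct_action=_opt_str(row.correct_action),
                )
            )
        out.append(SubjectDataset(subject_id=str(sid), config=config, trials=trials))
    return out


def _opt_str(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA or v == "":
        return None
    return str(v)


def _opt_int(v) -> Optional[int]:
    if v is None or v is pd.NA or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return int(v)


def write_config(config: TaskConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["pavlovian_outcome_values"] = list(config.pavlovian_outcome_values)
    d["block_order"] = list(config.block_order)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_config(path) -> TaskConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["pavlovian_outcome_values"] = tuple(d["pavlovian_outcome_values"])
    d["block_order"] = tuple(d["block_order"])
    return TaskConfig(**d)


def write_cohort(
    datasets: Sequence[SubjectDataset],
    outdir,
    truth: Optional[pd.DataFrame] = None,
) -> None:
    """Write trials.csv + task_config.yaml (+ truth.csv) into a directory.

    The sidecar stores the first subject's configuration; per-subject block
    order is recoverable from the trial order itself.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datasets_to_frame(datasets).to_csv(outdir / "trials.csv", index=False)
    write_config(datasets[0].config, outdir / "task_config.yaml")
    if truth is not None:
        truth.to_csv(outdir / "truth.csv", index=False)


def read_cohort(indir) -> list:
    indir = Path(indir)
    config = read_config(indir / "task_config.yaml")
    df = pd.read_csv(
        indir / "trials.csv",
        dtype={"outcome": "Int64", "trial_index": int},
        keep_default_na=False,
        na_values=[""],
    )
    return frame_to_datasets(df, config)


def write_fit_result(fit: FitResult, outdir) -> None:
    """Serialize a FitResult: per-subject MAPs/variances, prior, trajectory, settings."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = list(fit.spec.param_names)

    rows = []
    for sf in fit.subject_fits:
        for name, m, v in zip(names, sf.map_estimate, sf.posterior_variance):
            rows.append(
                {
                    "subject_id": sf.subject_id,
                    "parameter": name,
                    "map_inference": m,
                    "posterior_variance": v,
                    "converged": sf.converged,
                    "hessian_pd": sf.hessian_pd,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "subject_fits.csv", index=False)

    pd.DataFrame(
        {"parameter": names, "mean": fit.group_prior.mean, "variance": fit.group_prior.var}
    ).to_csv(outdir / "group_prior.csv", index=False)

    pd.DataFrame(
        {"iteration": np.arange(1, len(fit.trajectory) + 1), "objective": fit.trajectory}
    ).to_csv(outdir / "em_trajectory.csv", index=False)

    settings = dataclasses.asdict(fit.settings)
    settings.update(
        model_id=fit.spec.model_id,
        converged=fit.converged,
        n_iterations=fit.n_iterations,
    )
    (outdir / "settings.json").write_text(json.dumps(settings, indent=2))
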