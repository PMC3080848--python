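"""Model-free behavioural summaries computed directly from trial records.

Three summaries, each self-auditing (raw counts are reported next to every
probability):

* learning curves — the probability of choosing the design-correct action,
  binned over presentations, split by block and by which action is correct;
* stay/switch probabilities — the probability of repeating an action after
  the most recent outcome *for the same instrumental stimulus* was a
  reward, and of switching after it was a punishment, plus the
  unconditional stay probability needed to interpret the two;
* PIT go/nogo log ratios — per Pavlovian stimulus and block, the log of the
  go/nogo choice-count ratio during transfer (with a +0.5 continuity
  correction on both counts), computed per subject and then averaged.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task import (
    GO,
    STAGE_INSTRUMENTAL,
    STAGE_PIT,
    SubjectDataset,
    pavlovian_value,
)

__all__ = [
    "correct_choice_curve",
    "stay_switch_probabilities",
    "pit_log_ratios",
    "plot_report",
]


def correct_choice_curve(
    datasets: Sequence[SubjectDataset],
    stage: str = STAGE_INSTRUMENTAL,
    bin_width: int = 4,
) -> pd.DataFrame:
    """Binned correct-choice probability per (block, correct action).

    Within each condition a subject's trials are numbered in time order and
    averaged in bins of ``bin_width`` presentations; the curve is the mean
    across subjects with its standard error.  Condition cells with no data
    are simply absent from the result.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    rows = []
    for ds in datasets:
        per_cond: dict = {}
        for t in ds.trials:
            if t.stage != stage:
                continue
            key = (t.block, t.correct_action)
            per_cond.setdefault(key, []).append(1.0 if t.action == t.correct_action else 0.0)
        for (block, correct), vals in per_cond.items():
            vals = np.asarray(vals)
            for b in range(int(np.ceil(len(vals) / bin_width))):
                chunk = vals[b * bin_width:(b + 1) * bin_width]
                rows.append(
                    {
                        "subject_id": ds.subject_id,
                        "block": block,
                        "correct_action": correct,
                        "bin": b,
                        "p_correct": chunk.mean(),
                        "n_trials": len(chunk),
                    }
                )
    per_subject = pd.DataFrame(rows)
    if per_subject.empty:
        return per_subject
    out = (
        per_subject.groupby(["block", "correct_action", "bin"])
        .agg(
            p_correct=("p_correct", "mean"),
            sem=("p_correct", lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan),
            n_subjects=("subject_id", "nunique"),
            n_trials=("n_trials", "sum"),
        )
        .reset_index()
    )
    return out


def stay_switch_probabilities(datasets: Sequence[SubjectDataset]) -> pd.DataFrame:
    """Stay-after-reward / switch-after-punishment on instrumental trials.

    Conditioning is on the most recent *earlier* trial with the same
    instrumental stimulus.  Per-subject probabilities are averaged across
    subjects (SEM across subjects); pooled event counts are reported
    alongside.  Stimuli never repeated contribute nothing.
    """
    per_subject = []
    counts = {"stay_after_reward": [0, 0], "switch_after_punishment": [0, 0],
              "overall_stay": [0, 0]}
    for ds in datasets:
        last: dict = {}
        tallies = {k: [0, 0] for k in counts}
        for t in ds.trials:
            if t.stage != STAGE_INSTRUMENTAL:
                continue
            s = t.instrumental_stimulus
            if s in last:
                prev_action, prev_outcome = last[s]
                stayed = t.action == prev_action
                tallies["overall_stay"][0] += int(stayed)
                tallies["overall_stay"][1] += 1
                if prev_outcome > 0:
                    tallies["stay_after_reward"][0] += int(stayed)
                    tallies["stay_after_reward"][1] += 1
                else:
                    tallies["switch_after_punishment"][0] += int(not stayed)
                    tallies["switch_after_punishment"][1] += 1
            last[s] = (t.action, t.outcome)
        row = {"subject_id": ds.subject_id}
        for k, (num, den) in tallies.items():
            row[k] = num / den if den else np.nan
            counts[k][0] += num
            counts[k][1] += den
        per_subject.append(row)
    df = pd.DataFrame(per_subject)
    rows = []
    for k in counts:
        vals = df[k].dropna()
        rows.append(
            {
                "measure": k,
                "probability": vals.mean() if len(vals) else np.nan,
                "sem": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan,
                "n_subjects": len(vals),
                "events": counts[k][0],
                "opportunities": counts[k][1],
            }
        )
    return pd.DataFrame(rows)


def pit_log_ratios(datasets: Sequence[SubjectDataset]) -> pd.DataFrame:
    """Go/nogo log choice ratio per (block, Pavlovian stimulus) during PIT.

    Per subject: ln((n_go + 0.5) / (n_nogo + 0.5)); the continuity
    correction keeps empty cells finite.  Averaged across subjects with
    SEM; pooled raw counts accompany every ratio.
    """
    per_subject = []
    for ds in datasets:
        cell: dict = {}
        for t in ds.trials:
            if t.stage != STAGE_PIT:
                continue
            key = (t.block, t.pavlovian_stimulus)
            go, nogo = cell.get(key, (0, 0))
            cell[key] = (go + int(t.action == GO), nogo + int(t.action != GO))
        for (block, pav), (go, nogo) in cell.items():
            try:
                value = pavlovian_value(pav)
            except (IndexError, ValueError):
                value = np.nan
            per_subject.append(
                {
                    "subject_id": ds.subject_id,
                    "block": block,
                    "pavlovian_stimulus": pav,
                    "pavlovian_value": value,
                    "log_ratio": np.log((go + 0.5) / (nogo + 0.5)),
                    "go_count": go,
                    "nogo_count": nogo,
                }
            )
    df = pd.DataFrame(per_subject)
    if df.empty:
        return df
    out = (
        df.groupby(["block", "pavlovian_stimulus", "pavlovian_value"])
        .agg(
            mean_log_ratio=("log_ratio", "mean"),
            sem=("log_ratio", lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan),
            n_subjects=("subject_id", "nunique"),
            go_count=("go_count", "sum"),
            nogo_count=("nogo_count", "sum"),
        )
        .reset_index()
        .sort_values(["block", "pavlovian_value"], ascending=[True, False])
        .reset_index(drop=True)
    )
    return out


def plot_report(
    curves: pd.DataFrame,
    stay_switch: pd.DataFrame,
    ratios: pd.DataFrame,
    path: Optional[str] = None,
):
    """Three-panel summary figure (learning curves, stay/switch, PIT ratios)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    for (block, correct), sub in curves.groupby(["block", "correct_action"]):
        axes[0].errorbar(sub["bin"], sub["p_correct"], yerr=sub["sem"],
                         label=f"{block}/{correct}")
    axes[0].axhline(0.5, color="grey", lw=0.5)
    axes[0].set(xlabel="trial bin", ylabel="P(correct)", title="learning curves")
    axes[0].legend(fontsize=7)

    axes[1].bar(stay_switch["measure"], stay_switch["probability"],
                yerr=stay_switch["sem"], color="lightgrey", edgecolor="k")
    axes[1].axhline(0.5, color="grey", lw=0.5)
    axes[1].tick_params(axis="x", rotation=20, labelsize=7)
    axes[1].set(ylabel="probability", title="stay / switch")

    for block, sub in ratios.groupby("block"):
        sub = sub.sort_values("pavlovian_value", ascending=False)
        axes[2].errorbar(sub["pavlovian_value"], sub["mean_log_ratio"],
                         yerr=sub["sem"], marker="o", label=block)
    axes[2].axhline(0.0, color="grey", lw=0.5)
    axes[2].set(xlabel="Pavlovian value (cents)", ylabel="ln(go/nogo)",
                title="PIT transfer")
    axes[2].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
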