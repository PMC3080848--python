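"""Task structure and trial-level data model.

The experiment consists of two counterbalanced blocks (approach, withdrawal).
Within each block the subject passes through three stages:

1. *Instrumental training* — 60 trials on 6 coloured-mushroom stimuli (3 of
   which are "good", i.e. the go action is correct, and 3 "bad").  Every
   choice earns +20 or -20 euro cents; under deterministic feedback the
   correct action always wins +20, under probabilistic feedback it wins with
   probability 0.7.
2. *Pavlovian conditioning* — five compound (fractal + tone) stimuli worth
   +100, +10, 0, -10 and -100 cents, each shown 20 times and followed
   deterministically by its outcome; every fifth trial of the stage is a
   *query* trial in which the subject chooses between two Pavlovian stimuli
   without feedback.
3. *Pavlovian-instrumental transfer (PIT)* — 100 trials in which the
   instrumental stimuli reappear on a Pavlovian background, in extinction
   (no outcomes shown).

This module defines the validated task configuration and trial records that
every other module (simulation, likelihood, fitting, descriptives) consumes.
Money is held as integer cents throughout to keep outcome bookkeeping exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

__all__ = [
    "APPROACH",
    "WITHDRAWAL",
    "BLOCKS",
    "STAGE_INSTRUMENTAL",
    "STAGE_PAVLOVIAN",
    "STAGE_QUERY",
    "STAGE_PIT",
    "GO",
    "NOGO",
    "ConfigurationError",
    "TaskConfig",
    "TrialRecord",
    "SubjectDataset",
    "Violation",
    "build_default_task_config",
    "validate_dataset",
    "instrumental_stimuli",
    "pavlovian_stimuli",
    "pavlovian_value",
]

APPROACH = "approach"
WITHDRAWAL = "withdrawal"
BLOCKS = (APPROACH, WITHDRAWAL)

STAGE_INSTRUMENTAL = "instrumental"
STAGE_PAVLOVIAN = "pavlovian_conditioning"
STAGE_QUERY = "pavlovian_query"
STAGE_PIT = "pit"
STAGES = (STAGE_INSTRUMENTAL, STAGE_PAVLOVIAN, STAGE_QUERY, STAGE_PIT)

GO = "go"
NOGO = "nogo"

_BLOCK_PREFIX = {APPROACH: "app", WITHDRAWAL: "wth"}

QUERY_PAIR_SEP = "|"  # query trials store the offered pair as "idA|idB"


class ConfigurationError(ValueError):
    """Invalid task configuration or unknown enum value."""


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the go/nogo approach-withdrawal task.

    Defaults reproduce the standard layout: 60 instrumental trials and 100
    PIT trials per block, five Pavlovian stimuli worth (+100, +10, 0, -10,
    -100) cents each conditioned 20 times with a query every fifth Pavlovian
    trial, and +/-20-cent instrumental feedback.
    """

    feedback_regime: str = "deterministic"  # or "probabilistic"
    withdrawal_action_style: str = "throwaway"  # or "release"
    n_instrumental_trials_per_block: int = 60
    n_pit_trials_per_block: int = 100
    n_pavlovian_presentations_per_stimulus: int = 20
    query_trial_period: int = 5
    instrumental_outcome_magnitude: int = 20  # euro cents
    pavlovian_outcome_values: tuple = (100, 10, 0, -10, -100)  # cents
    correct_outcome_probability: float = 1.0
    n_instrumental_stimuli_per_block: int = 6  # half "good", half "bad"
    block_order: tuple = (APPROACH, WITHDRAWAL)

    def __post_init__(self):
        if self.feedback_regime not in ("deterministic", "probabilistic"):
            raise ConfigurationError(
                f"unknown feedback_regime {self.feedback_regime!r}"
            )
        if self.withdrawal_action_style not in ("throwaway", "release"):
            raise ConfigurationError(
                f"unknown withdrawal_action_style {self.withdrawal_action_style!r}"
            )
        expected_p = 1.0 if self.feedback_regime == "deterministic" else 0.7
        if abs(self.correct_outcome_probability - expected_p) > 1e-12:
            raise ConfigurationError(
                f"correct_outcome_probability must be {expected_p} under "
                f"{self.feedback_regime} feedback"
            )
        vals = self.pavlovian_outcome_values
        if len(vals) != 5 or any(nxt >= prev for prev, nxt in zip(vals, vals[1:])):
            raise ConfigurationError(
                "pavlovian_outcome_values must be 5 strictly decreasing values"
            )
        if self.n_instrumental_stimuli_per_block % 2 != 0:
            raise ConfigurationError(
                "need equal numbers of go-correct and nogo-correct stimuli"
            )
        if sorted(self.block_order) != sorted(BLOCKS):
            raise ConfigurationError(f"block_order must be a permutation of {BLOCKS}")

    def with_block_order(self, order: Sequence[str]) -> "TaskConfig":
        return replace(self, block_order=tuple(order))


def build_default_task_config(
    feedback_regime: str = "deterministic",
    withdrawal_action_style: str = "throwaway",
) -> TaskConfig:
    """Return the default task layout for a feedback regime and withdrawal style.

    ``correct_outcome_probability`` is 1.0 under deterministic and 0.7 under
    probabilistic feedback; everything else takes the standard defaults.
    """
    p = {"deterministic": 1.0, "probabilistic": 0.7}.get(feedback_regime)
    if p is None:
        raise ConfigurationError(f"unknown feedback_regime {feedback_regime!r}")
    return TaskConfig(
        feedback_regime=feedback_regime,
        withdrawal_action_style=withdrawal_action_style,
        correct_outcome_probability=p,
    )


def instrumental_stimuli(block: str, n: int = 6) -> list:
    """Canonical instrumental stimulus identifiers for a block.

    The first half are "good" (go is correct), the second half "bad"
    (nogo is correct).
    """
    return [f"{_BLOCK_PREFIX[block]}_s{i}" for i in range(1, n + 1)]


def pavlovian_stimuli(block: str, values: Sequence[int] = (100, 10, 0, -10, -100)) -> list:
    """Canonical Pavlovian stimulus identifiers for a block, best to worst."""
    return [f"{_BLOCK_PREFIX[block]}_p{v:+d}" for v in values]


def pavlovian_value(stimulus_id: str) -> int:
    """Parse the conditioned monetary value (cents) from a canonical id."""
    return int(stimulus_id.rsplit("_p", 1)[1])


@dataclass(frozen=True)
class TrialRecord:
    """One observed or simulated trial.

    ``action`` is ``"go"``/``"nogo"`` on choice trials and the chosen
    stimulus identifier on query trials (where ``pavlovian_stimulus`` holds
    the offered pair joined by ``"|"``).  ``correct_action`` is the latent
    design label used only for scoring and descriptive curves; likelihood
    code never reads it.  ``outcome`` is in signed cents and absent (None)
    on query and PIT trials, which run in extinction.
    """

    subject_id: str
    block: str
    stage: str
    trial_index: int
    instrumental_stimulus: Optional[str] = None
    pavlovian_stimulus: Optional[str] = None
    action: Optional[str] = None
    outcome: Optional[int] = None
    correct_action: Optional[str] = None


@dataclass
class SubjectDataset:
    """All trials of one subject, in time order, plus the task configuration."""

    subject_id: str
    config: TaskConfig
    trials: list = field(default_factory=list)

    def choice_trials(self, include_pit: bool) -> list:
        """Instrumental-stage (and optionally PIT-stage) go/nogo trials."""
        stages = {STAGE_INSTRUMENTAL}
        if include_pit:
            stages.add(STAGE_PIT)
        return [t for t in self.trials if t.stage in stages]

    def n_choices(self, include_pit: bool) -> int:
        return len(self.choice_trials(include_pit))


class Violation(NamedTuple):
    trial_index: int  # -1 for dataset-level violations
    rule: str


_STAGE_ORDER = {
    STAGE_INSTRUMENTAL: 0,
    STAGE_PAVLOVIAN: 1,
    STAGE_QUERY: 1,  # interleaved with conditioning
    STAGE_PIT: 2,
}


def validate_dataset(dataset: SubjectDataset) -> list:
    """Check every trial-level invariant; return a list of violations.

    Violations are data, not exceptions: an empty list means the dataset is
    well formed.  Rules checked: strictly increasing trial indices; stage
    ordering instrumental -> pavlovian -> pit within each block; outcomes
    absent on PIT/query trials and of the configured magnitude on
    instrumental trials (with deterministic sign under deterministic
    feedback); stimulus fields present exactly on the stages that use them;
    valid action values.
    """
    cfg = dataset.config
    out: list = []
    last_index = None
    last_stage_rank: dict = {}
    blocks_seen: list = []

    for t in dataset.trials:
        ti = t.trial_index
        if last_index is not None and ti <= last_index:
            out.append(Violation(ti, "trial_index not strictly increasing"))
        last_index = ti

        if t.block not in BLOCKS:
            out.append(Violation(ti, f"unknown block {t.block!r}"))
            continue
        if t.stage not in STAGES:
            out.append(Violation(ti, f"unknown stage {t.stage!r}"))
            continue
        if t.block not in blocks_seen:
            blocks_seen.append(t.block)
        elif t.block != blocks_seen[-1]:
            out.append(Violation(ti, "block revisited after switching"))

        rank = _STAGE_ORDER[t.stage]
        prev = last_stage_rank.get(t.block)
        if prev is not None and rank < prev:
            out.append(
                Violation(ti, f"stage {t.stage} after a later stage in block {t.block}")
            )
        last_stage_rank[t.block] = max(rank, prev or 0)

        if t.stage in (STAGE_INSTRUMENTAL, STAGE_PIT):
            if t.instrumental_stimulus is None:
                out.append(Violation(ti, "missing instrumental_stimulus"))
            if t.action not in (GO, NOGO):
                out.append(Violation(ti, f"invalid choice action {t.action!r}"))
            if t.correct_action not in (GO, NOGO):
                out.append(Violation(ti, "missing correct_action label"))
        else:
            if t.instrumental_stimulus is not None:
                out.append(Violation(ti, "instrumental_stimulus on a Pavlovian trial"))

        if t.stage == STAGE_INSTRUMENTAL:
            if t.pavlovian_stimulus is not None:
                out.append(Violation(ti, "pavlovian_stimulus on an instrumental trial"))
            if t.outcome is None:
                out.append(Violation(ti, "missing outcome on instrumental trial"))
            else:
                if abs(t.outcome) != cfg.instrumental_outcome_magnitude:
                    out.append(
                        Violation(ti, "instrumental outcome magnitude mismatch")
                    )
                elif cfg.feedback_regime == "deterministic":
                    won = t.outcome > 0
                    if won != (t.action == t.correct_action):
                        out.append(
                            Violation(
                                ti,
                                "deterministic outcome sign inconsistent with "
                                "correct_action",
                            )
                        )
        elif t.stage == STAGE_PIT:
            if t.pavlovian_stimulus is None:
                out.append(Violation(ti, "missing pavlovian_stimulus on PIT trial"))
            if t.outcome is not None:
                out.append(Violation(ti, "outcome present on PIT trial (extinction)"))
        elif t.stage == STAGE_PAVLOVIAN:
            if t.pavlovian_stimulus is None:
                out.append(Violation(ti, "missing pavlovian_stimulus"))
            if t.outcome is None:
                out.append(Violation(ti, "missing outcome on conditioning trial"))
        elif t.stage == STAGE_QUERY:
            if t.outcome is not None:
                out.append(Violation(ti, "outcome present on query trial"))
            if t.pavlovian_stimulus is None or QUERY_PAIR_SEP not in t.pavlovian_stimulus:
                out.append(Violation(ti, "query trial must carry an offered pair"))
            elif t.action not in t.pavlovian_stimulus.split(QUERY_PAIR_SEP):
                out.append(Violation(ti, "query choice not among the offered pair"))

    return out
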