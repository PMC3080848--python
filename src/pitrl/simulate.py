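"""Synthetic cohorts: simulated subjects performing the full task.

Choices are emitted by the same model operations the likelihood uses
(``action_weights`` / ``choice_probabilities`` / ``update_q``), so the
probability assigned to every simulated choice is exactly the probability
the likelihood recomputes afterwards.  Ground-truth parameters are drawn
per subject from a Gaussian group prior in inference space.

What the generator emulates: the full two-block layout (instrumental
training with deterministic or 0.7/0.3 probabilistic +/-20-cent feedback,
Pavlovian conditioning with interleaved query trials, and 100 feedback-free
PIT trials per block), counterbalanced block order across subjects, and
near-ceiling query performance through a small lapse rate.  It does not
emulate reaction times, mouse kinematics, or off-target responses.

For instrumental-only models (1-7) there is no PIT-stage choice rule; PIT
actions are then sampled from the frozen instrumental weights (end-of-
training Q plus bias, no transfer term), which keeps datasets complete
while the likelihood of those models ignores the PIT stage anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .fit import GroupPrior
from .models import (
    ModelSpec,
    ParameterVector,
    QState,
    action_weights,
    choice_probabilities,
    update_q,
)
from .task import (
    APPROACH,
    GO,
    NOGO,
    STAGE_INSTRUMENTAL,
    STAGE_PAVLOVIAN,
    STAGE_PIT,
    STAGE_QUERY,
    QUERY_PAIR_SEP,
    SubjectDataset,
    TaskConfig,
    TrialRecord,
    WITHDRAWAL,
    instrumental_stimuli,
    pavlovian_stimuli,
    pavlovian_value,
)

__all__ = [
    "CohortSpec",
    "draw_subject_parameters",
    "simulate_subject",
    "simulate_cohort",
    "default_truth_prior",
]


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a simulated cohort with known ground truth."""

    n_subjects: int
    model_spec: ModelSpec
    group_prior_truth: GroupPrior
    task_config: TaskConfig
    master_seed: int
    query_lapse_rate: float = 0.02

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.query_lapse_rate <= 0.5:
            raise ValueError("query_lapse_rate must lie in [0, 0.5]")
        if self.group_prior_truth.n_params != self.model_spec.n_params:
            raise ValueError("truth prior dimension does not match the model")


def draw_subject_parameters(
    group_prior_truth: GroupPrior, model_spec: ModelSpec, seed
) -> ParameterVector:
    """Draw one subject's inference-space parameters from the group prior."""
    if group_prior_truth.n_params != model_spec.n_params:
        raise ValueError("prior dimension does not match the model")
    rng = np.random.default_rng(seed)
    return ParameterVector(model_spec, group_prior_truth.sample(rng))


def _instrumental_sequence(rng, config: TaskConfig, block: str) -> list:
    stims = instrumental_stimuli(block, config.n_instrumental_stimuli_per_block)
    n = config.n_instrumental_trials_per_block
    seq = (stims * (n // len(stims) + 1))[:n]
    rng.shuffle(seq)
    return seq


def _correct_action(stimulus: str, config: TaskConfig) -> str:
    # first half of each block's stimuli are "good": go is correct
    rank = int(stimulus.rsplit("_s", 1)[1])
    return GO if rank <= config.n_instrumental_stimuli_per_block // 2 else NOGO


def _pavlovian_sequence(rng, config: TaskConfig, block: str) -> list:
    """Conditioning trials with a query interleaved every ``period``-th trial."""
    stims = pavlovian_stimuli(block, config.pavlovian_outcome_values)
    cond = stims * config.n_pavlovian_presentations_per_stimulus
    rng.shuffle(cond)
    period = config.query_trial_period
    n_queries = len(cond) // (period - 1)
    seq = []
    i = 0
    for p in range(1, len(cond) + n_queries + 1):
        if p % period == 0:
            seq.append(("query", None))
        else:
            seq.append(("conditioning", cond[i]))
            i += 1
    return seq


def _pit_sequence(rng, config: TaskConfig, block: str) -> list:
    n = config.n_pit_trials_per_block
    pav = pavlovian_stimuli(block, config.pavlovian_outcome_values)
    instr = instrumental_stimuli(block, config.n_instrumental_stimuli_per_block)
    pav_seq = (pav * (n // len(pav) + 1))[:n]
    instr_seq = (instr * (n // len(instr) + 1))[:n]
    rng.shuffle(pav_seq)
    rng.shuffle(instr_seq)
    return list(zip(instr_seq, pav_seq))


def simulate_subject(
    params: ParameterVector,
    model_spec: ModelSpec,
    task_config: TaskConfig,
    seed,
    subject_id: str = "sim_0",
    query_lapse_rate: float = 0.02,
    return_log_probs: bool = False,
):
    """Run one agent forward through both blocks of the task.

    Instrumental choices are sampled from the model's softmax and update Q
    from the delivered outcome; PIT choices are sampled from the PIT-stage
    weights with no outcomes and no updates (the extinction model's decay
    clock is the only PIT-stage dynamics).  With ``return_log_probs`` the
    summed log probability of the sampled in-scope choices is also
    returned, split by stage.
    """
    rng = np.random.default_rng(seed)
    state = QState()
    trials: list = []
    logp = {"instrumental": 0.0, "pit": 0.0}
    idx = 0
    mag = task_config.instrumental_outcome_magnitude
    p_correct = task_config.correct_outcome_probability

    for block in task_config.block_order:
        for stimulus in _instrumental_sequence(rng, task_config, block):
            correct = _correct_action(stimulus, task_config)
            trial = TrialRecord(
                subject_id=subject_id, block=block, stage=STAGE_INSTRUMENTAL,
                trial_index=idx, instrumental_stimulus=stimulus,
                correct_action=correct,
            )
            probs = choice_probabilities(
                action_weights(state, trial, params, model_spec)
            )
            action = GO if rng.random() < probs[GO] else NOGO
            logp["instrumental"] += float(np.log(probs[action]))
            won = rng.random() < (p_correct if action == correct else 1.0 - p_correct)
            trial = replace(trial, action=action, outcome=mag if won else -mag)
            state = update_q(state, trial, params, model_spec)
            trials.append(trial)
            idx += 1

        pav_ids = pavlovian_stimuli(block, task_config.pavlovian_outcome_values)
        for kind, stimulus in _pavlovian_sequence(rng, task_config, block):
            if kind == "conditioning":
                trials.append(TrialRecord(
                    subject_id=subject_id, block=block, stage=STAGE_PAVLOVIAN,
                    trial_index=idx, pavlovian_stimulus=stimulus,
                    outcome=pavlovian_value(stimulus),
                ))
            else:
                pair = list(rng.choice(pav_ids, 2, replace=False))
                best = max(pair, key=pavlovian_value)
                worst = min(pair, key=pavlovian_value)
                choice = worst if rng.random() < query_lapse_rate else best
                trials.append(TrialRecord(
                    subject_id=subject_id, block=block, stage=STAGE_QUERY,
                    trial_index=idx,
                    pavlovian_stimulus=QUERY_PAIR_SEP.join(pair),
                    action=choice,
                ))
            idx += 1

        for stimulus, pav in _pit_sequence(rng, task_config, block):
            trial = TrialRecord(
                subject_id=subject_id, block=block, stage=STAGE_PIT,
                trial_index=idx, instrumental_stimulus=stimulus,
                pavlovian_stimulus=pav,
                correct_action=_correct_action(stimulus, task_config),
            )
            if model_spec.includes_pit:
                weights = action_weights(state, trial, params, model_spec)
            else:
                # frozen instrumental weights: same softmax, no transfer term
                pseudo = replace(trial, stage=STAGE_INSTRUMENTAL,
                                 pavlovian_stimulus=None)
                weights = action_weights(state, pseudo, params, model_spec)
            probs = choice_probabilities(weights)
            action = GO if rng.random() < probs[GO] else NOGO
            logp["pit"] += float(np.log(probs[action]))
            trials.append(replace(trial, action=action))
            state = state.advance_pit(block)
            idx += 1

    dataset = SubjectDataset(subject_id=subject_id, config=task_config, trials=trials)
    if return_log_probs:
        return dataset, logp
    return dataset


def simulate_cohort(spec: CohortSpec):
    """Simulate a cohort; returns (datasets, ground-truth parameter table).

    Per-subject seeds are spawned deterministically from ``master_seed`` via
    ``numpy.random.SeedSequence`` so subjects are independent and the cohort
    is bit-reproducible.  Block order alternates across subjects
    (counterbalancing).
    """
    datasets = []
    rows = []
    for i in range(spec.n_subjects):
        ss = np.random.SeedSequence(entropy=spec.master_seed, spawn_key=(i,))
        param_seed, behav_seed = ss.spawn(2)
        params = draw_subject_parameters(
            spec.group_prior_truth, spec.model_spec, param_seed
        )
        order = (APPROACH, WITHDRAWAL) if i % 2 == 0 else (WITHDRAWAL, APPROACH)
        subject_id = f"sim_{i:03d}"
        datasets.append(
            simulate_subject(
                params,
                spec.model_spec,
                spec.task_config.with_block_order(order),
                behav_seed,
                subject_id=subject_id,
                query_lapse_rate=spec.query_lapse_rate,
            )
        )
        native = params.native
        for name, inf_v, nat_v in zip(
            spec.model_spec.param_names, params.inference, native
        ):
            rows.append(
                {
                    "subject_id": subject_id,
                    "parameter": name,
                    "value_inference": inf_v,
                    "value_native": nat_v,
                }
            )
    truth = pd.DataFrame(rows)
    return datasets, truth


# ---------------------------------------------------------------------------
# documented ground-truth group priors for the recovery suites

# (inference-space mean, sd) per parameter name.  Chosen once so simulated
# cohorts show the moderate, non-ceiling conditioning the task aims for:
# learning rates spread over roughly 0.08-0.65 (logit mean -1, sd 0.8), a
# clear reward-over-punishment sensitivity asymmetry, no approach bias but a
# bias against withdrawal go, transfer weights rising with Pavlovian value
# in the approach block and falling in the withdrawal block, and
# generalization noise large enough to disrupt transfer visibly.
_TRUTH_TABLE = {
    "eps": (-1.0, 0.8),
    "eps_rew": (-1.0, 0.8),
    "eps_pun": (-1.5, 0.8),
    "eps_app": (-1.0, 0.8),
    "eps_wth": (-1.2, 0.8),
    "rho": (2.2, 0.5),
    "rho_rew": (2.2, 0.5),
    "rho_pun": (0.3, 0.3),
    "rho_rew_app": (2.2, 0.5),
    "rho_pun_app": (0.3, 0.3),
    "rho_rew_wth": (2.2, 0.5),
    "rho_pun_wth": (0.3, 0.3),
    "b_app": (0.0, 0.3),
    "b_wth": (-0.5, 0.4),
    "gamma": (2.0, 0.5),
}
_PI_TRUTH = {  # by Pavlovian value; approach slope positive, withdrawal negative
    ("app", 100): 0.6, ("app", 10): 0.3, ("app", 0): 0.0,
    ("app", -10): -0.3, ("app", -100): -0.6,
    ("wth", 100): -0.6, ("wth", 10): -0.3, ("wth", 0): 0.0,
    ("wth", -10): 0.3, ("wth", -100): 0.6,
}
_PI_SD = 0.4
_XI_TRUTH = (0.0, 1.0)
_LEVEL_FROM_TAG = {"p100": 100, "p10": 10, "z0": 0, "m10": -10, "m100": -100}


def default_truth_prior(model_spec: ModelSpec) -> GroupPrior:
    """The generating group prior used throughout the recovery suites."""
    mean = np.empty(model_spec.n_params)
    sd = np.empty(model_spec.n_params)
    for i, name in enumerate(model_spec.param_names):
        if name in _TRUTH_TABLE:
            mean[i], sd[i] = _TRUTH_TABLE[name]
        elif name.startswith("pi_"):
            _, blk, tag = name.split("_")
            mean[i] = _PI_TRUTH[(blk, _LEVEL_FROM_TAG[tag])]
            sd[i] = _PI_SD
        elif name.startswith("xi_"):
            mean[i], sd[i] = _XI_TRUTH
        else:  # pragma: no cover
            raise KeyError(f"no documented truth for parameter {name}")
    return GroupPrior(mean, sd**2)
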