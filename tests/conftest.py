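"""Shared fixtures: hand-built trial sequences and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from pitrl.fit import GroupPrior
from pitrl.models import get_model
from pitrl.simulate import CohortSpec, default_truth_prior, simulate_cohort
from pitrl.task import (
    APPROACH,
    GO,
    NOGO,
    STAGE_INSTRUMENTAL,
    STAGE_PIT,
    SubjectDataset,
    TrialRecord,
    build_default_task_config,
)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def make_instrumental_trial(
    idx, stimulus="app_s1", action=GO, outcome=20, block=APPROACH, correct=GO,
    subject="t",
):
    return TrialRecord(
        subject_id=subject, block=block, stage=STAGE_INSTRUMENTAL,
        trial_index=idx, instrumental_stimulus=stimulus, action=action,
        outcome=outcome, correct_action=correct,
    )


def make_pit_trial(
    idx, stimulus="app_s1", pav="app_p+100", action=GO, block=APPROACH,
    correct=GO, subject="t",
):
    return TrialRecord(
        subject_id=subject, block=block, stage=STAGE_PIT, trial_index=idx,
        instrumental_stimulus=stimulus, pavlovian_stimulus=pav, action=action,
        correct_action=correct,
    )


def make_dataset(trials, config=None, subject="t"):
    return SubjectDataset(
        subject_id=subject,
        config=config or build_default_task_config(),
        trials=list(trials),
    )


@pytest.fixture(scope="session")
def task_config():
    return build_default_task_config()


@pytest.fixture(scope="session")
def prob_config():
    return build_default_task_config(feedback_regime="probabilistic")


def simulate_small_cohort(model_id, n_subjects=4, master_seed=123,
                          feedback="probabilistic", prior=None):
    spec = get_model(model_id)
    cohort = CohortSpec(
        n_subjects=n_subjects,
        model_spec=spec,
        group_prior_truth=prior or default_truth_prior(spec),
        task_config=build_default_task_config(feedback_regime=feedback),
        master_seed=master_seed,
    )
    return simulate_cohort(cohort)


@pytest.fixture(scope="session")
def m5_cohort_small():
    return simulate_small_cohort(5)


@pytest.fixture(scope="session")
def m10_cohort_small():
    return simulate_small_cohort(10)
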