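"""Surrogate-data verification suites: parameter and model recovery.

The fitting and comparison machinery is validated on cohorts simulated from
known ground truth: (i) *parameter recovery* — fit the generating model and
correlate per-subject MAP estimates with the true parameters, and compare
recovered group means with the generating ones; (ii) *model recovery* —
score a family of candidate models on data generated by one member and
check that the generator wins.

Study conditions used throughout: cohorts of 40 subjects performing the
full task (2 x 60 instrumental + 2 x 100 PIT choice trials each) under
probabilistic (0.7/0.3) feedback — the informative regime, since
deterministic feedback stops producing prediction errors once behaviour
stabilises and leaves the learning rate nearly unconstrained.  Ground truth
comes from :func:`pitrl.simulate.default_truth_prior`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .compare import ModelEvidence, group_score, hyperparameter_error_bars
from .fit import FitResult, FitSettings, em_fit
from .models import ModelSpec, get_model
from .simulate import CohortSpec, default_truth_prior, simulate_cohort
from .task import build_default_task_config

__all__ = [
    "recovery_settings",
    "simulate_recovery_cohort",
    "RecoveryRep",
    "run_parameter_recovery_rep",
    "true_map_correlation",
    "pooled_pi_correlation",
    "group_mean_coverage",
    "model_recovery_scores",
]

N_SUBJECTS = 40
K_EVIDENCE = 2000


def recovery_settings(seed: int) -> FitSettings:
    """EM settings for the recovery suites.

    Two restarts and a 0.02 stopping tolerance with at most 80 iterations:
    the group prior is stationary to well below its own standard error by
    then, at a few seconds per fit.
    """
    return FitSettings(seed=seed, restarts=2, em_tol=0.02, em_max_iter=80)


def simulate_recovery_cohort(model_id: int, master_seed: int,
                             n_subjects: int = N_SUBJECTS):
    spec = get_model(model_id)
    cohort = CohortSpec(
        n_subjects=n_subjects,
        model_spec=spec,
        group_prior_truth=default_truth_prior(spec),
        task_config=build_default_task_config(feedback_regime="probabilistic"),
        master_seed=master_seed,
    )
    return simulate_cohort(cohort)


@dataclass
class RecoveryRep:
    """One parameter-recovery repetition: data, truth, fit and evidence."""

    spec: ModelSpec
    datasets: list
    truth_inference: "np.ndarray"  # (n_subjects, n_params), row order = datasets
    fit: FitResult
    evidence: Optional[ModelEvidence] = None
    intervals: Optional[list] = None


def _truth_matrix(truth, spec, datasets) -> np.ndarray:
    wide = truth.pivot(index="subject_id", columns="parameter",
                       values="value_inference")
    order = [ds.subject_id for ds in datasets]
    return wide.loc[order, list(spec.param_names)].to_numpy(dtype=float)


def run_parameter_recovery_rep(
    model_id: int,
    master_seed: int,
    seed: int,
    n_subjects: int = N_SUBJECTS,
    K: int = K_EVIDENCE,
    with_intervals: bool = True,
) -> RecoveryRep:
    """Simulate one cohort from the model, fit it, and score/interval it."""
    spec = get_model(model_id)
    datasets, truth = simulate_recovery_cohort(model_id, master_seed, n_subjects)
    fit = em_fit(datasets, spec, recovery_settings(seed))
    rep = RecoveryRep(
        spec=spec,
        datasets=datasets,
        truth_inference=_truth_matrix(truth, spec, datasets),
        fit=fit,
    )
    if with_intervals:
        rep.evidence = group_score(datasets, fit, K=K, seed=seed)
        rep.intervals = hyperparameter_error_bars(rep.evidence, fit)
    return rep


def true_map_correlation(reps: Sequence[RecoveryRep], name: str) -> float:
    """Pearson correlation of true vs MAP values, pooled across repetitions."""
    idx = reps[0].spec.index(name)
    t = np.concatenate([r.truth_inference[:, idx] for r in reps])
    m = np.concatenate([r.fit.map_matrix()[:, idx] for r in reps])
    return float(np.corrcoef(t, m)[0, 1])


def pooled_pi_correlation(reps: Sequence[RecoveryRep]) -> float:
    """True-vs-MAP correlation over all transfer-weight coordinates at once."""
    spec = reps[0].spec
    cols = [i for i, n in enumerate(spec.param_names) if n.startswith("pi_")]
    t = np.concatenate(
        [r.truth_inference[:, c] for r in reps for c in cols]
    )
    m = np.concatenate([r.fit.map_matrix()[:, c] for r in reps for c in cols])
    return float(np.corrcoef(t, m)[0, 1])


def group_mean_coverage(rep: RecoveryRep) -> tuple:
    """(covered, total): generating group means inside the fitted 95% intervals."""
    spec = rep.spec
    truth_prior = default_truth_prior(spec)
    covered = 0
    for grp, iv in zip(spec.hyper_groups, rep.intervals):
        tm = float(np.mean(truth_prior.mean[list(grp)]))
        covered += bool(iv.ci_low <= tm <= iv.ci_high)
    return covered, len(spec.hyper_groups)


def model_recovery_scores(
    generator_id: int,
    candidate_ids: Sequence[int],
    master_seed: int,
    seed: int,
    n_subjects: int = N_SUBJECTS,
    K: int = K_EVIDENCE,
    datasets: Optional[list] = None,
    fits: Optional[dict] = None,
) -> dict:
    """Group scores of each candidate model on one generated cohort.

    ``datasets`` / ``fits`` may carry pre-computed pieces (e.g. the
    generating model's own fit) to avoid redundant work.
    """
    if datasets is None:
        datasets, _ = simulate_recovery_cohort(generator_id, master_seed,
                                               n_subjects)
    fits = dict(fits or {})
    scores = {}
    for mid in candidate_ids:
        if mid not in fits:
            fits[mid] = em_fit(datasets, get_model(mid),
                               recovery_settings(seed * 100 + mid))
        scores[mid] = group_score(datasets, fits[mid], K=K, seed=seed).total_score
    return scores
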