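"""Group-level Bayesian model comparison.

Each subject's individual parameters are integrated out under the fitted
group prior by importance sampling: with K draws theta_k from the prior,

    log p(D_i | prior)  ~=  log( (1/K) * sum_k p(D_i | theta_k) )

computed throughout in log space.  The group score adds a BIC-style penalty
for the fitted hyperparameters,

    score = -2 * sum_i log p(D_i | prior) + n_hyper * ln(N_choices),

with ``n_hyper`` counting the fitted prior means and variances (model 10's
pooled offsets contribute a single mean/variance pair) and ``N_choices``
the total number of in-scope choices across subjects.  Smaller is better,
and only score differences between models are meaningful.

The retained samples also give hyperparameter error bars without new
likelihood evaluations: shifting a prior mean by delta re-weights every
sample by the prior-density ratio, and the curvature of the shifted group
log likelihood around its maximum yields a standard error.

Finally, an absolute goodness-of-fit check: the per-trial "predictive
probability" of each observed choice given the past under the subject's MAP
parameters, summarized as a geometric mean and a binomial test of the
number of choices predicted better than chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binomtest

from .fit import FitResult, GroupPrior
from .models import (
    CompiledTrials,
    ModelSpec,
    ParameterVector,
    compile_trials,
    log_likelihood_many,
    per_trial_log_probabilities,
    transform_to_native,
)
from .task import SubjectDataset

__all__ = [
    "ModelEvidence",
    "HyperparameterInterval",
    "integrated_subject_likelihood",
    "group_score",
    "hyperparameter_error_bars",
    "predictive_probability",
    "cohort_predictive_probability",
    "score_table",
]


@dataclass
class SubjectSamples:
    """Importance samples retained for one subject (inference space)."""

    draws: np.ndarray  # (K, d)
    logliks: np.ndarray  # (K,)


@dataclass
class ModelEvidence:
    """Per-subject integrated log-likelihoods and the penalized group score."""

    model_id: int
    per_subject_loglik: np.ndarray
    per_subject_mc_error: np.ndarray
    K: int
    n_hyper: int
    n_choices: int
    penalty: float
    seed: int
    samples: list  # SubjectSamples per subject

    @property
    def total_integrated_loglik(self) -> float:
        return float(np.sum(self.per_subject_loglik))

    @property
    def total_score(self) -> float:
        return -2.0 * self.total_integrated_loglik + self.penalty


@dataclass
class HyperparameterInterval:
    name: str
    point: float
    se: float
    ci_low: float
    ci_high: float
    reliable: bool


def _is_estimate(logliks: np.ndarray) -> tuple:
    """Log of the mean likelihood and its delta-method MC standard error."""
    K = logliks.shape[0]
    est = float(logsumexp(logliks) - np.log(K))
    if K == 1:
        return est, 0.0
    w = np.exp(logliks - np.max(logliks))
    mean_w = float(np.mean(w))
    se = float(np.std(w, ddof=1) / (mean_w * np.sqrt(K)))
    return est, se


def integrated_subject_likelihood(
    dataset: Optional[SubjectDataset],
    prior: GroupPrior,
    spec: ModelSpec,
    K: int,
    seed,
    compiled: Optional[CompiledTrials] = None,
    loglik_fn=None,
):
    """Importance-sampled integrated likelihood of one subject.

    Returns ``(estimate, mc_error, SubjectSamples)``.  ``loglik_fn(draws)``
    mapping a (K, d) array of inference-space draws to K log-likelihoods may
    be injected for toy models; by default the compiled model likelihood is
    used.  All averaging happens in log space (log-sum-exp), so individual
    likelihood underflow is harmless.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if prior.n_params != spec.n_params:
        raise ValueError("prior dimension does not match the model")
    rng = np.random.default_rng(seed)
    draws = prior.sample(rng, K)
    if loglik_fn is not None:
        lls = np.asarray(loglik_fn(draws), dtype=float)
    else:
        ct = compiled or compile_trials(dataset, spec)
        lls = log_likelihood_many(transform_to_native(draws, spec), ct)
    est, se = _is_estimate(lls)
    return est, se, SubjectSamples(draws=draws, logliks=lls)


def group_score(
    datasets: Sequence[SubjectDataset],
    fit: FitResult,
    K: int = 2000,
    seed: int = 0,
) -> ModelEvidence:
    """Penalized group score of one fitted model on a cohort (lower = better)."""
    spec = fit.spec
    prior = fit.group_prior
    ests = np.empty(len(datasets))
    ses = np.empty(len(datasets))
    samples = []
    n_choices = 0
    for i, ds in enumerate(datasets):
        ct = compile_trials(ds, spec)
        n_choices += ct.n_trials
        est, se, smp = integrated_subject_likelihood(
            ds, prior, spec, K,
            np.random.SeedSequence(entropy=seed, spawn_key=(i,)),
            compiled=ct,
        )
        ests[i] = est
        ses[i] = se
        samples.append(smp)
    n_hyper = 2 * len(spec.hyper_groups)
    penalty = n_hyper * float(np.log(max(n_choices, 1)))
    return ModelEvidence(
        model_id=spec.model_id,
        per_subject_loglik=ests,
        per_subject_mc_error=ses,
        K=K,
        n_hyper=n_hyper,
        n_choices=n_choices,
        penalty=penalty,
        seed=seed,
        samples=samples,
    )


def _shifted_group_loglik(
    evidence: ModelEvidence, prior: GroupPrior, coords, delta: float
) -> float:
    """Group log likelihood with the prior mean shifted on ``coords``.

    Uses only the retained samples: each draw is re-weighted by the density
    ratio of the shifted to the original prior, which for a diagonal
    Gaussian is exp(delta * (x - mu - delta/2) / sigma2) per coordinate.
    """
    total = 0.0
    for smp in evidence.samples:
        logr = np.zeros(smp.draws.shape[0])
        for c in coords:
            x = smp.draws[:, c]
            logr += delta * (x - prior.mean[c] - 0.5 * delta) / prior.var[c]
        total += float(logsumexp(smp.logliks + logr) - np.log(smp.draws.shape[0]))
    return total


def _min_ess(evidence: ModelEvidence, prior: GroupPrior, coords, delta: float) -> float:
    ess = np.inf
    for smp in evidence.samples:
        logr = np.zeros(smp.draws.shape[0])
        for c in coords:
            x = smp.draws[:, c]
            logr += delta * (x - prior.mean[c] - 0.5 * delta) / prior.var[c]
        logw = smp.logliks + logr
        logw -= np.max(logw)
        w = np.exp(logw)
        ess = min(ess, float(np.sum(w) ** 2 / np.sum(w**2)))
    return ess


def _quadratic_se(deltas: np.ndarray, values: np.ndarray) -> tuple:
    """Fit a parabola; return (vertex offset, SE from curvature, ok flag)."""
    coefs = np.polyfit(deltas, values, 2)
    c2, c1 = coefs[0], coefs[1]
    if not np.isfinite(c2) or c2 >= -1e-300:
        return 0.0, np.inf, False
    vertex = -c1 / (2.0 * c2)
    return float(vertex), float(np.sqrt(-1.0 / (2.0 * c2))), True


def hyperparameter_error_bars(
    evidence: ModelEvidence,
    fit: FitResult,
    grid=(0.5, 1.0, 1.5, 2.0),
    ess_min: float = 25.0,
    n_subjects_override: Optional[int] = None,
) -> list:
    """Standard errors and 95% intervals for the fitted prior means.

    For every hyperparameter group the shifted group likelihood is evaluated
    along ``+-grid`` times a seed standard error (sigma/sqrt(n)) by sample
    re-weighting, a parabola is fitted, the grid is re-scaled once from the
    fitted curvature, and the final curvature gives the SE.  Flat likelihood
    surfaces yield an infinite SE with ``reliable=False``; so do shifts whose
    effective sample size falls below ``ess_min``.
    """
    spec = fit.spec
    prior = fit.group_prior
    n_sub = n_subjects_override or len(evidence.samples)
    # a likelihood that is constant across draws for every subject carries no
    # information about any hyperparameter: SE diverges by definition
    flat = all(np.ptp(s.logliks) < 1e-9 for s in evidence.samples)
    out = []
    for grp, name in zip(spec.hyper_groups, spec.hyper_group_names()):
        if flat:
            point = float(prior.mean[grp[0]])
            out.append(
                HyperparameterInterval(
                    name=name, point=point, se=np.inf, ci_low=-np.inf,
                    ci_high=np.inf, reliable=False,
                )
            )
            continue
        coords = list(grp)
        n_obs = n_sub * len(coords)
        se_seed = float(np.sqrt(prior.var[coords[0]] / n_obs))
        se = se_seed
        vertex = 0.0
        ok = True
        for _ in range(2):  # seed grid, then one re-scaled pass
            deltas = np.concatenate([[-m * se for m in reversed(grid)], [0.0],
                                     [m * se for m in grid]])
            vals = np.array(
                [_shifted_group_loglik(evidence, prior, coords, d) for d in deltas]
            )
            vertex, se_new, ok = _quadratic_se(deltas, vals)
            if not ok or not np.isfinite(se_new):
                se = np.inf
                break
            se = se_new
        ess = (
            _min_ess(evidence, prior, coords, 2.0 * se)
            if np.isfinite(se)
            else _min_ess(evidence, prior, coords, 0.0)
        )
        reliable = bool(ok and np.isfinite(se) and ess >= ess_min)
        point = float(prior.mean[coords[0]] + (vertex if np.isfinite(se) else 0.0))
        half = 1.96 * se
        out.append(
            HyperparameterInterval(
                name=name, point=point, se=se,
                ci_low=point - half, ci_high=point + half,
                reliable=reliable,
            )
        )
    return out


def predictive_probability(
    dataset: SubjectDataset,
    map_params: ParameterVector,
    spec: Optional[ModelSpec] = None,
):
    """Per-trial probability of each observed choice given the past.

    Returns ``(per_trial_probabilities, geometric_mean, binomial_p)``.
    A trial counts as "predicted correctly" when the model assigns the
    observed action probability > 0.5; the one-sided binomial test asks
    whether the number of such trials exceeds the Binomial(T, 1/2) chance
    level.
    """
    spec = spec or map_params.spec
    logp = per_trial_log_probabilities(dataset, map_params, spec)
    probs = np.exp(logp)
    geo = float(np.exp(np.mean(logp)))
    successes = int(np.sum(probs > 0.5))
    pval = float(binomtest(successes, len(probs), 0.5, alternative="greater").pvalue)
    return probs, geo, pval


def cohort_predictive_probability(
    datasets: Sequence[SubjectDataset], fit: FitResult
) -> pd.DataFrame:
    """Per-subject predictive summaries plus the pooled geometric mean.

    The last row (``subject_id == "__overall__"``) pools all choices of all
    subjects into one geometric mean, the cohort-level figure of merit.
    """
    rows = []
    all_logp = []
    for ds, sf in zip(datasets, fit.subject_fits):
        params = ParameterVector(fit.spec, sf.map_estimate)
        probs, geo, pval = predictive_probability(ds, params, fit.spec)
        all_logp.append(np.log(probs))
        rows.append(
            {
                "subject_id": ds.subject_id,
                "n_choices": len(probs),
                "geometric_mean": geo,
                "binomial_p": pval,
            }
        )
    pooled = np.concatenate(all_logp)
    rows.append(
        {
            "subject_id": "__overall__",
            "n_choices": len(pooled),
            "geometric_mean": float(np.exp(np.mean(pooled))),
            "binomial_p": np.nan,
        }
    )
    return pd.DataFrame(rows)


def score_table(evidences: Sequence[ModelEvidence], specs=None) -> pd.DataFrame:
    """Comparison table: id, scope, parameter count, score, delta-score.

    Delta-scores are relative to the best (lowest-scoring) model, which is
    the reported quantity; absolute scores are kept for completeness, both
    with and without the hyperparameter penalty.
    """
    from .models import get_model

    rows = []
    for ev in evidences:
        spec = get_model(ev.model_id)
        rows.append(
            {
                "model": ev.model_id,
                "data": "instr&PIT" if spec.includes_pit else "instrumental",
                "n_subject_params": spec.n_params,
                "n_hyperparams": ev.n_hyper,
                "neg2_integrated_loglik": -2.0 * ev.total_integrated_loglik,
                "penalty": ev.penalty,
                "score": ev.total_score,
            }
        )
    df = pd.DataFrame(rows)
    df["delta_score"] = df["score"] - df["score"].min()
    return df.sort_values("model").reset_index(drop=True)
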