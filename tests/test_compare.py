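"""Integrated likelihoods, group scores, error bars and predictive probability."""

import numpy as np
import pytest
from scipy.special import expit

from pitrl.compare import (
    cohort_predictive_probability,
    group_score,
    hyperparameter_error_bars,
    integrated_subject_likelihood,
    predictive_probability,
    score_table,
    _shifted_group_loglik,
)
from pitrl.fit import FitResult, FitSettings, GroupPrior, em_fit
from pitrl.models import ParameterVector, get_model
from test_fit import toy_spec


def bernoulli_loglik(k, n):
    """Vectorised one-parameter toy likelihood: k successes of n, p=sigmoid(x)."""

    def fn(draws):
        x = np.atleast_2d(draws)[:, 0]
        p = expit(x)
        return k * np.log(p) + (n - k) * np.log1p(-p)

    return fn


def quadrature_log_evidence(k, n, prior, lo=-12, hi=12, m=20001):
    grid = np.linspace(lo, hi, m)
    ll = bernoulli_loglik(k, n)(grid[:, None])
    logpost = ll - 0.5 * (grid - prior.mean[0]) ** 2 / prior.var[0] - 0.5 * np.log(
        2 * np.pi * prior.var[0]
    )
    mx = logpost.max()
    return mx + np.log(np.trapezoid(np.exp(logpost - mx), grid))


def test_k_equal_one_returns_single_draw_likelihood():
    spec = toy_spec(1)
    prior = GroupPrior(np.zeros(1), np.ones(1))
    fn = bernoulli_loglik(6, 10)
    est, se, smp = integrated_subject_likelihood(
        None, prior, spec, K=1, seed=5, loglik_fn=fn
    )
    assert est == pytest.approx(float(fn(smp.draws)[0]))
    assert se == 0.0


def test_constant_likelihood_has_zero_mc_error(m5_cohort_small):
    datasets, _ = m5_cohort_small
    ds = datasets[0]
    spec = get_model(5)
    # zero prior variance on sensitivities/biases -> coin-flip likelihood
    prior = GroupPrior(np.zeros(spec.n_params), np.full(spec.n_params, 1e-30))
    est, se, _ = integrated_subject_likelihood(ds, prior, spec, K=50, seed=0)
    T = ds.n_choices(include_pit=False)
    assert est == pytest.approx(T * np.log(0.5), rel=1e-9)
    assert se == pytest.approx(0.0, abs=1e-9)


def test_importance_sampling_matches_quadrature_oracle():
    spec = toy_spec(1)
    prior = GroupPrior(np.array([0.4]), np.array([1.5]))
    k, n = 130, 200
    oracle = quadrature_log_evidence(k, n, prior)
    est, se, _ = integrated_subject_likelihood(
        None, prior, spec, K=1000, seed=11, loglik_fn=bernoulli_loglik(k, n)
    )
    assert abs(est - oracle) <= 3 * se


def test_importance_sampling_error_shrinks_with_k():
    spec = toy_spec(1)
    prior = GroupPrior(np.array([0.4]), np.array([1.5]))
    k, n = 130, 200
    oracle = quadrature_log_evidence(k, n, prior)
    fn = bernoulli_loglik(k, n)
    mean_abs_err = {}
    for K in (10, 100, 1000):
        errs = [
            abs(
                integrated_subject_likelihood(
                    None, prior, spec, K=K, seed=1000 + r, loglik_fn=fn
                )[0]
                - oracle
            )
            for r in range(30)
        ]
        mean_abs_err[K] = np.mean(errs)
    assert mean_abs_err[10] > mean_abs_err[100] > mean_abs_err[1000]


@pytest.fixture(scope="module")
def m1_scored(m5_cohort_small):
    datasets, _ = m5_cohort_small
    spec = get_model(1)
    res = em_fit(datasets, spec,
                 FitSettings(seed=6, restarts=2, em_tol=0.02, em_max_iter=40))
    ev = group_score(datasets, res, K=400, seed=9)
    return datasets, res, ev


def test_group_score_composition(m1_scored):
    datasets, res, ev = m1_scored
    n_choices = sum(ds.n_choices(include_pit=False) for ds in datasets)
    assert ev.n_choices == n_choices
    assert ev.n_hyper == 4  # two coordinates, mean + variance each
    assert ev.penalty == pytest.approx(4 * np.log(n_choices))
    assert ev.total_score == pytest.approx(
        -2 * np.sum(ev.per_subject_loglik) + ev.penalty
    )


def test_group_score_reproducible(m1_scored):
    datasets, res, ev = m1_scored
    ev2 = group_score(datasets, res, K=400, seed=9)
    assert np.array_equal(ev.per_subject_loglik, ev2.per_subject_loglik)
    assert np.array_equal(ev.per_subject_mc_error, ev2.per_subject_mc_error)


def test_unused_extra_hyperparameters_cost_exactly_the_penalty(m1_scored):
    """Two models with identical (degenerate) likelihood surfaces differ in
    score by exactly the penalty increment of the extra hyperparameters."""
    datasets, res, ev = m1_scored
    spec1, spec5 = get_model(1), get_model(5)
    mu1 = res.group_prior.mean
    deg1 = GroupPrior(mu1, np.full(2, 1e-30))
    fit1 = FitResult(spec=spec1, group_prior=deg1, subject_fits=[],
                     trajectory=[], converged=True, n_iterations=0,
                     settings=res.settings)
    mean5 = np.zeros(spec5.n_params)
    mean5[spec5.index("eps")] = mu1[0]
    mean5[spec5.index("rho_rew")] = mu1[1]
    mean5[spec5.index("rho_pun")] = mu1[1]
    fit5 = FitResult(
        spec=spec5, group_prior=GroupPrior(mean5, np.full(spec5.n_params, 1e-30)),
        subject_fits=[], trajectory=[], converged=True, n_iterations=0,
        settings=res.settings,
    )
    ev1 = group_score(datasets, fit1, K=400, seed=9)
    ev5 = group_score(datasets, fit5, K=400, seed=9)
    extra_pen = (ev5.n_hyper - ev1.n_hyper) * np.log(ev1.n_choices)
    assert ev5.total_score - ev1.total_score == pytest.approx(extra_pen, abs=1e-6)


def test_reweighting_at_zero_offset_is_identity(m1_scored):
    datasets, res, ev = m1_scored
    base = float(np.sum(ev.per_subject_loglik))
    shifted = _shifted_group_loglik(ev, res.group_prior, [0], 0.0)
    assert shifted == pytest.approx(base, rel=1e-12)


def test_flat_likelihood_trips_unreliable_flag():
    spec = toy_spec(1)
    prior = GroupPrior(np.zeros(1), np.ones(1))
    fit = FitResult(spec=spec, group_prior=prior, subject_fits=[], trajectory=[],
                    converged=True, n_iterations=0, settings=FitSettings())
    evs = []
    for i in range(3):
        est, se, smp = integrated_subject_likelihood(
            None, prior, spec, K=200, seed=i,
            loglik_fn=lambda draws: np.full(np.atleast_2d(draws).shape[0], -7.0),
        )
        evs.append(smp)
    from pitrl.compare import ModelEvidence

    ev = ModelEvidence(
        model_id=0, per_subject_loglik=np.full(3, -7.0),
        per_subject_mc_error=np.zeros(3), K=200, n_hyper=2, n_choices=10,
        penalty=0.0, seed=0, samples=evs,
    )
    ivs = hyperparameter_error_bars(ev, fit)
    assert not ivs[0].reliable
    assert not np.isfinite(ivs[0].se)


def test_error_bars_match_conjugate_gaussian_toy():
    """Gaussian 'likelihood' per subject: SE of the prior mean has a closed form."""
    rng = np.random.default_rng(3)
    spec = toy_spec(1)
    n_sub, tau2 = 12, 0.3  # per-subject observation noise
    prior = GroupPrior(np.array([0.2]), np.array([0.8]))
    obs = prior.mean[0] + np.sqrt(prior.var[0] + tau2) * rng.standard_normal(n_sub)
    samples = []
    ests = []
    for i, y in enumerate(obs):
        fn = lambda draws, y=y: -0.5 * (np.atleast_2d(draws)[:, 0] - y) ** 2 / tau2
        est, se, smp = integrated_subject_likelihood(
            None, prior, spec, K=4000, seed=100 + i, loglik_fn=fn
        )
        ests.append(est)
        samples.append(smp)
    from pitrl.compare import ModelEvidence

    ev = ModelEvidence(
        model_id=0, per_subject_loglik=np.array(ests),
        per_subject_mc_error=np.zeros(n_sub), K=4000, n_hyper=2, n_choices=1,
        penalty=0.0, seed=0, samples=samples,
    )
    fit = FitResult(spec=spec, group_prior=prior, subject_fits=[], trajectory=[],
                    converged=True, n_iterations=0, settings=FitSettings())
    ivs = hyperparameter_error_bars(ev, fit)
    closed_form = np.sqrt((prior.var[0] + tau2) / n_sub)
    assert ivs[0].se == pytest.approx(closed_form, rel=0.15)
    assert ivs[0].ci_low <= ivs[0].point <= ivs[0].ci_high


def test_predictive_probability_chance_agent(m10_cohort_small):
    datasets, _ = m10_cohort_small
    ds = datasets[0]
    spec = get_model(10)
    params = ParameterVector.from_inference(spec, np.zeros(spec.n_params))
    probs, geo, pval = predictive_probability(ds, params, spec)
    assert np.all(probs == 0.5)
    assert geo == pytest.approx(0.5, abs=1e-15)
    assert pval == pytest.approx(1.0)


def test_predictive_probability_sharp_agent():
    """A deterministic agent evaluated at very large sensitivities is nearly
    perfectly predicted."""
    from pitrl.simulate import simulate_subject
    from pitrl.task import build_default_task_config

    spec = get_model(5)
    sharp = ParameterVector.from_dict(
        spec, {"eps": 0.9999, "rho_rew": 50.0, "rho_pun": 50.0}
    )
    ds = simulate_subject(sharp, spec, build_default_task_config(), seed=2)
    _, geo, pval = predictive_probability(ds, sharp, spec)
    assert geo > 0.9
    assert pval < 1e-10


def test_cohort_predictive_summary_matches_recomputation(m5_cohort_small):
    datasets, _ = m5_cohort_small
    spec = get_model(5)
    res = em_fit(datasets, spec,
                 FitSettings(seed=1, restarts=1, em_tol=1e9, em_max_iter=2))
    table = cohort_predictive_probability(datasets, res)
    logs = []
    for ds, sf in zip(datasets, res.subject_fits):
        probs, geo, _ = predictive_probability(
            ds, ParameterVector(spec, sf.map_estimate), spec
        )
        row = table[table.subject_id == ds.subject_id].iloc[0]
        assert row["geometric_mean"] == pytest.approx(geo)
        logs.append(np.log(probs))
    pooled = float(np.exp(np.mean(np.concatenate(logs))))
    assert table.iloc[-1]["geometric_mean"] == pytest.approx(pooled)


def test_score_table_reports_delta_relative_to_best(m1_scored):
    datasets, res, ev = m1_scored
    df = score_table([ev])
    assert df["delta_score"].iloc[0] == 0.0
    assert df["score"].iloc[0] == pytest.approx(ev.total_score)
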