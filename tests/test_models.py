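"""Likelihood-model family: transforms, dynamics, hand-computed oracles,
nesting identities and gradient correctness."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit

from pitrl.models import (
    ParameterVector,
    QState,
    ScopeError,
    StageError,
    action_weights,
    choice_probabilities,
    compile_trials,
    get_model,
    per_trial_log_probabilities,
    subject_log_likelihood,
    subject_log_likelihood_and_grad,
    transform_to_inference,
    transform_to_native,
    update_q,
)
from pitrl.task import APPROACH, GO, NOGO, WITHDRAWAL
from conftest import make_dataset, make_instrumental_trial, make_pit_trial


def params_from(model_id, **native):
    spec = get_model(model_id)
    return ParameterVector.from_dict(spec, native)


# ---------------------------------------------------------------------------
# transforms


@pytest.mark.parametrize("model_id", range(1, 11))
def test_transform_roundtrip(model_id):
    spec = get_model(model_id)
    rng = np.random.default_rng(model_id)
    x = rng.normal(0, 2, spec.n_params)
    back = transform_to_inference(transform_to_native(x, spec), spec)
    assert np.max(np.abs(back - x)) <= 1e-12


def test_transform_maps_learning_rate_through_sigmoid():
    spec = get_model(1)
    native = transform_to_native(np.array([0.0, -1.3]), spec)
    assert native[spec.index("eps")] == 0.5  # sigmoid(0)
    assert native[spec.index("rho")] == -1.3  # identity on sensitivities


@given(st.floats(-5, 5), st.floats(-5, 5))
def test_transform_constrained_coordinates_stay_in_unit_interval(a, b):
    spec = get_model(9)
    x = np.zeros(spec.n_params)
    x[spec.index("eps")] = a
    x[spec.index("gamma")] = b
    native = transform_to_native(x, spec)
    assert 0 < native[spec.index("eps")] < 1
    assert 0 < native[spec.index("gamma")] < 1


# ---------------------------------------------------------------------------
# softmax


def test_softmax_basics():
    assert choice_probabilities({GO: 0.0, NOGO: 0.0}) == {GO: 0.5, NOGO: 0.5}
    p = choice_probabilities({GO: np.log(3.0), NOGO: 0.0})
    assert p[GO] == pytest.approx(0.75, abs=1e-12)
    p = choice_probabilities({GO: 1000.0, NOGO: 0.0})
    assert p[GO] == pytest.approx(1.0)
    assert np.isfinite(p[NOGO])
    with pytest.raises(FloatingPointError):
        choice_probabilities({GO: np.inf, NOGO: 0.0})


@given(
    st.floats(-700, 700), st.floats(-700, 700),
    st.floats(-100, 100),
)
def test_softmax_normalized_and_shift_invariant(wg, wn, shift):
    p = choice_probabilities({GO: wg, NOGO: wn})
    assert p[GO] + p[NOGO] == pytest.approx(1.0, abs=1e-12)
    q = choice_probabilities({GO: wg + shift, NOGO: wn + shift})
    assert q[GO] == pytest.approx(p[GO], abs=1e-9)


# ---------------------------------------------------------------------------
# Q updates (hand-iterated oracles)


def test_q_update_three_rewards():
    # eps=0.5, rho=1: Q after successive rewards on the same pair
    params = params_from(1, eps=0.5, rho=1.0)
    spec = get_model(1)
    state = QState()
    expected = [0.5, 0.75, 0.875]
    for i, want in enumerate(expected):
        t = make_instrumental_trial(i, action=GO, outcome=20)
        state = update_q(state, t, params, spec)
        assert state.value("app_s1", GO) == pytest.approx(want, abs=1e-12)


def test_q_update_zero_learning_rate_freezes_values():
    params = params_from(1, eps=1e-300, rho=1.0)
    # native eps under the logistic floor of from_dict is ~1e-15; use exact 0
    params = ParameterVector.from_inference(get_model(1), [-750.0, 1.0])
    spec = get_model(1)
    state = update_q(QState(), make_instrumental_trial(0, outcome=20), params, spec)
    assert state.value("app_s1", GO) == pytest.approx(0.0, abs=1e-300)


def test_q_update_zero_punishment_sensitivity_still_punishes():
    # a zero-valued punishment pulls Q toward 0, below positive expectations
    params = params_from(2, eps=0.5, rho_rew=1.0, rho_pun=0.0)
    spec = get_model(2)
    state = QState()
    state.q[("app_s1", GO)] = 0.6
    state = update_q(
        state, make_instrumental_trial(0, action=GO, outcome=-20), params, spec
    )
    assert state.value("app_s1", GO) == pytest.approx(0.3, abs=1e-12)


def test_q_update_requires_outcome():
    with pytest.raises(StageError):
        update_q(QState(), make_pit_trial(0), params_from(1), get_model(1))


def test_model3_uses_outcome_specific_learning_rate():
    params = params_from(3, eps_rew=0.5, eps_pun=0.1, rho=1.0)
    spec = get_model(3)
    s1 = update_q(QState(), make_instrumental_trial(0, outcome=20), params, spec)
    assert s1.value("app_s1", GO) == pytest.approx(0.5)
    s2 = update_q(QState(), make_instrumental_trial(0, outcome=-20), params, spec)
    assert s2.value("app_s1", GO) == pytest.approx(-0.1)


# ---------------------------------------------------------------------------
# action weights


def test_action_weights_additive_definition():
    params = params_from(5, eps=0.5, rho_rew=1.0, rho_pun=1.0, b_app=0.7)
    spec = get_model(5)
    state = QState()
    state.q[("app_s1", GO)] = 0.3
    state.q[("app_s1", NOGO)] = -0.2
    w = action_weights(state, make_instrumental_trial(0), params, spec)
    assert w[GO] == pytest.approx(1.0, abs=1e-12)
    assert w[NOGO] == pytest.approx(-0.2, abs=1e-12)


def test_action_weights_all_zero_parameters():
    w = action_weights(QState(), make_instrumental_trial(0), params_from(5),
                       get_model(5))
    assert w == {GO: 0.0, NOGO: 0.0}


def test_pit_trial_rejected_by_instrumental_only_model():
    with pytest.raises(ScopeError):
        action_weights(QState(), make_pit_trial(0), params_from(5), get_model(5))


def test_extinction_decay_hand_case():
    # gamma=0.5, Q_end(go)=0.8: on the 2nd PIT trial of the block the
    # effective go contribution is 0.8 * 0.5**2 = 0.2
    params = params_from(9, eps=0.5, rho_rew=1.0, rho_pun=1.0, gamma=0.5)
    spec = get_model(9)
    state = QState()
    state.q[("app_s1", GO)] = 0.8
    state = state.advance_pit(APPROACH)  # one PIT trial already taken
    w = action_weights(state, make_pit_trial(1), params, spec)
    assert w[GO] == pytest.approx(0.2, abs=1e-12)
    assert w[NOGO] == pytest.approx(0.0, abs=1e-12)


def test_pit_weight_attaches_to_go_only():
    spec = get_model(8)
    native = {"pi_app_p100": 1.3}
    params = ParameterVector.from_dict(spec, native)
    w = action_weights(QState(), make_pit_trial(0, pav="app_p+100"), params, spec)
    assert w[GO] == pytest.approx(1.3)
    assert w[NOGO] == 0.0
    w2 = action_weights(QState(), make_pit_trial(0, pav="app_p0"), params, spec)
    assert w2[GO] == 0.0


# ---------------------------------------------------------------------------
# subject log-likelihood


def three_trial_dataset():
    return make_dataset(
        [
            make_instrumental_trial(0, action=GO, outcome=20, correct=GO),
            make_instrumental_trial(1, action=GO, outcome=-20, correct=GO),
            make_instrumental_trial(2, action=NOGO, outcome=-20, correct=GO),
        ]
    )


def test_three_trial_hand_likelihood():
    # model 5, eps=.5, rho_rew=1, rho_pun=2, b_app=.3; hand iteration:
    #   t0: Q=0, W(go)=.3          -> p(go)  = sigmoid(.3);  reward: Qgo=.5
    #   t1: W(go)=.8               -> p(go)  = sigmoid(.8);  punish: Qgo=-.75
    #   t2: W(go)=-.45, W(nogo)=0  -> p(nogo)= sigmoid(.45); punish on nogo
    params = params_from(5, eps=0.5, rho_rew=1.0, rho_pun=2.0, b_app=0.3)
    want = float(np.log(expit(0.3)) + np.log(expit(0.8)) + np.log(expit(0.45)))
    got = subject_log_likelihood(three_trial_dataset(), params)
    assert got == pytest.approx(want, abs=1e-12)


def test_all_zero_parameters_give_chance_likelihood(m10_cohort_small):
    datasets, _ = m10_cohort_small
    ds = datasets[0]
    for model_id in (1, 5, 10):
        spec = get_model(model_id)
        params = params_from(model_id)  # all sensitivities/biases zero
        T = ds.n_choices(include_pit=spec.includes_pit)
        ll = subject_log_likelihood(ds, params, spec)
        assert ll == pytest.approx(T * np.log(0.5), rel=1e-12)


@pytest.mark.parametrize(
    "small_id,big_id,tie",
    [
        (1, 5, {"rho_rew": "rho", "rho_pun": "rho"}),
        (2, 5, {}),
        (5, 6, {"rho_rew_app": "rho_rew", "rho_rew_wth": "rho_rew",
                "rho_pun_app": "rho_pun", "rho_pun_wth": "rho_pun"}),
        (5, 7, {"eps_app": "eps", "eps_wth": "eps"}),
        (8, 10, {}),
    ],
)
def test_nesting_identities(small_id, big_id, tie, m10_cohort_small):
    """Each smaller model is an exact special case of its extension."""
    datasets, _ = m10_cohort_small
    small, big = get_model(small_id), get_model(big_id)
    rng = np.random.default_rng(small_id * 10 + big_id)
    x_small = rng.normal(0, 0.8, small.n_params)
    small_map = dict(zip(small.param_names, transform_to_native(x_small, small)))
    big_native = {}
    for name in big.param_names:
        src = tie.get(name, name)
        big_native[name] = small_map.get(src, 0.0)  # extras (b, xi) zero
    p_small = ParameterVector.from_inference(small, x_small)
    p_big = ParameterVector.from_dict(big, big_native)
    for ds in datasets[:2]:
        ll_small = subject_log_likelihood(ds, p_small, small)
        ll_big = subject_log_likelihood(ds, p_big, big)
        assert ll_big == pytest.approx(ll_small, abs=1e-9)


def test_model8_equals_model9_at_unit_decay(m10_cohort_small):
    datasets, _ = m10_cohort_small
    m8, m9 = get_model(8), get_model(9)
    rng = np.random.default_rng(89)
    x8 = rng.normal(0, 0.8, m8.n_params)
    nat8 = dict(zip(m8.param_names, transform_to_native(x8, m8)))
    nat9 = dict(nat8, gamma=1.0 - 1e-15)
    p8 = ParameterVector.from_inference(m8, x8)
    p9 = ParameterVector.from_dict(m9, nat9)
    for ds in datasets[:2]:
        assert subject_log_likelihood(ds, p9, m9) == pytest.approx(
            subject_log_likelihood(ds, p8, m8), abs=1e-9
        )


def test_likelihood_invariant_to_stimulus_relabelling(m5_cohort_small):
    import dataclasses

    datasets, _ = m5_cohort_small
    ds = datasets[0]
    spec = get_model(5)
    params = params_from(5, eps=0.3, rho_rew=2.0, rho_pun=0.5, b_app=0.2,
                         b_wth=-0.4)
    renamed = [
        dataclasses.replace(
            t,
            instrumental_stimulus=(
                None if t.instrumental_stimulus is None
                else "zz_" + t.instrumental_stimulus
            ),
        )
        for t in ds.trials
    ]
    ds2 = make_dataset(renamed, config=ds.config)
    assert subject_log_likelihood(ds2, params, spec) == pytest.approx(
        subject_log_likelihood(ds, params, spec), rel=1e-12
    )


@pytest.mark.parametrize("model_id", range(1, 11))
def test_analytic_gradient_matches_finite_differences(model_id, m10_cohort_small):
    datasets, _ = m10_cohort_small
    ds = datasets[1]
    spec = get_model(model_id)
    ct = compile_trials(ds, spec)
    rng = np.random.default_rng(model_id)
    x = rng.normal(0, 0.7, spec.n_params)
    ll, g = subject_log_likelihood_and_grad(x, spec, ct)
    h = 1e-6
    for i in range(spec.n_params):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        fd = (
            subject_log_likelihood_and_grad(xp, spec, ct)[0]
            - subject_log_likelihood_and_grad(xm, spec, ct)[0]
        ) / (2 * h)
        assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


def test_per_trial_probabilities_sum_to_likelihood(m10_cohort_small):
    datasets, _ = m10_cohort_small
    ds = datasets[2]
    spec = get_model(10)
    params = ParameterVector.from_inference(
        spec, np.random.default_rng(4).normal(0, 0.5, spec.n_params)
    )
    logp = per_trial_log_probabilities(ds, params, spec)
    assert len(logp) == ds.n_choices(include_pit=True)
    assert np.sum(logp) == pytest.approx(
        subject_log_likelihood(ds, params, spec), rel=1e-12
    )
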