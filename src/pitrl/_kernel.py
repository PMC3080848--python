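"""Numba likelihood kernels.

The per-subject likelihood walks the choice trials in order, maintaining the
Rescorla-Wagner table Q[stimulus, action] (and, for the gradient, its exact
derivative w.r.t. every native-space parameter).  Trials arrive pre-compiled
as index arrays (see ``models.compile_trials``): for each trial the arrays
say which parameter coordinate supplies the learning rate, sensitivity,
bias, transfer weight and offset, so one kernel serves all ten models.

Index conventions: action 1 = go, 0 = nogo; ``r`` is +1/-1 on instrumental
trials; an index of -1 means "this term is absent from the model"; ``pitk``
is the 1-based PIT-trial counter within the block (the extinction model
scales Q by gamma**pitk).
"""

import numpy as np
from numba import njit


@njit(cache=False)
def _logp_chosen(wd, a):
    """log p(observed action) for weight difference wd = W(go) - W(nogo)."""
    z = wd if a == 1 else -wd
    # -log(1 + exp(-z)), stable for |z| up to the double range
    if z > 0.0:
        return -np.log1p(np.exp(-z))
    return z - np.log1p(np.exp(z))


@njit(cache=False)
def loglik(theta, stim, act, is_pit, r, ieps, irho, ib, ipi, ixi, igamma,
           pitk, n_stim):
    Q = np.zeros((n_stim, 2))
    ll = 0.0
    for t in range(stim.shape[0]):
        s = stim[t]
        a = act[t]
        wd = Q[s, 1] - Q[s, 0]
        if is_pit[t] == 1:
            if igamma >= 0:
                wd *= theta[igamma] ** pitk[t]
            if ixi[t] >= 0:
                wd += theta[ixi[t]]
            if ipi[t] >= 0:
                wd += theta[ipi[t]]
        if ib[t] >= 0:
            wd += theta[ib[t]]
        ll += _logp_chosen(wd, a)
        if is_pit[t] == 0:
            eps = theta[ieps[t]]
            rho = theta[irho[t]]
            Q[s, a] = Q[s, a] + eps * (rho * r[t] - Q[s, a])
    return ll


@njit(cache=False)
def loglik_trials(theta, stim, act, is_pit, r, ieps, irho, ib, ipi, ixi,
                  igamma, pitk, n_stim):
    T = stim.shape[0]
    out = np.empty(T)
    Q = np.zeros((n_stim, 2))
    for t in range(T):
        s = stim[t]
        a = act[t]
        wd = Q[s, 1] - Q[s, 0]
        if is_pit[t] == 1:
            if igamma >= 0:
                wd *= theta[igamma] ** pitk[t]
            if ixi[t] >= 0:
                wd += theta[ixi[t]]
            if ipi[t] >= 0:
                wd += theta[ipi[t]]
        if ib[t] >= 0:
            wd += theta[ib[t]]
        out[t] = _logp_chosen(wd, a)
        if is_pit[t] == 0:
            eps = theta[ieps[t]]
            rho = theta[irho[t]]
            Q[s, a] = Q[s, a] + eps * (rho * r[t] - Q[s, a])
    return out


@njit(cache=False)
def loglik_many(thetas, stim, act, is_pit, r, ieps, irho, ib, ipi, ixi,
                igamma, pitk, n_stim):
    K = thetas.shape[0]
    out = np.empty(K)
    for k in range(K):
        out[k] = loglik(thetas[k], stim, act, is_pit, r, ieps, irho, ib,
                        ipi, ixi, igamma, pitk, n_stim)
    return out


@njit(cache=False)
def loglik_grad(theta, stim, act, is_pit, r, ieps, irho, ib, ipi, ixi,
                igamma, pitk, n_stim):
    """Log-likelihood and its exact native-space gradient.

    G[s, a, p] carries dQ[s, a]/dtheta[p] through the recursion:
        Q_new = Q + eps * (rho * r - Q)
    so  dQ_new/dp = (1 - eps) dQ/dp  (+ eps*r on the rho coordinate,
    + (rho*r - Q) on the eps coordinate).  On extinction-model PIT trials
    the weight difference is gamma**k * (Qg - Qn), contributing
    k * gamma**(k-1) * (Qg - Qn) to the gamma coordinate.
    """
    P = theta.shape[0]
    T = stim.shape[0]
    Q = np.zeros((n_stim, 2))
    G = np.zeros((n_stim, 2, P))
    g = np.zeros(P)
    dw = np.zeros(P)
    ll = 0.0
    for t in range(T):
        s = stim[t]
        a = act[t]
        qd = Q[s, 1] - Q[s, 0]
        for p in range(P):
            dw[p] = G[s, 1, p] - G[s, 0, p]
        wd = qd
        if is_pit[t] == 1:
            if igamma >= 0:
                gam = theta[igamma]
                k = pitk[t]
                f = gam ** k
                for p in range(P):
                    dw[p] *= f
                dw[igamma] += k * gam ** (k - 1) * qd
                wd = f * qd
            if ixi[t] >= 0:
                wd += theta[ixi[t]]
                dw[ixi[t]] += 1.0
            if ipi[t] >= 0:
                wd += theta[ipi[t]]
                dw[ipi[t]] += 1.0
        if ib[t] >= 0:
            wd += theta[ib[t]]
            dw[ib[t]] += 1.0
        ll += _logp_chosen(wd, a)
        # d log p / d wd = (a - p_go)
        if wd >= 0.0:
            pgo = 1.0 / (1.0 + np.exp(-wd))
        else:
            e = np.exp(wd)
            pgo = e / (1.0 + e)
        coef = a - pgo
        for p in range(P):
            g[p] += coef * dw[p]
        if is_pit[t] == 0:
            eps = theta[ieps[t]]
            rho = theta[irho[t]]
            old = Q[s, a]
            delta = rho * r[t] - old
            Q[s, a] = old + eps * delta
            for p in range(P):
                G[s, a, p] *= 1.0 - eps
            G[s, a, irho[t]] += eps * r[t]
            G[s, a, ieps[t]] += delta
    return ll, g
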