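"""Hierarchical empirical-Bayes fitting (MAP + Laplace + EM).

Each subject's parameters are estimated by maximum a posteriori under a
diagonal Gaussian group prior in inference space; the posterior around the
MAP is approximated by a Laplace (local curvature) Gaussian; and the group
prior is re-estimated by moment matching across subjects.  Iterating the
two steps is Expectation-Maximisation for the group-level likelihood, with
the Laplace approximation standing in for the exact E-step.

The M-step sets, per coordinate,

    mu     = mean_i( m_i )
    sigma2 = mean_i( m_i**2 + v_i ) - mu**2      (floored)

where ``m_i`` is subject i's MAP and ``v_i`` the Laplace posterior variance
— i.e. the prior variance matches the second moment of the approximate
posteriors.  For model 10 the twelve generalization offsets share a single
(mean, variance) pair: they are fitted per subject and per stimulus but
pooled in the M-step exactly like one coordinate observed twelve times.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.optimize

from .models import (
    CompiledTrials,
    ModelSpec,
    ParameterVector,
    compile_trials,
    subject_log_likelihood_and_grad,
)
from .task import SubjectDataset

__all__ = [
    "GroupPrior",
    "FitSettings",
    "SubjectFit",
    "FitResult",
    "FitError",
    "map_estimate",
    "m_step",
    "em_fit",
]


class FitError(RuntimeError):
    """Raised when every optimizer restart fails to converge."""


@dataclass
class GroupPrior:
    """Diagonal Gaussian over inference-space parameters."""

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if self.mean.shape != self.var.shape or self.mean.ndim != 1:
            raise ValueError("mean and var must be 1-d arrays of equal length")
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be strictly positive")

    @property
    def n_params(self) -> int:
        return self.mean.shape[0]

    @classmethod
    def default_init(cls, spec: ModelSpec, mean: float = 0.0, var: float = 6.25):
        """Weakly informative starting prior (zero mean, sd 2.5 per coordinate)."""
        d = spec.n_params
        return cls(np.full(d, mean), np.full(d, var))

    def logpdf(self, x: np.ndarray) -> float:
        z = (x - self.mean) ** 2 / self.var
        return float(-0.5 * np.sum(z + np.log(2.0 * np.pi * self.var)))

    def grad_logpdf(self, x: np.ndarray) -> np.ndarray:
        return -(x - self.mean) / self.var

    def sample(self, rng: np.random.Generator, size: Optional[int] = None) -> np.ndarray:
        shape = (self.n_params,) if size is None else (size, self.n_params)
        return self.mean + np.sqrt(self.var) * rng.standard_normal(shape)


@dataclass(frozen=True)
class FitSettings:
    """Optimizer and EM controls.

    ``restarts`` quasi-Newton starts (prior mean plus prior-scaled jitter)
    are used on the first E-step; later E-steps warm-start from the previous
    MAP.  The Hessian at the MAP is built by central finite differences of
    the analytic gradient with step ``hessian_step``.
    """

    restarts: int = 4
    jitter_scale: float = 1.0
    seed: int = 0
    max_opt_iter: int = 500
    hessian_step: float = 1e-4
    em_tol: float = 1e-3
    em_max_iter: int = 100
    var_floor: float = 1e-6


@dataclass
class SubjectFit:
    """MAP estimate and Laplace moments for one subject."""

    subject_id: str
    map_estimate: np.ndarray  # inference space
    posterior_variance: np.ndarray
    log_posterior_at_map: float
    log_likelihood_at_map: float
    converged: bool
    restarts_used: int
    hessian_pd: bool
    # diagonal curvature of the negative log-likelihood at the MAP; lets the
    # EM objective include the second-order likelihood term
    neg_loglik_curvature: Optional[np.ndarray] = None


@dataclass
class FitResult:
    """Converged group prior, per-subject fits and the EM trajectory."""

    spec: ModelSpec
    group_prior: GroupPrior
    subject_fits: list
    trajectory: list  # per-iteration Laplace approximation of the group objective
    converged: bool
    n_iterations: int
    settings: FitSettings

    def map_matrix(self) -> np.ndarray:
        return np.array([f.map_estimate for f in self.subject_fits])

    def parameter_vector(self, i: int) -> ParameterVector:
        return ParameterVector(self.spec, self.subject_fits[i].map_estimate)


def _default_loglik(spec: ModelSpec, compiled: CompiledTrials) -> Callable:
    def fn(x: np.ndarray):
        return subject_log_likelihood_and_grad(x, spec, compiled)

    return fn


def _hessian(grad_neg: Callable, x: np.ndarray, step: float) -> np.ndarray:
    d = x.shape[0]
    H = np.empty((d, d))
    for i in range(d):
        e = np.zeros(d)
        e[i] = step
        H[i] = (grad_neg(x + e) - grad_neg(x - e)) / (2.0 * step)
    return 0.5 * (H + H.T)


def map_estimate(
    dataset: Optional[SubjectDataset],
    prior: GroupPrior,
    spec: ModelSpec,
    settings: Optional[FitSettings] = None,
    compiled: Optional[CompiledTrials] = None,
    init: Optional[np.ndarray] = None,
    loglik_and_grad: Optional[Callable] = None,
    seed: Optional[int] = None,
) -> SubjectFit:
    """Quasi-Newton MAP fit of one subject under the group prior.

    ``loglik_and_grad(x) -> (ll, grad)`` may be injected (e.g. a toy
    quadratic likelihood in tests); by default it is the compiled model
    likelihood for ``dataset``.  Posterior variances come from the diagonal
    of the inverse negative Hessian of the log posterior at the MAP; any
    non-positive-curvature coordinate falls back to its prior variance and
    is flagged via ``hessian_pd``.
    """
    settings = settings or FitSettings()
    if prior.n_params != spec.n_params:
        raise ValueError("prior dimension does not match the model")
    if loglik_and_grad is None:
        ct = compiled or compile_trials(dataset, spec)
        loglik_and_grad = _default_loglik(spec, ct)

    def objective(x):
        ll, g = loglik_and_grad(x)
        return (
            -(ll + prior.logpdf(x)),
            -(np.asarray(g) + prior.grad_logpdf(x)),
        )

    def grad_neg(x):
        return objective(x)[1]

    rng = np.random.default_rng(
        np.random.SeedSequence((settings.seed if seed is None else seed, 0xF17))
    )
    n_starts = max(settings.restarts, 1)
    starts = []
    if init is not None:
        starts.append(np.asarray(init, dtype=float))
    if len(starts) < n_starts:
        starts.append(prior.mean.copy())
    while len(starts) < n_starts:
        starts.append(
            prior.mean
            + settings.jitter_scale * np.sqrt(prior.var) * rng.standard_normal(prior.n_params)
        )

    best = None
    n_ok = 0
    for x0 in starts:
        res = scipy.optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": settings.max_opt_iter},
        )
        if np.all(np.isfinite(res.x)) and np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise FitError(
            f"all {len(starts)} restarts failed for subject "
            f"{getattr(dataset, 'subject_id', '?')}"
        )

    x = best.x
    H = _hessian(grad_neg, x, settings.hessian_step)
    eigvals = np.linalg.eigvalsh(H)
    pd = bool(eigvals[0] > 0)
    if pd:
        var = np.diag(np.linalg.inv(H)).copy()
        if np.any(var <= 0):  # numerically indefinite despite positive eigs
            pd = False
    if not pd:
        diag = np.diag(H)
        var = np.where(diag > 0, 1.0 / np.maximum(diag, 1e-300), prior.var)
    var = np.minimum(np.maximum(var, 1e-12), 1e12)

    ll_at_map = float(loglik_and_grad(x)[0])
    return SubjectFit(
        subject_id=getattr(dataset, "subject_id", "synthetic"),
        map_estimate=x,
        posterior_variance=var,
        log_posterior_at_map=float(-best.fun),
        log_likelihood_at_map=ll_at_map,
        converged=bool(best.success or np.max(np.abs(best.jac)) < 1e-3),
        restarts_used=n_ok,
        hessian_pd=pd,
        neg_loglik_curvature=np.diag(H) - 1.0 / prior.var,
    )


def m_step(
    subject_fits: Sequence[SubjectFit],
    spec: Optional[ModelSpec] = None,
    var_floor: float = 1e-6,
) -> GroupPrior:
    """Moment-matching update of the group prior from the subject fits.

    Coordinates listed together in ``spec.hyper_groups`` (the model-10
    offsets) are pooled into one shared mean and variance.  Without a spec
    every coordinate is its own group.
    """
    if len(subject_fits) < 2:
        raise ValueError("m_step needs at least 2 subjects")
    M = np.array([f.map_estimate for f in subject_fits])
    V = np.array([f.posterior_variance for f in subject_fits])
    d = M.shape[1]
    groups = spec.hyper_groups if spec is not None else tuple((i,) for i in range(d))
    mean = np.empty(d)
    var = np.empty(d)
    for grp in groups:
        cols = list(grp)
        mu = float(np.mean(M[:, cols]))
        second = float(np.mean(M[:, cols] ** 2 + V[:, cols]))
        mean[cols] = mu
        var[cols] = max(second - mu**2, var_floor)
    return GroupPrior(mean, var)


def _laplace_objective(fits: Sequence[SubjectFit], prior: GroupPrior) -> float:
    """EM lower bound (free energy) under the Laplace posteriors.

    Per subject: the expected log joint under the Gaussian posterior
    q = N(m, v) — the log-likelihood at the MAP minus the second-order
    curvature correction v * H_lik / 2, plus the expected log prior (which
    carries the -v/(2 sigma2) term) — plus the entropy of q.  The
    moment-matching M-step maximizes this bound exactly; the Laplace E-step
    maximizes it approximately, so the trajectory is non-decreasing up to
    E-step approximation error.
    """
    total = 0.0
    for f in fits:
        m, v = f.map_estimate, f.posterior_variance
        e_loglik = f.log_likelihood_at_map
        if f.neg_loglik_curvature is not None:
            e_loglik -= 0.5 * float(np.sum(v * f.neg_loglik_curvature))
        e_logprior = -0.5 * float(
            np.sum(
                np.log(2.0 * np.pi * prior.var)
                + ((m - prior.mean) ** 2 + v) / prior.var
            )
        )
        entropy = 0.5 * float(np.sum(np.log(2.0 * np.pi * np.e * v)))
        total += e_loglik + e_logprior + entropy
    return total


def em_fit(
    datasets: Sequence[SubjectDataset],
    spec: ModelSpec,
    settings: Optional[FitSettings] = None,
    init_prior: Optional[GroupPrior] = None,
) -> FitResult:
    """Fit the group prior and all subjects by MAP-EM with Laplace E-steps.

    Deterministic given ``settings.seed``.  The tracked objective is the
    Laplace approximation of the total log evidence; iteration stops when it
    changes by less than ``em_tol`` or after ``em_max_iter`` iterations.
    """
    settings = settings or FitSettings()
    if len(datasets) < 2:
        raise ValueError("em_fit needs at least 2 subjects")
    compiled = [compile_trials(ds, spec) for ds in datasets]
    prior = init_prior or GroupPrior.default_init(spec)

    fits: list = []
    trajectory: list = []
    prev_obj = -np.inf
    converged = False
    it = 0
    for it in range(1, settings.em_max_iter + 1):
        new_fits = []
        for i, (ds, ct) in enumerate(zip(datasets, compiled)):
            warm = fits[i].map_estimate if fits else None
            sub_settings = settings if not fits else replace(settings, restarts=1)
            new_fits.append(
                map_estimate(
                    ds,
                    prior,
                    spec,
                    settings=sub_settings,
                    compiled=ct,
                    init=warm,
                    seed=hash((settings.seed, it, i)) % (2**31),
                )
            )
        fits = new_fits
        obj = _laplace_objective(fits, prior)
        trajectory.append(obj)
        if np.isfinite(prev_obj) and abs(obj - prev_obj) < settings.em_tol:
            converged = True
            prior = m_step(fits, spec, settings.var_floor)
            break
        prev_obj = obj
        prior = m_step(fits, spec, settings.var_floor)

    return FitResult(
        spec=spec,
        group_prior=prior,
        subject_fits=fits,
        trajectory=trajectory,
        converged=converged,
        n_iterations=it,
        settings=settings,
    )
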