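"""The family of reinforcement-learning choice models (Models 1-10).

All models share the same skeleton.  On each choice trial the subject sees
an instrumental stimulus ``s`` and emits ``go`` or ``nogo``.  Action weights
are

    W(go)   = Q(s, go) + b_block [+ pi(pav, block) on PIT trials]
    W(nogo) = Q(s, nogo)

and the choice probability is a softmax (logistic in the weight
difference).  ``Q`` is a Rescorla-Wagner expectation updated only for the
chosen pair on outcome-bearing (instrumental-stage) trials,

    Q <- Q + eps * (rho * r - Q),    r = +1 reward, -1 punishment,

with ``rho`` a reward/punishment sensitivity and ``eps`` a learning rate.
The go bias ``b`` and the ten Pavlovian transfer weights ``pi`` (one per
Pavlovian stimulus per block) attach to the go action only, so the
instrumental and Pavlovian controllers superpose additively inside the
softmax.

The ten variants differ in which parameters are shared or split:

====== ============= ==========================================================
model  data scope    parameters
====== ============= ==========================================================
1      instrumental  eps, rho (one sensitivity for rewards and punishments)
2      instrumental  eps, rho_rew, rho_pun
3      instrumental  eps_rew, eps_pun, rho
4      instrumental  eps, rho, b_app, b_wth
5      instrumental  eps, rho_rew, rho_pun, b_app, b_wth
6      instrumental  model 5 with block-specific sensitivities
7      instrumental  model 5 with block-specific learning rates
8      instr. + PIT  model 5 + 10 pi weights, exact Q generalization
9      instr. + PIT  model 8 + decay gamma: effective Q on PIT trial k of a
                     block is Q_end * gamma**k (extinction-like)
10     instr. + PIT  model 8 + a fixed Gaussian offset xi[s] added to the go
                     weight of each instrumental stimulus during PIT
                     ("generalization noise"; all xi share one group prior)
====== ============= ==========================================================

Learning rates and the decay live in (0, 1) and are logistic-transformed for
inference; sensitivities, biases, transfer weights and offsets are
unconstrained and inferred in their native space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit, logit

from . import _kernel
from .task import (
    APPROACH,
    BLOCKS,
    GO,
    NOGO,
    STAGE_INSTRUMENTAL,
    STAGE_PIT,
    WITHDRAWAL,
    SubjectDataset,
    TrialRecord,
    pavlovian_value,
)

__all__ = [
    "ModelSpec",
    "ParameterVector",
    "QState",
    "ScopeError",
    "StageError",
    "get_model",
    "list_models",
    "transform_to_native",
    "transform_to_inference",
    "action_weights",
    "choice_probabilities",
    "update_q",
    "subject_log_likelihood",
    "subject_log_likelihood_and_grad",
    "per_trial_log_probabilities",
    "CompiledTrials",
    "compile_trials",
]

PAV_LEVELS = (100, 10, 0, -10, -100)
_LEVEL_TAG = {100: "p100", 10: "p10", 0: "z0", -10: "m10", -100: "m100"}
_BLK = {APPROACH: "app", WITHDRAWAL: "wth"}


class ScopeError(ValueError):
    """A PIT-stage quantity was requested from an instrumental-only model."""


class StageError(ValueError):
    """An operation was applied to a trial from the wrong stage."""


def pi_name(block: str, value: int) -> str:
    return f"pi_{_BLK[block]}_{_LEVEL_TAG[value]}"


def xi_name(block: str, rank: int) -> str:
    return f"xi_{_BLK[block]}_s{rank + 1}"


@dataclass(frozen=True)
class ModelSpec:
    """Which model is in force: its parameters, transforms and scope.

    ``hyper_groups`` lists, per group-level Gaussian, the coordinate indices
    it governs.  Every coordinate forms its own group except the twelve xi
    offsets of model 10, which share a single mean and variance.
    """

    model_id: int
    data_scope: str  # "instrumental_only" | "instrumental_and_pit"
    param_names: tuple
    transforms: tuple  # "logit" | "identity", per coordinate
    generalization: str  # "none" | "exact" | "extinction" | "noisy"
    hyper_groups: tuple

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def includes_pit(self) -> bool:
        return self.data_scope == "instrumental_and_pit"

    def index(self, name: str) -> int:
        return self.param_names.index(name)

    def has(self, name: str) -> bool:
        return name in self.param_names

    def hyper_group_names(self) -> list:
        """One label per group: the parameter name, or 'xi' for the pooled block."""
        labels = []
        for grp in self.hyper_groups:
            if len(grp) == 1:
                labels.append(self.param_names[grp[0]])
            else:
                labels.append("xi")
        return labels


def _build_spec(model_id: int) -> ModelSpec:
    if model_id == 1:
        names = ["eps", "rho"]
    elif model_id == 2:
        names = ["eps", "rho_rew", "rho_pun"]
    elif model_id == 3:
        names = ["eps_rew", "eps_pun", "rho"]
    elif model_id == 4:
        names = ["eps", "rho", "b_app", "b_wth"]
    elif model_id == 5:
        names = ["eps", "rho_rew", "rho_pun", "b_app", "b_wth"]
    elif model_id == 6:
        names = [
            "eps",
            "rho_rew_app", "rho_pun_app", "rho_rew_wth", "rho_pun_wth",
            "b_app", "b_wth",
        ]
    elif model_id == 7:
        names = ["eps_app", "eps_wth", "rho_rew", "rho_pun", "b_app", "b_wth"]
    elif model_id in (8, 9, 10):
        names = ["eps", "rho_rew", "rho_pun", "b_app", "b_wth"]
        names += [pi_name(b, v) for b in BLOCKS for v in PAV_LEVELS]
        if model_id == 9:
            names.append("gamma")
        if model_id == 10:
            names += [xi_name(b, i) for b in BLOCKS for i in range(6)]
    else:
        raise ValueError(f"unknown model id {model_id}")

    transforms = tuple(
        "logit" if n.startswith("eps") or n == "gamma" else "identity" for n in names
    )
    scope = "instrumental_and_pit" if model_id >= 8 else "instrumental_only"
    gen = {8: "exact", 9: "extinction", 10: "noisy"}.get(model_id, "none")

    xi_idx = tuple(i for i, n in enumerate(names) if n.startswith("xi_"))
    groups = [(i,) for i, n in enumerate(names) if not n.startswith("xi_")]
    if xi_idx:
        groups.append(xi_idx)
    return ModelSpec(
        model_id=model_id,
        data_scope=scope,
        param_names=tuple(names),
        transforms=transforms,
        generalization=gen,
        hyper_groups=tuple(groups),
    )


_REGISTRY = {k: _build_spec(k) for k in range(1, 11)}


def get_model(model_id: int) -> ModelSpec:
    """Look up a model by its id (1-10)."""
    try:
        return _REGISTRY[int(model_id)]
    except (KeyError, ValueError) as err:
        raise ValueError(f"unknown model id {model_id!r}") from err


def list_models() -> list:
    return [_REGISTRY[k] for k in sorted(_REGISTRY)]


# ---------------------------------------------------------------------------
# parameter transforms


def transform_to_native(vector: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Map unconstrained inference-space values to native space.

    Learning-rate and decay coordinates pass through the logistic function;
    all other coordinates are untouched.
    """
    vector = np.asarray(vector, dtype=float)
    if vector.shape[-1] != spec.n_params:
        raise ValueError(
            f"expected {spec.n_params} coordinates, got {vector.shape[-1]}"
        )
    out = vector.copy()
    mask = np.array([t == "logit" for t in spec.transforms])
    out[..., mask] = expit(vector[..., mask])
    return out


def transform_to_inference(vector: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Exact inverse of :func:`transform_to_native`."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape[-1] != spec.n_params:
        raise ValueError(
            f"expected {spec.n_params} coordinates, got {vector.shape[-1]}"
        )
    out = vector.copy()
    mask = np.array([t == "logit" for t in spec.transforms])
    out[..., mask] = logit(np.clip(vector[..., mask], 1e-15, 1 - 1e-15))
    return out


@dataclass
class ParameterVector:
    """One subject's parameters with paired native/inference-space views."""

    spec: ModelSpec
    inference: np.ndarray

    def __post_init__(self):
        self.inference = np.asarray(self.inference, dtype=float)
        if self.inference.shape != (self.spec.n_params,):
            raise ValueError(
                f"model {self.spec.model_id} needs {self.spec.n_params} "
                f"parameters, got shape {self.inference.shape}"
            )

    @classmethod
    def from_inference(cls, spec: ModelSpec, values) -> "ParameterVector":
        return cls(spec, np.asarray(values, dtype=float))

    @classmethod
    def from_native(cls, spec: ModelSpec, values) -> "ParameterVector":
        return cls(spec, transform_to_inference(np.asarray(values, float), spec))

    @classmethod
    def from_dict(cls, spec: ModelSpec, native: dict, default: float = 0.0):
        """Build from native-space values by name; missing names default.

        The default is native 0 for unconstrained coordinates and native 0.5
        (inference 0) for logistic ones, unless ``default`` overrides the
        unconstrained fill value.
        """
        vec = np.zeros(spec.n_params)
        for i, (name, tr) in enumerate(zip(spec.param_names, spec.transforms)):
            if name in native:
                v = native[name]
                vec[i] = logit(np.clip(v, 1e-15, 1 - 1e-15)) if tr == "logit" else v
            else:
                vec[i] = 0.0 if tr == "logit" else default
        return cls(spec, vec)

    @property
    def native(self) -> np.ndarray:
        return transform_to_native(self.inference, self.spec)

    def __getitem__(self, name: str) -> float:
        return float(self.native[self.spec.index(name)])

    def as_dict(self) -> dict:
        return dict(zip(self.spec.param_names, self.native))


# ---------------------------------------------------------------------------
# reference (pure-Python) model dynamics
#
# These operations define the model one trial at a time and are the code
# path the simulator walks; the numba kernel below must agree with them to
# machine precision (tested).


@dataclass
class QState:
    """Rescorla-Wagner expectations per (stimulus, action) plus the PIT clock.

    ``q`` maps ``(stimulus_id, action)`` to the current expectation; unseen
    pairs are implicitly zero.  ``pit_count`` counts PIT trials already taken
    in each block, so the extinction model's effective value on the k-th PIT
    trial (1-based) is ``Q_end * gamma**k``.
    """

    q: dict = field(default_factory=dict)
    pit_count: dict = field(default_factory=dict)

    def value(self, stimulus: str, action: str) -> float:
        return self.q.get((stimulus, action), 0.0)

    def copy(self) -> "QState":
        return QState(dict(self.q), dict(self.pit_count))

    def advance_pit(self, block: str) -> "QState":
        new = self.copy()
        new.pit_count[block] = new.pit_count.get(block, 0) + 1
        return new


def _bias(params: ParameterVector, block: str) -> float:
    name = "b_app" if block == APPROACH else "b_wth"
    return params[name] if params.spec.has(name) else 0.0


def action_weights(
    state: QState, trial: TrialRecord, params: ParameterVector, spec: ModelSpec
) -> dict:
    """Additive action weights W(go), W(nogo) for one choice trial.

    The go bias, the Pavlovian transfer weight and the model-10 offset all
    attach to go only; the extinction decay of model 9 scales the Q values
    entering both actions.
    """
    if trial.stage not in (STAGE_INSTRUMENTAL, STAGE_PIT):
        raise StageError(f"not a choice trial: stage {trial.stage}")
    if trial.stage == STAGE_PIT and not spec.includes_pit:
        raise ScopeError(
            f"model {spec.model_id} is fitted to instrumental trials only"
        )
    s = trial.instrumental_stimulus
    qg = state.value(s, GO)
    qn = state.value(s, NOGO)
    w_go = 0.0
    if trial.stage == STAGE_PIT:
        if spec.generalization == "extinction":
            k = state.pit_count.get(trial.block, 0) + 1  # this trial's 1-based index
            decay = params["gamma"] ** k
            qg *= decay
            qn *= decay
        elif spec.generalization == "noisy":
            w_go += params[_xi_for(spec, trial.block, s)]
        w_go += params[pi_name(trial.block, pavlovian_value(trial.pavlovian_stimulus))]
    w_go += qg + _bias(params, trial.block)
    return {GO: w_go, NOGO: qn}


def _xi_for(spec: ModelSpec, block: str, stimulus: str) -> str:
    # canonical ids "app_s3" map straight onto the xi coordinate of that rank
    rank = int(stimulus.rsplit("_s", 1)[1]) - 1
    return xi_name(block, rank)


def choice_probabilities(weights: dict) -> dict:
    """Two-action softmax of the weights; stable for large |W|."""
    wg, wn = float(weights[GO]), float(weights[NOGO])
    if not (np.isfinite(wg) and np.isfinite(wn)):
        raise FloatingPointError("non-finite action weight")
    p_go = expit(wg - wn)
    return {GO: p_go, NOGO: 1.0 - p_go}


def _select_eps_rho(trial: TrialRecord, params: ParameterVector, spec: ModelSpec):
    r = 1 if trial.outcome > 0 else -1
    blk = "app" if trial.block == APPROACH else "wth"
    if spec.has("eps"):
        eps = params["eps"]
    elif spec.has("eps_rew"):  # model 3: outcome-specific learning rates
        eps = params["eps_rew"] if r > 0 else params["eps_pun"]
    else:  # model 7: block-specific learning rates
        eps = params[f"eps_{blk}"]
    if spec.has("rho"):
        rho = params["rho"]
    elif spec.has("rho_rew"):
        rho = params["rho_rew"] if r > 0 else params["rho_pun"]
    else:  # model 6: block-specific sensitivities
        rho = params[f"rho_{'rew' if r > 0 else 'pun'}_{blk}"]
    return eps, rho, r


def update_q(
    state: QState, trial: TrialRecord, params: ParameterVector, spec: ModelSpec
) -> QState:
    """Rescorla-Wagner update of the chosen (stimulus, action) pair only."""
    if trial.outcome is None:
        raise StageError("update_q needs an outcome-bearing (instrumental) trial")
    eps, rho, r = _select_eps_rho(trial, params, spec)
    s, a = trial.instrumental_stimulus, trial.action
    new = state.copy()
    old = state.value(s, a)
    new.q[(s, a)] = old + eps * (rho * r - old)
    return new


# ---------------------------------------------------------------------------
# compiled per-subject likelihood


@dataclass
class CompiledTrials:
    """Per-subject trial arrays consumed by the numba likelihood kernel."""

    spec: ModelSpec
    n_trials: int
    n_stim: int
    stim: np.ndarray
    act: np.ndarray
    is_pit: np.ndarray
    r: np.ndarray
    ieps: np.ndarray
    irho: np.ndarray
    ib: np.ndarray
    ipi: np.ndarray
    ixi: np.ndarray
    igamma: int
    pitk: np.ndarray


def _pav_rank_map(ids: list) -> dict:
    """Map Pavlovian ids of one block to value levels, best to worst."""
    parsed = {}
    for pid in ids:
        try:
            parsed[pid] = pavlovian_value(pid)
        except (IndexError, ValueError):
            parsed = None
            break
    if parsed is not None and len(set(parsed.values())) == len(parsed):
        order = sorted(parsed, key=lambda p: -parsed[p])
    else:  # non-canonical ids: deterministic fallback by sorted identifier
        order = sorted(ids)
    if len(order) > len(PAV_LEVELS):
        raise ValueError(f"more than {len(PAV_LEVELS)} Pavlovian stimuli in a block")
    return {pid: PAV_LEVELS[i] for i, pid in enumerate(order)}


def compile_trials(dataset: SubjectDataset, spec: ModelSpec) -> CompiledTrials:
    """Flatten the in-scope choice trials of one subject into index arrays.

    Stimulus identifiers are mapped to dense indices by sorted order within
    each block, which for canonical ids coincides with their design rank.
    """
    trials = dataset.choice_trials(include_pit=spec.includes_pit)
    names = spec.param_names

    def idx(name: str) -> int:
        return names.index(name) if name in names else -1

    stim_ids = sorted({t.instrumental_stimulus for t in trials})
    stim_map = {s: i for i, s in enumerate(stim_ids)}
    # per-block stimulus rank for the xi offsets of model 10
    xi_map = {}
    if spec.generalization == "noisy":
        for blk in BLOCKS:
            blk_ids = sorted(
                {t.instrumental_stimulus for t in trials if t.block == blk}
            )
            for rank, sid in enumerate(blk_ids):
                xi_map[sid] = idx(xi_name(blk, rank))
    pav_maps = {
        blk: _pav_rank_map(
            sorted(
                {
                    t.pavlovian_stimulus
                    for t in trials
                    if t.block == blk and t.stage == STAGE_PIT
                }
            )
        )
        for blk in BLOCKS
    }

    T = len(trials)
    stim = np.zeros(T, np.int64)
    act = np.zeros(T, np.int64)
    is_pit = np.zeros(T, np.int64)
    r = np.zeros(T, np.int64)
    ieps = np.full(T, -1, np.int64)
    irho = np.full(T, -1, np.int64)
    ib = np.full(T, -1, np.int64)
    ipi = np.full(T, -1, np.int64)
    ixi = np.full(T, -1, np.int64)
    pitk = np.zeros(T, np.int64)
    pit_seen = {blk: 0 for blk in BLOCKS}

    for j, t in enumerate(trials):
        blk = "app" if t.block == APPROACH else "wth"
        stim[j] = stim_map[t.instrumental_stimulus]
        act[j] = 1 if t.action == GO else 0
        ib[j] = idx(f"b_{blk}")
        if t.stage == STAGE_PIT:
            is_pit[j] = 1
            pit_seen[t.block] += 1
            pitk[j] = pit_seen[t.block]
            ipi[j] = idx(
                pi_name(t.block, pav_maps[t.block][t.pavlovian_stimulus])
            )
            if spec.generalization == "noisy":
                ixi[j] = xi_map[t.instrumental_stimulus]
        else:
            r[j] = 1 if t.outcome > 0 else -1
            rj = r[j]
            if spec.has("eps"):
                ieps[j] = idx("eps")
            elif spec.has("eps_rew"):
                ieps[j] = idx("eps_rew" if rj > 0 else "eps_pun")
            else:
                ieps[j] = idx(f"eps_{blk}")
            if spec.has("rho"):
                irho[j] = idx("rho")
            elif spec.has("rho_rew"):
                irho[j] = idx("rho_rew" if rj > 0 else "rho_pun")
            else:
                irho[j] = idx(f"rho_{'rew' if rj > 0 else 'pun'}_{blk}")

    return CompiledTrials(
        spec=spec,
        n_trials=T,
        n_stim=max(len(stim_ids), 1),
        stim=stim,
        act=act,
        is_pit=is_pit,
        r=r,
        ieps=ieps,
        irho=irho,
        ib=ib,
        ipi=ipi,
        ixi=ixi,
        igamma=idx("gamma"),
        pitk=pitk,
    )


def _kernel_args(ct: CompiledTrials):
    return (
        ct.stim, ct.act, ct.is_pit, ct.r, ct.ieps, ct.irho, ct.ib, ct.ipi,
        ct.ixi, ct.igamma, ct.pitk, ct.n_stim,
    )


def _jacobian(inference: np.ndarray, native: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """d(native)/d(inference), diagonal; sigmoid slope on logit coordinates."""
    jac = np.ones_like(native)
    for i, tr in enumerate(spec.transforms):
        if tr == "logit":
            jac[i] = native[i] * (1.0 - native[i])
    return jac


def subject_log_likelihood(
    dataset: SubjectDataset,
    params: ParameterVector,
    spec: Optional[ModelSpec] = None,
    compiled: Optional[CompiledTrials] = None,
) -> float:
    """Summed log probability of the observed in-scope choices.

    Models 1-7 consume instrumental trials only; models 8-10 also consume
    PIT trials.  Pavlovian conditioning and query trials never contribute.
    """
    spec = spec or params.spec
    ct = compiled or compile_trials(dataset, spec)
    return float(_kernel.loglik(params.native, *_kernel_args(ct)))


def subject_log_likelihood_and_grad(
    inference: np.ndarray,
    spec: ModelSpec,
    compiled: CompiledTrials,
) -> tuple:
    """Log-likelihood and its exact gradient w.r.t. inference-space values.

    The gradient is propagated analytically through the Rescorla-Wagner
    recursion (and the PIT-stage decay/offset terms) in native space and
    chained through the logistic transforms.
    """
    native = transform_to_native(inference, spec)
    ll, g_native = _kernel.loglik_grad(native, *_kernel_args(compiled))
    return float(ll), g_native * _jacobian(inference, native, spec)


def per_trial_log_probabilities(
    dataset: SubjectDataset,
    params: ParameterVector,
    spec: Optional[ModelSpec] = None,
    compiled: Optional[CompiledTrials] = None,
) -> np.ndarray:
    """Log probability of each observed in-scope choice, in trial order."""
    spec = spec or params.spec
    ct = compiled or compile_trials(dataset, spec)
    return _kernel.loglik_trials(params.native, *_kernel_args(ct))


def log_likelihood_many(
    natives: np.ndarray, compiled: CompiledTrials
) -> np.ndarray:
    """Vectorised log-likelihood over rows of native-space parameter draws."""
    natives = np.ascontiguousarray(natives, dtype=float)
    return _kernel.loglik_many(natives, *_kernel_args(compiled))
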