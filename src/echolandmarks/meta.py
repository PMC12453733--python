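"""Model-agnostic meta-learning update rules over the backbone contract.

Four learners are implemented, all first-order (no backpropagation through
the inner-loop trajectory):

``fomaml``
    Inner: theta_k = theta_{k-1} - alpha * grad L_support(theta_{k-1}).
    Outer: theta_meta <- theta_meta - beta * grad L_query(theta_K).
``meta_sgd``
    One learnable learning rate per scalar parameter; the inner step is the
    elementwise product alpha ⊙ grad.  The outer loop updates both the
    initialisation and alpha.  With alpha frozen at a constant scalar the
    inner trajectory is identical to FOMAML's.
``meta_curvature``
    Inner gradients are preconditioned by a meta-learned Kronecker-factored
    matrix M_mc = (M_o ⊗ I ⊗ I)(I ⊗ M_i ⊗ I)(I ⊗ I ⊗ M_f) acting on the
    flattened C_out x C_in x d filter; applied as three mode-wise tensor
    contractions, never materialising the dense Kronecker product.  Factors
    start at identity, so training starts exactly as FOMAML.
``anil``
    "Almost no inner loop": the inner loop adapts only the head parameters
    (the body tensors are passed through untouched, bit-identical); the
    outer loop meta-updates both body and head at the adapted head.

The learnable-rate and curvature meta-gradients use the same first-order
approximation as FOMAML: inner-loop gradients are treated as constants when
differentiating the query loss, so
d L_query / d alpha = -g_query ⊙ sum_k g_inner_k, and the curvature-factor
gradients are the corresponding mode-wise contractions of
-alpha * g_query with each inner gradient.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .backbone import ModelParams, clone_params

LEARNERS = ("fomaml", "meta_sgd", "meta_curvature", "anil")


# ---------------------------------------------------------------------------
# configuration and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InnerConfig:
    """Inner-loop (task adaptation) settings.

    Defaults follow the meta-train protocol: rate 0.03, 10 steps; at
    meta-test the rate is 0.05 with 100 adaptation steps.
    """

    inner_lr: float = 0.03
    n_steps: int = 10
    max_grad_norm: float = 10.0  # global-norm clip; 0 disables

    def __post_init__(self):
        if self.inner_lr <= 0:
            raise ValueError("inner_lr must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.max_grad_norm < 0:
            raise ValueError("max_grad_norm must be >= 0")


TEST_TIME = InnerConfig(inner_lr=0.05, n_steps=100)


@dataclass
class MetaState:
    """Meta-learned initialisation plus learner-specific extras."""

    theta: ModelParams
    learner: str = "fomaml"
    outer_lr: float = 5e-3
    outer_optimizer: str = "adam"  # 'adam' | 'sgd'
    alpha: Optional[OrderedDict] = None        # meta_sgd: per-parameter rates
    curvature: Optional[OrderedDict] = None    # meta_curvature: factor tuples
    adam_m: dict = field(default_factory=dict)
    adam_v: dict = field(default_factory=dict)
    adam_t: int = 0

    def copy(self) -> "MetaState":
        return MetaState(
            theta=self.theta.copy(),
            learner=self.learner,
            outer_lr=self.outer_lr,
            outer_optimizer=self.outer_optimizer,
            alpha=None if self.alpha is None else OrderedDict(
                (k, v.copy()) for k, v in self.alpha.items()),
            curvature=None if self.curvature is None else OrderedDict(
                (k, tuple(m.copy() for m in ms)) for k, ms in self.curvature.items()),
            adam_m={k: v.copy() for k, v in self.adam_m.items()},
            adam_v={k: v.copy() for k, v in self.adam_v.items()},
            adam_t=self.adam_t,
        )


def _filter_shape(arr: np.ndarray) -> Optional[tuple[int, int, int]]:
    """(C_out, C_in, d) for conv weights, None for vector parameters."""
    if arr.ndim == 4:
        return arr.shape[0], arr.shape[1], arr.shape[2] * arr.shape[3]
    return None


def create_meta_state(
    theta: ModelParams,
    learner: str = "fomaml",
    outer_lr: float = 5e-3,
    outer_optimizer: str = "adam",
    inner_lr_init: float = 0.03,
) -> MetaState:
    """Allocate the meta-state for a learner; extras only where the learner
    needs them (alpha for meta_sgd, curvature factors for meta_curvature)."""
    if learner not in LEARNERS:
        raise ValueError(f"unknown learner {learner!r}; expected one of {LEARNERS}")
    if outer_optimizer not in ("adam", "sgd"):
        raise ValueError("outer_optimizer must be 'adam' or 'sgd'")
    alpha = None
    curvature = None
    if learner == "meta_sgd":
        alpha = OrderedDict(
            (k, np.full_like(v, inner_lr_init)) for k, v in theta.items())
    elif learner == "meta_curvature":
        curvature = OrderedDict()
        for k, v in theta.items():
            fs = _filter_shape(v)
            if fs is None:
                curvature[k] = (np.eye(v.size, dtype=v.dtype),)
            else:
                co, ci, d = fs
                curvature[k] = (
                    np.eye(co, dtype=v.dtype),
                    np.eye(ci, dtype=v.dtype),
                    np.eye(d, dtype=v.dtype),
                )
    return MetaState(
        theta=clone_params(theta), learner=learner, outer_lr=outer_lr,
        outer_optimizer=outer_optimizer, alpha=alpha, curvature=curvature)


# ---------------------------------------------------------------------------
# meta-curvature preconditioning
# ---------------------------------------------------------------------------

def mc_precondition(grad: np.ndarray, factors: Sequence[np.ndarray]) -> np.ndarray:
    """Apply the Kronecker-factored curvature matrix to a gradient tensor.

    For a C_out x C_in x kh x kw filter gradient with factors
    (M_o, M_i, M_f) this computes M_mc . vec(grad) via three mode-wise
    contractions; vector parameters use a single square factor.
    """
    if len(factors) == 1:
        (m,) = factors
        if m.shape != (grad.size, grad.size):
            raise ValueError(
                f"factor shape {m.shape} mismatches vector size {grad.size}")
        return (m @ grad.ravel()).reshape(grad.shape)
    mo, mi, mf = factors
    fs = _filter_shape(grad)
    if fs is None:
        raise ValueError("three-factor preconditioning needs a 4-d filter tensor")
    co, ci, d = fs
    if mo.shape != (co, co) or mi.shape != (ci, ci) or mf.shape != (d, d):
        raise ValueError(
            f"factor shapes {[m.shape for m in factors]} mismatch filter "
            f"({co},{ci},{d})")
    g = grad.reshape(co, ci, d)
    g = np.einsum("ab,oib->oia", mf, g)
    g = np.einsum("ji,oif->ojf", mi, g)
    g = np.einsum("po,oif->pif", mo, g)
    return g.reshape(grad.shape)


def _mc_factor_grads(upstream, grad, factors):
    """Gradients of <upstream, M_mc.grad> w.r.t. each curvature factor."""
    if len(factors) == 1:
        u = upstream.ravel()
        g = grad.ravel()
        return (np.outer(u, g),)
    mo, mi, mf = factors
    co, ci, d = _filter_shape(grad)
    u = upstream.reshape(co, ci, d)
    g = grad.reshape(co, ci, d)
    g1 = np.einsum("ab,oib->oia", mf, g)       # after M_f
    g2 = np.einsum("ji,oif->ojf", mi, g1)      # after M_i
    d_mo = np.einsum("pif,oif->po", u, g2)
    v = np.einsum("po,pif->oif", mo, u)
    d_mi = np.einsum("ojf,oif->ji", v, g1)
    w = np.einsum("ji,ojf->oif", mi, v)
    d_mf = np.einsum("oia,oib->ab", w, g)
    return d_mo, d_mi, d_mf


# ---------------------------------------------------------------------------
# inner loop
# ---------------------------------------------------------------------------

@dataclass
class AdaptResult:
    """Adapted parameters plus the inner trajectory's gradients and losses."""

    params: ModelParams
    inner_grads: list
    losses: list


def _check_finite(grads: OrderedDict) -> None:
    for k, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient for parameter {k!r}")


def _clip_global_norm(grads: OrderedDict, max_norm: float, keys) -> OrderedDict:
    """Rescale gradients so their joint norm does not exceed max_norm.

    A no-op for healthy gradients; it guards the fixed-rate inner loop
    against runaway steps late in meta-training.
    """
    if not max_norm:
        return grads
    total = np.sqrt(sum(float(np.sum(grads[k].astype(np.float64) ** 2))
                        for k in keys))
    if total <= max_norm:
        return grads
    scale = max_norm / total
    out = OrderedDict(grads)
    for k in keys:
        out[k] = grads[k] * grads[k].dtype.type(scale)
    return out


def inner_adapt(
    model,
    state: MetaState,
    support_batch,
    cfg: InnerConfig,
    record_grads: bool = False,
) -> AdaptResult:
    """Run K inner-loop adaptation steps from the meta-initialisation.

    The meta-state is never mutated.  For ANIL only the head parameters are
    updated; body tensors of the returned params are the *same arrays* as
    the meta-initialisation's (bit-identical by construction).
    """
    theta = state.theta
    learner = state.learner
    if learner == "anil":
        # share body arrays, copy head
        params = ModelParams(
            body=OrderedDict(theta.body),
            head=OrderedDict((k, v.copy()) for k, v in theta.head.items()))
    else:
        params = clone_params(theta)
    inner_grads: list = []
    losses: list = []
    for _ in range(cfg.n_steps):
        loss, grads = model.loss_and_grad(params, support_batch)
        _check_finite(grads)
        losses.append(loss)
        step_keys = (list(theta.head) if learner == "anil"
                     else list(grads))
        grads = _clip_global_norm(grads, cfg.max_grad_norm, step_keys)
        if record_grads:
            inner_grads.append(grads)
        new_head = OrderedDict()
        new_body = OrderedDict()
        for k, v in params.items():
            g = grads[k]
            if learner == "anil":
                if params.is_head(k):
                    new_head[k] = v - cfg.inner_lr * g
                # body untouched on purpose
                continue
            if learner == "meta_sgd":
                step = state.alpha[k] * g
            elif learner == "meta_curvature":
                step = cfg.inner_lr * mc_precondition(g, state.curvature[k])
            else:  # fomaml
                step = cfg.inner_lr * g
            if params.is_head(k):
                new_head[k] = v - step
            else:
                new_body[k] = v - step
        if learner == "anil":
            params = ModelParams(body=params.body, head=new_head)
        else:
            params = ModelParams(body=new_body, head=new_head)
    return AdaptResult(params=params, inner_grads=inner_grads, losses=losses)


# ---------------------------------------------------------------------------
# outer loop
# ---------------------------------------------------------------------------

def compute_meta_grads(
    model,
    state: MetaState,
    adapt: AdaptResult,
    query_batch,
    cfg: InnerConfig,
) -> tuple[float, dict]:
    """First-order meta-gradients for one task.

    Returns (query_loss, grads) where grads maps flat keys:
    ``theta::<name>`` always; ``alpha::<name>`` for meta_sgd;
    ``mc::<name>::<j>`` for meta_curvature factor j.
    """
    q_loss, g_q = model.loss_and_grad(adapt.params, query_batch)
    _check_finite(g_q)
    meta: dict = {f"theta::{k}": g_q[k] for k in g_q}
    if state.learner == "meta_sgd":
        if not adapt.inner_grads and cfg.n_steps > 0:
            raise ValueError("meta_sgd outer update needs record_grads=True inner loop")
        for k in g_q:
            acc = sum((gr[k] for gr in adapt.inner_grads),
                      start=np.zeros_like(g_q[k]))
            meta[f"alpha::{k}"] = -g_q[k] * acc
    elif state.learner == "meta_curvature":
        if not adapt.inner_grads and cfg.n_steps > 0:
            raise ValueError("meta_curvature outer update needs record_grads=True")
        for k in g_q:
            factors = state.curvature[k]
            upstream = -cfg.inner_lr * g_q[k]
            accs = [np.zeros_like(m) for m in factors]
            for gr in adapt.inner_grads:
                for acc, d in zip(accs, _mc_factor_grads(upstream, gr[k], factors)):
                    acc += d
            for j, acc in enumerate(accs):
                meta[f"mc::{k}::{j}"] = acc
    return q_loss, meta


def _slot(state: MetaState, key: str) -> np.ndarray:
    kind, rest = key.split("::", 1)
    if kind == "theta":
        return state.theta[rest]
    if kind == "alpha":
        return state.alpha[rest]
    name, j = rest.rsplit("::", 1)
    return state.curvature[name][int(j)]


def _assign(state: MetaState, key: str, value: np.ndarray) -> None:
    kind, rest = key.split("::", 1)
    if kind == "theta":
        if rest in state.theta.body:
            state.theta.body[rest] = value
        else:
            state.theta.head[rest] = value
    elif kind == "alpha":
        state.alpha[rest] = value
    else:
        name, j = rest.rsplit("::", 1)
        ms = list(state.curvature[name])
        ms[int(j)] = value
        state.curvature[name] = tuple(ms)


def apply_outer_step(state: MetaState, meta_grads: dict) -> MetaState:
    """One outer (meta) update; returns a new MetaState, input untouched.

    'sgd' applies the plain rule x <- x - beta*g as written; 'adam' applies
    an Adam step with learning rate beta to the same meta-gradients.
    """
    new = state.copy()
    beta = state.outer_lr
    if beta == 0.0:
        return new
    if state.outer_optimizer == "sgd":
        for key, g in meta_grads.items():
            _assign(new, key, _slot(new, key) - beta * g)
        return new
    b1, b2, eps = 0.9, 0.999, 1e-8
    new.adam_t = state.adam_t + 1
    t = new.adam_t
    for key, g in meta_grads.items():
        m = new.adam_m.get(key)
        v = new.adam_v.get(key)
        if m is None:
            m = np.zeros_like(g)
            v = np.zeros_like(g)
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * (g * g)
        new.adam_m[key] = m
        new.adam_v[key] = v
        mhat = m / (1 - b1**t)
        vhat = v / (1 - b2**t)
        step = beta * mhat / (np.sqrt(vhat) + eps)
        _assign(new, key, (_slot(new, key) - step).astype(g.dtype, copy=False))
    return new


def outer_update(
    model,
    state: MetaState,
    adapt: AdaptResult,
    query_batch,
    cfg: InnerConfig,
) -> tuple[MetaState, float]:
    """Single-task outer update (meta_iteration with a singleton batch)."""
    q_loss, meta = compute_meta_grads(model, state, adapt, query_batch, cfg)
    return apply_outer_step(state, meta), q_loss


def save_meta_state(state: MetaState, path) -> None:
    """Serialise a MetaState (initialisation + learner extras) to .npz."""
    arrays = {f"theta.body::{k}": v for k, v in state.theta.body.items()}
    arrays.update({f"theta.head::{k}": v for k, v in state.theta.head.items()})
    if state.alpha is not None:
        arrays.update({f"alpha::{k}": v for k, v in state.alpha.items()})
    if state.curvature is not None:
        for k, ms in state.curvature.items():
            for j, m in enumerate(ms):
                arrays[f"mc::{k}::{j}"] = m
    arrays["__meta__"] = np.array(
        [state.learner, str(state.outer_lr), state.outer_optimizer])
    np.savez(path, **arrays)


def load_meta_state(path) -> MetaState:
    data = np.load(path, allow_pickle=False)
    learner, outer_lr, outer_opt = (str(x) for x in data["__meta__"])
    body, head = OrderedDict(), OrderedDict()
    alpha: OrderedDict = OrderedDict()
    curvature: dict = {}
    for key in data.files:
        if key == "__meta__":
            continue
        kind, rest = key.split("::", 1)
        if kind == "theta.body":
            body[rest] = data[key]
        elif kind == "theta.head":
            head[rest] = data[key]
        elif kind == "alpha":
            alpha[rest] = data[key]
        else:
            name, j = rest.rsplit("::", 1)
            curvature.setdefault(name, {})[int(j)] = data[key]
    curv = None
    if curvature:
        curv = OrderedDict(
            (k, tuple(v[j] for j in sorted(v))) for k, v in curvature.items())
    return MetaState(
        theta=ModelParams(body=body, head=head), learner=learner,
        outer_lr=float(outer_lr), outer_optimizer=outer_opt,
        alpha=alpha or None, curvature=curv)


def meta_iteration(
    model,
    state: MetaState,
    episode_batch: Sequence[tuple],
    cfg: InnerConfig,
) -> tuple[MetaState, list]:
    """One meta-iteration over a batch of tasks.

    episode_batch: sequence of (support_batch, query_batch) pairs.  Query
    losses are aggregated by summation across tasks, so the meta-gradient
    of two identical episodes is exactly twice the single-episode one.
    """
    if len(episode_batch) == 0:
        raise ValueError("empty episode batch")
    need_grads = state.learner in ("meta_sgd", "meta_curvature")
    total: dict = {}
    q_losses = []
    for support_batch, query_batch in episode_batch:
        adapt = inner_adapt(model, state, support_batch, cfg,
                            record_grads=need_grads)
        q_loss, meta = compute_meta_grads(model, state, adapt, query_batch, cfg)
        q_losses.append(q_loss)
        for key, g in meta.items():
            if key in total:
                total[key] = total[key] + g
            else:
                total[key] = g
    return apply_outer_step(state, total), q_losses
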