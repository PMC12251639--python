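"""Numerics for sparse temporal attention.

This module collects the pure-array primitives the attention pathway is
built from: a numerically stable softmax, exact alpha-entmax computed by
bisection on the threshold tau, its Jacobian-vector product (needed to
backpropagate through the sparse transform), Shannon entropy of simplex
vectors, sigma-gamma score scaling (a running-standard-deviation gain
control), Top-K support selection, and linear annealing schedules.

alpha-entmax generalises softmax: for ``alpha=1`` it coincides with
softmax, for ``alpha=2`` with sparsemax, and for intermediate values it
interpolates, assigning *exactly zero* probability to low-scoring items.
The solution of the entmax problem

    max_p  p.z + H_alpha(p)   s.t.  p on the simplex

has the closed form ``p_i = [(alpha-1) z_i - tau]_+ ^ (1/(alpha-1))``
where the threshold ``tau`` is the unique root of ``sum_i p_i = 1``.
``tau`` is bracketed by ``[max((alpha-1)z) - 1, max((alpha-1)z)]`` and
found by bisection, which is derivative-free and deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "softmax",
    "entmax_bisect",
    "entmax_jvp",
    "shannon_entropy",
    "ScaleState",
    "sigma_gamma_scale",
    "topk_support",
    "LinearSchedule",
    "schedule_value",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Stable softmax along ``axis``: ``p_i ∝ exp(z_i - max z)``."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite inputs")
    e = np.exp(z - np.max(z, axis=axis, keepdims=True))
    return e / np.sum(e, axis=axis, keepdims=True)


def entmax_bisect(
    z: np.ndarray,
    alpha: float,
    n_iter: int = 50,
    axis: int = -1,
    allow_softmax: bool = False,
) -> np.ndarray:
    """Exact alpha-entmax via bisection on the simplex threshold tau.

    Parameters
    ----------
    z
        Scores (any shape; the transform acts along ``axis``).
    alpha
        Sparsity parameter, must be > 1 (``alpha=2`` is sparsemax). With
        ``allow_softmax=True``, ``alpha <= 1`` routes to :func:`softmax`.
    n_iter
        Bisection iterations; 50 shrinks the bracket by 2^-50, well below
        the 1e-9 normalisation tolerance.
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("entmax of an empty vector is undefined")
    if not np.all(np.isfinite(z)):
        raise ValueError("entmax requires finite inputs")
    if alpha <= 1.0:
        if allow_softmax:
            return softmax(z, axis=axis)
        raise ValueError(f"entmax requires alpha > 1, got {alpha}")

    zt = (alpha - 1.0) * np.moveaxis(z, axis, -1)
    zmax = np.max(zt, axis=-1, keepdims=True)
    lo = zmax - 1.0
    hi = zmax.copy()
    inv = 1.0 / (alpha - 1.0)
    for _ in range(n_iter):
        tau = 0.5 * (lo + hi)
        p = np.maximum(zt - tau, 0.0) ** inv
        mass = np.sum(p, axis=-1, keepdims=True)
        # sum is decreasing in tau: too much mass -> raise tau
        hi = np.where(mass >= 1.0, hi, tau)
        lo = np.where(mass >= 1.0, tau, lo)
    tau = 0.5 * (lo + hi)
    p = np.maximum(zt - tau, 0.0) ** inv
    p /= np.sum(p, axis=-1, keepdims=True)
    return np.moveaxis(p, -1, axis)


def entmax_jvp(
    z: np.ndarray, alpha: float, p: np.ndarray, v: np.ndarray
) -> np.ndarray:
    """Jacobian-vector product of entmax at ``p = entmax(z, alpha)``.

    On the support S = {i : p_i > 0} the Jacobian is
    ``J = diag(s) - s s^T / sum(s)`` with ``s_i = p_i^(2-alpha)``; rows
    and columns off the support are zero. J is symmetric, so the same
    expression serves as the vector-Jacobian product in backpropagation.
    """
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    if p.shape != v.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs v {v.shape}")
    s = np.where(p > 0.0, p ** (2.0 - alpha), 0.0)
    sv = np.sum(s * v, axis=-1, keepdims=True)
    ssum = np.sum(s, axis=-1, keepdims=True)
    return s * v - s * (sv / ssum)


def shannon_entropy(p: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Shannon entropy in nats, with the convention 0·ln 0 = 0."""
    p = np.asarray(p, dtype=float)
    plogp = np.where(p > 0.0, p * np.log(np.where(p > 0.0, p, 1.0)), 0.0)
    h = -np.sum(plogp, axis=axis)
    return float(h) if np.ndim(h) == 0 else h


@dataclass
class ScaleState:
    """State of the sigma-gamma gain control.

    ``running_sigma`` tracks an exponential moving average of per-call
    score standard deviations; ``gamma`` is a learnable gain (held as a
    plain float here; the network keeps its own trainable copy).
    """

    running_sigma: float = 1.0
    momentum: float = 0.99
    gamma: float = 1.0
    epsilon: float = 1e-5

    def __post_init__(self) -> None:
        if not 0.0 < self.momentum < 1.0:
            raise ValueError("momentum must lie in (0, 1)")
        if self.running_sigma <= 0.0:
            raise ValueError("running_sigma must be positive")
        if self.epsilon <= 0.0:
            raise ValueError("epsilon must be positive")


def sigma_gamma_scale(
    raw_scores: np.ndarray, state: ScaleState, training: bool
) -> tuple[np.ndarray, ScaleState]:
    """Scale raw attention scores by ``gamma / (running_sigma + eps)``.

    In training mode the scores are scaled with the current running sigma
    and the state is then updated from the batch standard deviation; a
    zero-variance batch leaves the state untouched (with a warning). In
    eval mode the state is frozen.
    """
    raw = np.asarray(raw_scores, dtype=float)
    if training and raw.size < 2:
        raise ValueError("training-mode scaling needs >= 2 scores")
    scaled = state.gamma * raw / (state.running_sigma + state.epsilon)
    if training:
        sd = float(np.std(raw))
        if sd <= 0.0:
            warnings.warn("zero-variance score batch: running sigma unchanged")
            new_sigma = state.running_sigma
        else:
            new_sigma = state.momentum * state.running_sigma + (1.0 - state.momentum) * sd
        state = ScaleState(
            running_sigma=new_sigma,
            momentum=state.momentum,
            gamma=state.gamma,
            epsilon=state.epsilon,
        )
    return scaled, state


def topk_support(weights: np.ndarray, ratio: float) -> np.ndarray:
    """Indices of the K largest attention weights, K = max(1, ceil(ratio·T)).

    Ties are broken in favour of the smaller index; the result is sorted
    ascending. ``ratio`` must lie in (0, 1].
    """
    if not 0.0 < ratio <= 1.0:
        raise ValueError(f"ratio must lie in (0, 1], got {ratio}")
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights must be a nonempty 1-d simplex vector")
    t = w.size
    k = max(1, int(np.ceil(ratio * t)))
    # stable sort on -w keeps the smaller index first among ties
    order = np.argsort(-w, kind="stable")
    return np.sort(order[:k])


@dataclass(frozen=True)
class LinearSchedule:
    """Linear interpolation between two epoch-anchored values, clamped outside."""

    start_epoch: int
    end_epoch: int
    start_value: float
    end_value: float

    def __post_init__(self) -> None:
        if self.end_epoch <= self.start_epoch:
            raise ValueError("end_epoch must exceed start_epoch")


def schedule_value(schedule: LinearSchedule, epoch: float) -> float:
    """Value of a linear schedule at ``epoch``, clamped to the endpoints."""
    if epoch <= schedule.start_epoch:
        return schedule.start_value
    if epoch >= schedule.end_epoch:
        return schedule.end_value
    frac = (epoch - schedule.start_epoch) / (schedule.end_epoch - schedule.start_epoch)
    return schedule.start_value + frac * (schedule.end_value - schedule.start_value)
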