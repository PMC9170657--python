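"""Neuron-space formulation of the recursive learner.

Instead of kernel loads, learning is expressed directly on the readout
weights w and a recurrent novelty operator N (an N x N symmetric projection,
initialized to the identity):

    delta_w = (y_P - w' x_P) * N x_P / (x_P' N x_P)      (error x novelty)
    N      <- N - (N x_P)(N x_P)' / (x_P' N x_P)         (anti-Hebbian)

Both updates use the *same* pre-update N; the weight step is applied first.
N projects onto the orthogonal complement of all learned patterns, so
N x_P = 0 flags a fully familiar input and the update is skipped.  For a
naive learner (N = identity, w = 0) the rule is plain Hebbian.  With the
empirical kernel kappa(n, m) = x_n . x_m, this learner and the kernel-space
recursion produce identical input–output maps; importance scaling maps to an
attenuation of the inputs, x_t -> a_t x_t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("neuroksvr")

__all__ = [
    "weight_update",
    "novelty_update",
    "NoveltyLearner",
    "NetworkResponse",
    "novelty_network_dynamics",
    "anti_hebbian_reconstruction",
    "loads_to_weights",
]


def _novelty_denominator(nop, x):
    nx = nop @ x
    return nx, float(x @ nx)


def weight_update(w: np.ndarray, nop: np.ndarray, x: np.ndarray, y,
                  tol: float = 1e-8):
    """One error-times-novelty weight step.  Returns (w_new, accepted).

    After an accepted step the new w satisfies w' x = y exactly while
    leaving the readout of all previously learned patterns untouched.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    nx, denom = _novelty_denominator(nop, x)
    if denom <= tol * float(x @ x):
        logger.warning("weight update skipped: pattern novelty %.3g below "
                       "tolerance", denom)
        return w, False
    error = y - w.T @ x if w.ndim == 2 else np.atleast_1d(y - w @ x)
    if w.ndim == 1:
        return w + nx * (error[0] / denom), True
    return w + np.outer(nx, error) / denom, True


def novelty_update(nop: np.ndarray, x: np.ndarray, tol: float = 1e-8):
    """Anti-Hebbian projection step.  Returns (nop_new, accepted).

    The updated operator annihilates x and every previously learned pattern
    and remains a symmetric projection; its trace drops by exactly 1.
    """
    x = np.asarray(x, dtype=float)
    nx, denom = _novelty_denominator(nop, x)
    if denom <= tol * float(x @ x):
        logger.warning("novelty update skipped: pattern novelty %.3g below "
                       "tolerance", denom)
        return nop, False
    return nop - np.outer(nx, nx) / denom, True


class NoveltyLearner:
    """Stateful neuron-space learner pairing readout weights with the
    novelty operator.  ``learn`` applies the weight step first, then the
    novelty step, both with the same pre-update operator (the only order
    that preserves interference-free recovery).
    """

    def __init__(self, n_neurons: int, n_channels: int = 1,
                 novelty_tolerance: float = 1e-8):
        self.w = np.zeros((n_neurons, n_channels))
        self.nop = np.eye(n_neurons)
        self.novelty_tolerance = novelty_tolerance

    def learn(self, x, y, importance: float = 1.0) -> bool:
        """Absorb one (pattern, target) pair; importance attenuates the input."""
        if not 0.0 <= importance <= 1.0:
            raise ValueError("importance must lie in [0, 1]")
        xs = importance * np.asarray(x, dtype=float)
        w_new, ok = weight_update(self.w, self.nop, xs, y,
                                  self.novelty_tolerance)
        if not ok:
            return False
        self.w = w_new
        self.nop, _ = novelty_update(self.nop, xs, self.novelty_tolerance)
        return True

    def predict(self, x) -> np.ndarray:
        """Readout w' x of an (unattenuated) probe pattern."""
        return np.asarray(x, dtype=float) @ self.w


@dataclass(frozen=True)
class NetworkResponse:
    """Trajectory of the recurrent novelty network and its outcome flag."""

    states: np.ndarray  # (n_steps, N); states[s-1] is r(s)
    zero_novelty: bool  # input fully explained by memory (N x = 0)


def novelty_network_dynamics(nop: np.ndarray, x: np.ndarray,
                             n_steps: int = 3) -> NetworkResponse:
    """Discrete-time recurrent dynamics r(s+1) = phi[delta_{s,0} x + N r(s)]
    with r(0) = 0 and phi(z) = z / ||z||.

    r(1) = x/||x||; from s >= 2 the activity settles at the normalized novel
    component N x / ||N x||, a fixed point of the projection.  If N x = 0 the
    response reports a zero-novelty flag (remaining states zero) instead of
    dividing by zero.
    """
    x = np.asarray(x, dtype=float)
    norm = np.linalg.norm(x)
    if norm == 0.0:
        raise ValueError("input pattern must be nonzero")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    states = np.zeros((n_steps, x.size))
    states[0] = x / norm
    zero_novelty = False
    for s in range(1, n_steps):
        z = nop @ states[s - 1]
        zn = np.linalg.norm(z)
        if zn <= 1e-12:
            zero_novelty = True
            break
        states[s] = z / zn
    return NetworkResponse(states, zero_novelty)


def anti_hebbian_reconstruction(patterns, n_neurons: int | None = None,
                                tol: float = 1e-8) -> np.ndarray:
    """Build the novelty operator as 1 - sum_t r_t r_t' with
    r_t = N_t x_t / sqrt(x_t' N_t x_t) accumulated over the patterns in
    order (N_t the operator before pattern t).  Algebraically identical to
    iterating the rank-one novelty update."""
    patterns = [np.asarray(p, dtype=float) for p in patterns]
    if n_neurons is None:
        if not patterns:
            raise ValueError("need n_neurons for an empty pattern set")
        n_neurons = patterns[0].size
    components: list[np.ndarray] = []
    for x in patterns:
        nop = np.eye(n_neurons)
        for r in components:
            nop -= np.outer(r, r)
        nx = nop @ x
        denom = float(x @ nx)
        if denom <= tol * float(x @ x):
            continue
        components.append(nx / np.sqrt(denom))
    nop = np.eye(n_neurons)
    for r in components:
        nop -= np.outer(r, r)
    return nop


def loads_to_weights(X, model) -> np.ndarray:
    """Fold a kernel-space memory back into readout weights w = X (a * u).

    ``X`` is the pattern matrix (columns indexed by the stored sample times,
    which must be integers addressing columns); ``model`` is a fitted
    :class:`~neuroksvr.ksvr.KSVR`.  For the empirical kernel of X, x_t' w
    equals the kernel-space prediction at t.
    """
    X = np.asarray(getattr(X, "X", X), dtype=float)
    idx = np.rint(model.store.times).astype(int)
    if idx.size and (idx.min() < 0 or idx.max() >= X.shape[1]):
        raise IndexError("stored sample times do not index pattern columns")
    if idx.size == 0:
        return np.zeros((X.shape[0], max(model.n_channels, 1)))
    return X[:, idx] @ (model.store.importances[:, None] * model.store.loads)
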