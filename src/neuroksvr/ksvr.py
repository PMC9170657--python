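"""Recursive kernel support vector regression (KSVR) in load space.

The learner stores, for each memorized sample, its time t_n, target(s) y_n,
importance a_n in [0, 1] and load u_n.  Prediction is the representer sum

    f(t) = sum_n u_n a_n kappa(t, t_n)        (per output channel)

and learning keeps the loads at the maximum of the dual objective
W(u) = -1/2 u' K' u + y' u, where K'_{nm} = kappa(t_n, t_m) a_n a_m is the
importance-scaled kernel matrix.  A new sample is absorbed in one shot:

    C_P = kappa(t_P, t_P) a_P^2 - k' K'^{-1} k      (novelty)
    u_P = (y_P - k' u) / C_P,   u <- u - u_P K'^{-1} k

with k the scaled kernel column of the new sample against the stored ones.
The inverse of K' is maintained incrementally by the Sherman–Morrison style
block update, so each insertion costs O(P^2).

Targets are *not* attenuated by the importance (only the kernel is scaled),
so below capacity retrieval at a stored time equals y_n / a_n: low-importance
samples incur retrieval error that grows as a_n decreases.  Samples whose
novelty C_P falls below a relative tolerance (duplicates, a_P = 0, linearly
dependent patterns) are rejected and leave the memory untouched.  When the
number of stored samples exceeds the cutoff dimension, the lowest-importance
sample is pruned and the inverse downdated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kernels import Kernel

logger = logging.getLogger("neuroksvr")

__all__ = [
    "FitConfig",
    "SampleStore",
    "InverseState",
    "KSVR",
    "scaled_kernel_entry",
    "direct_solve",
    "fit_batch",
]


@dataclass
class FitConfig:
    """Configuration of the recursive learner.

    kernel
        The kernel function kappa(t, t').
    cutoff_dimension
        Maximum number of retained samples d_c (default 300).
    novelty_tolerance
        Relative threshold on the novelty C_P; a sample with
        C_P <= novelty_tolerance * kappa(t,t) a^2 is rejected.
    seed
        Seed routed to any randomness in surrounding protocols; the core
        recursion itself is deterministic.
    """

    kernel: Kernel
    cutoff_dimension: int = 300
    novelty_tolerance: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.cutoff_dimension < 1:
            raise ValueError("cutoff_dimension must be >= 1")
        if self.novelty_tolerance <= 0:
            raise ValueError("novelty_tolerance must be positive")


@dataclass
class SampleStore:
    """The learned memory: times, per-channel targets, importances, loads."""

    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    targets: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    importances: np.ndarray = field(default_factory=lambda: np.empty(0))
    loads: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __len__(self) -> int:
        return self.times.size


@dataclass
class InverseState:
    """Maintained inverse of the importance-scaled kernel matrix."""

    inv: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    last_novelty: float = np.nan


def scaled_kernel_entry(store: SampleStore, kernel: Kernel, n: int, m: int) -> float:
    """Importance-scaled kernel entry kappa(t_n, t_m) a_n a_m."""
    return float(kernel.evaluate(store.times[n], store.times[m])
                 * store.importances[n] * store.importances[m])


def direct_solve(kernel_matrix: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Dense oracle: loads = K'^{-1} y (raises on singular K')."""
    return np.linalg.solve(np.asarray(kernel_matrix, float),
                           np.asarray(targets, float))


class KSVR:
    """Recursive KSVR learner with incremental inverse maintenance."""

    def __init__(self, config: FitConfig):
        self.config = config
        self.store = SampleStore()
        self.state = InverseState()
        self._n_channels: int | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.store)

    @property
    def n_channels(self) -> int:
        return 0 if self._n_channels is None else self._n_channels

    @property
    def kernel(self) -> Kernel:
        return self.config.kernel

    def scaled_kernel_matrix(self) -> np.ndarray:
        """Current K' = kappa(t_n, t_m) a_n a_m."""
        a = self.store.importances
        return self.kernel.matrix(self.store.times) * np.outer(a, a)

    def inverse_residual(self) -> float:
        """max-norm of K' inv - I, relative to the max-norm of K'."""
        if self.n_samples == 0:
            return 0.0
        kp = self.scaled_kernel_matrix()
        resid = kp @ self.state.inv - np.eye(self.n_samples)
        return float(np.abs(resid).max() / max(np.abs(kp).max(), 1e-300))

    # -- learning ----------------------------------------------------------

    def add_sample(self, t: float, y, importance: float = 1.0) -> bool:
        """Insert one observation; returns True if it was accepted.

        Rejects (with a logged warning, store untouched) samples whose
        novelty falls below the relative tolerance — duplicates, importance
        zero, or patterns linearly dependent on the stored ones.
        """
        t = float(t)
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if not np.isfinite(t) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite sample time or target")
        a = float(importance)
        if not 0.0 <= a <= 1.0:
            raise ValueError("importance must lie in [0, 1]")
        if self._n_channels is None:
            self._n_channels = y.size
            self.store.targets = np.empty((0, y.size))
            self.store.loads = np.empty((0, y.size))
        elif y.size != self._n_channels:
            raise ValueError(
                f"expected {self._n_channels} target channels, got {y.size}")

        kss = float(self.kernel.self_value(t)) * a * a
        p = self.n_samples
        if p == 0:
            k = np.empty(0)
            q = np.empty(0)
            novelty = kss
        else:
            k = (np.asarray(self.kernel.evaluate(t, self.store.times), float)
                 * a * self.store.importances)
            q = self.state.inv @ k
            novelty = kss - float(k @ q)
        self.state.last_novelty = novelty
        if novelty <= self.config.novelty_tolerance * kss or kss == 0.0:
            logger.warning(
                "rejected sample at t=%g: novelty %.3g below tolerance "
                "(duplicate, zero importance, or dependent pattern)", t, novelty)
            return False

        u_new = (y - k @ self.store.loads) / novelty  # per channel
        loads = np.vstack([self.store.loads - np.outer(q, u_new), u_new])
        inv = np.empty((p + 1, p + 1))
        inv[:p, :p] = self.state.inv + np.outer(q, q) / novelty
        inv[:p, p] = -q / novelty
        inv[p, :p] = -q / novelty
        inv[p, p] = 1.0 / novelty

        self.store.times = np.append(self.store.times, t)
        self.store.targets = np.vstack([self.store.targets, y])
        self.store.importances = np.append(self.store.importances, a)
        self.store.loads = loads
        self.state.inv = inv

        if self.n_samples > self.config.cutoff_dimension:
            self.prune_lowest_importance()
        return True

    def fit(self, times, targets, importances=None) -> "KSVR":
        """Sequential one-shot insertion of a batch of observations."""
        times = np.asarray(times, dtype=float)
        targets = np.asarray(targets, dtype=float)
        if targets.ndim == 1:
            targets = targets[:, None]
        if importances is None:
            importances = np.ones(times.size)
        importances = np.asarray(importances, dtype=float)
        if not (times.size == targets.shape[0] == importances.size):
            raise ValueError("times, targets and importances must have equal length")
        for t, y, a in zip(times, targets, importances):
            self.add_sample(t, y, a)
        return self

    # -- prediction --------------------------------------------------------

    def predict(self, t):
        """Representer prediction sum_n u_n a_n kappa(t, t_n) per channel.

        Scalar t gives shape (channels,) (or a float for one channel);
        array t gives shape (len(t), channels) squeezed to (len(t),) for a
        single channel.  An empty memory predicts 0.
        """
        scalar = np.ndim(t) == 0
        probes = np.atleast_1d(np.asarray(t, dtype=float))
        c = max(self.n_channels, 1)
        if self.n_samples == 0:
            out = np.zeros((probes.size, c))
        else:
            kc = self.kernel.cross(probes, self.store.times)
            out = kc @ (self.store.importances[:, None] * self.store.loads)
        if scalar:
            out = out[0]
        if c == 1:
            out = out.squeeze(-1) if not scalar else float(out[0])
        return out

    # -- pruning and importance editing -------------------------------------

    def prune_lowest_importance(self) -> int:
        """Remove the lowest-importance sample (ties: oldest) and downdate.

        The survivor inverse follows from partitioning the current inverse
        with the removed index last as [[A, b], [b', c]]: the remaining
        inverse is A - b b'/c.  Survivor loads are recomputed from the
        downdated inverse so exact recovery holds on the survivors.
        Returns the removed index.
        """
        p = self.n_samples
        if p < 2:
            raise ValueError("need at least 2 samples to prune")
        j = int(np.argmin(self.store.importances))  # argmin -> oldest on ties
        keep = np.array([i for i in range(p) if i != j])
        perm = np.append(keep, j)
        m = self.state.inv[np.ix_(perm, perm)]
        a_block, b, c = m[:-1, :-1], m[:-1, -1], m[-1, -1]
        if c <= 0.0 or not np.isfinite(c):
            logger.warning(
                "pruning downdate ill-posed (corner %.3g); re-inverting survivor "
                "kernel matrix", c)
            a_surv = self.store.importances[keep]
            kp = (self.kernel.matrix(self.store.times[keep])
                  * np.outer(a_surv, a_surv))
            inv = np.linalg.inv(kp)
        else:
            inv = a_block - np.outer(b, b) / c
        self.store.times = self.store.times[keep]
        self.store.targets = self.store.targets[keep]
        self.store.importances = self.store.importances[keep]
        self.state.inv = inv
        self.store.loads = inv @ self.store.targets
        return j

    def set_importance(self, n: int, a_new: float) -> "KSVR":
        """Post-hoc consolidation/extinction: change a_n and rebuild the fit.

        The scaled kernel changes a whole row/column, so the fit is rebuilt
        from the retained (t, y, a) triples; O(P^3).
        """
        if not 0 <= n < self.n_samples:
            raise IndexError(f"sample index {n} out of range")
        a_new = float(a_new)
        if not 0.0 <= a_new <= 1.0:
            raise ValueError("importance must lie in [0, 1]")
        importances = self.store.importances.copy()
        importances[n] = a_new
        rebuilt = KSVR(self.config).fit(self.store.times,
                                        self.store.targets, importances)
        self.store, self.state = rebuilt.store, rebuilt.state
        self._n_channels = rebuilt._n_channels
        return self

    # -- serialization -------------------------------------------------------

    def save_csv(self, path) -> None:
        """Flat CSV dump (time, importance, target_k..., load_k...) so fits
        are inspectable and resumable given the same kernel config."""
        c = max(self.n_channels, 1)
        header = ",".join(
            ["time", "importance"]
            + [f"target_{k}" for k in range(c)]
            + [f"load_{k}" for k in range(c)])
        table = np.column_stack([
            self.store.times, self.store.importances,
            self.store.targets.reshape(self.n_samples, -1),
            self.store.loads.reshape(self.n_samples, -1),
        ]) if self.n_samples else np.empty((0, 2 + 2 * c))
        np.savetxt(path, table, delimiter=",", header=header, comments="")

    @classmethod
    def load_csv(cls, path, config: FitConfig) -> "KSVR":
        """Rebuild a model from a CSV dump by refitting the stored triples
        (the inverse is reconstructed, not read)."""
        table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        model = cls(config)
        if table.size == 0:
            return model
        n_extra = table.shape[1] - 2
        c = n_extra // 2
        return model.fit(table[:, 0], table[:, 2:2 + c], table[:, 1])


def fit_batch(times, targets, importances=None, config: FitConfig | None = None,
              **config_kwargs) -> KSVR:
    """Convenience wrapper: build a :class:`KSVR` and fit it sequentially."""
    if config is None:
        config = FitConfig(**config_kwargs)
    return KSVR(config).fit(times, targets, importances)
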