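"""Kernel functions with a neural interpretation.

A kernel ``kappa(t, t')`` stands in for the scalar product of two reservoir
activity patterns indexed by time (the kernel trick).  Two analytic kernels
are provided — the triangular overlap of hippocampal theta-sequence patterns
and the autocorrelation of a gammatone (cochlear) filter — together with
empirical Gram-matrix kernels built from an explicit pattern matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Kernel",
    "TriangularThetaParams",
    "TriangularThetaKernel",
    "triangular_kernel",
    "GammatoneParams",
    "erb_bandwidth",
    "gammatone_impulse_response",
    "AutocorrelationKernel",
    "kernel_from_autocorrelation",
    "EmpiricalKernel",
    "empirical_kernel",
    "kernel_from_config",
]


class Kernel:
    """Symmetric positive-semidefinite function of two sample times.

    Subclasses implement :meth:`evaluate`, which must broadcast over numpy
    arrays.  ``self_value(t)`` is ``evaluate(t, t)`` and must be positive.
    """

    def evaluate(self, t, t_prime):
        raise NotImplementedError

    def self_value(self, t):
        return self.evaluate(t, t)

    def matrix(self, times) -> np.ndarray:
        """Gram matrix over a finite set of sample times."""
        times = np.asarray(times, dtype=float)
        return np.asarray(self.evaluate(times[:, None], times[None, :]), dtype=float)

    def cross(self, probes, times) -> np.ndarray:
        """Cross-kernel matrix, shape (len(probes), len(times))."""
        probes = np.atleast_1d(np.asarray(probes, dtype=float))
        times = np.asarray(times, dtype=float)
        return np.asarray(self.evaluate(probes[:, None], times[None, :]), dtype=float)

    def __call__(self, t, t_prime):
        return self.evaluate(t, t_prime)


# ---------------------------------------------------------------------------
# Triangular theta-sequence kernel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriangularThetaParams:
    """Parameters of the theta-sequence overlap kernel.

    n_neurons
        Population size N of the reservoir.
    seq_length
        Number S of phase ensembles active per theta cycle; also the distance
        beyond which pattern overlap stops decaying.
    sparseness
        Probability f of a neuron participating in a given ensemble.
    """

    n_neurons: int
    seq_length: int
    sparseness: float

    def __post_init__(self):
        if self.n_neurons < 1 or self.seq_length < 1:
            raise ValueError("n_neurons and seq_length must be >= 1")
        if not 0.0 < self.sparseness < 1.0:
            raise ValueError("sparseness must lie strictly between 0 and 1")


def triangular_kernel(d, params: TriangularThetaParams):
    """Expected overlap of two theta-cycle population patterns at cycle
    distance ``d``:  N ( [S - d]^+ f (1 - f) + (S f)^2 ).

    Piecewise linear, nonincreasing in ``d`` and constant (the chance-overlap
    pedestal ``N (S f)^2``) for ``d >= S``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("cycle distance d must be nonnegative")
    n, s, f = params.n_neurons, params.seq_length, params.sparseness
    tri = np.clip(s - d, 0.0, None)
    value = n * (tri * f * (1.0 - f) + (s * f) ** 2)
    return value if value.ndim else float(value)


class TriangularThetaKernel(Kernel):
    """Continuous-distance triangular kernel ``kappa(t, t') = K(|t - t'|)``."""

    def __init__(self, n_neurons: int = 10_000, seq_length: int = 10,
                 sparseness: float = 0.01):
        self.params = TriangularThetaParams(n_neurons, seq_length, sparseness)

    def evaluate(self, t, t_prime):
        return triangular_kernel(np.abs(np.asarray(t, float) - np.asarray(t_prime, float)),
                                 self.params)

    def __repr__(self):
        p = self.params
        return (f"TriangularThetaKernel(N={p.n_neurons}, S={p.seq_length}, "
                f"f={p.sparseness})")


# ---------------------------------------------------------------------------
# Gammatone autocorrelation kernel
# ---------------------------------------------------------------------------


def erb_bandwidth(f_hz):
    """Equivalent rectangular bandwidth 24.7 (4.37 f/1000 + 1) Hz
    (Glasberg & Moore)."""
    return 24.7 * (4.37 * np.asarray(f_hz, dtype=float) / 1000.0 + 1.0)


@dataclass(frozen=True)
class GammatoneParams:
    """Gammatone filter ``g(t) = t^(order-1) exp(-2 pi b ERB(f_c) t) cos(2 pi f_c t)``.

    f_c
        Center frequency in Hz; must satisfy 0 < f_c < fs/2.
    fs
        Sampling rate in Hz.
    bandwidth_scale
        Width constant b in multiples of the ERB (default 2.019).
    order
        Filter order (default 4, the standard auditory-model choice).
    max_lag
        Truncation of the impulse response in seconds (default 50 ms).
    """

    f_c: float
    fs: float = 44_100.0
    bandwidth_scale: float = 2.019
    order: int = 4
    max_lag: float = 0.05

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.bandwidth_scale <= 0:
            raise ValueError("bandwidth_scale must be positive")
        if not 0.0 < self.f_c < self.fs / 2.0:
            raise ValueError(
                f"center frequency {self.f_c} Hz would alias at fs={self.fs} Hz")
        if self.max_lag <= 0:
            raise ValueError("max_lag must be positive")


def gammatone_impulse_response(params: GammatoneParams) -> np.ndarray:
    """Peak-normalized gammatone filter taps sampled at ``params.fs`` on
    ``t in [0, max_lag)``."""
    t = np.arange(0.0, params.max_lag, 1.0 / params.fs)
    decay = 2.0 * np.pi * params.bandwidth_scale * erb_bandwidth(params.f_c)
    g = t ** (params.order - 1) * np.exp(-decay * t) * np.cos(
        2.0 * np.pi * params.f_c * t)
    peak = np.max(np.abs(g))
    if peak == 0.0:
        raise ValueError("degenerate gammatone impulse response")
    return g / peak


class AutocorrelationKernel(Kernel):
    """Kernel ``kappa(t, t') = A(|t - t'|)`` from the autocorrelation A of a
    filter's impulse response, normalized so A(0) = 1.

    This is the limit of a large population of auditory-nerve fibers driving
    one cochlear channel at random delays: the fiber-pattern scalar product
    converges to the autocorrelation of the channel response.  Lags between
    the tap grid are linearly interpolated; lags beyond the truncation are 0.
    """

    def __init__(self, autocorr: np.ndarray, fs: float):
        self._ac = np.asarray(autocorr, dtype=float)
        self._fs = float(fs)
        self._lags = np.arange(self._ac.size) / self._fs
        self.max_lag = self._lags[-1]

    def evaluate(self, t, t_prime):
        lag = np.abs(np.asarray(t, float) - np.asarray(t_prime, float))
        val = np.interp(lag, self._lags, self._ac, right=0.0)
        return val if np.ndim(val) else float(val)


def kernel_from_autocorrelation(taps, fs: float) -> AutocorrelationKernel:
    """Build the autocorrelation kernel of a filter-tap sequence."""
    taps = np.asarray(taps, dtype=float)
    if taps.size == 0:
        raise ValueError("taps must be nonempty")
    if not np.any(taps):
        raise ValueError("degenerate kernel: all-zero taps")
    ac = np.correlate(taps, taps, mode="full")[taps.size - 1:]
    return AutocorrelationKernel(ac / ac[0], fs)


# ---------------------------------------------------------------------------
# Empirical Gram-matrix kernel
# ---------------------------------------------------------------------------


class EmpiricalKernel(Kernel):
    """Kernel over integer pattern indices, ``kappa(n, m) = x_n . x_m``."""

    def __init__(self, gram: np.ndarray):
        self.gram = np.asarray(gram, dtype=float)

    def evaluate(self, t, t_prime):
        n = np.rint(np.asarray(t, dtype=float)).astype(int)
        m = np.rint(np.asarray(t_prime, dtype=float)).astype(int)
        val = self.gram[n, m]
        return val if np.ndim(val) else float(val)


def empirical_kernel(X) -> EmpiricalKernel:
    """Kernel from the Gram matrix ``X^T X`` of a pattern matrix whose columns
    are the reservoir patterns.  Accepts a raw (N, T) array or any object with
    an ``X`` attribute (e.g. a pattern matrix container)."""
    X = np.asarray(getattr(X, "X", X), dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("pattern matrix must be 2-D with at least one column")
    return EmpiricalKernel(X.T @ X)


# ---------------------------------------------------------------------------
# Config plumbing
# ---------------------------------------------------------------------------


def kernel_from_config(cfg: dict) -> Kernel:
    """Instantiate a kernel from a plain key-value block.

    ``kind: triangular`` takes N, S, f; ``kind: gammatone`` takes f_c, fs,
    bandwidth_scale, order, max_lag.
    """
    kind = str(cfg.get("kind", "triangular")).lower()
    if kind == "triangular":
        return TriangularThetaKernel(
            n_neurons=int(cfg.get("N", 10_000)),
            seq_length=int(cfg.get("S", 10)),
            sparseness=float(cfg.get("f", 0.01)),
        )
    if kind == "gammatone":
        params = GammatoneParams(
            f_c=float(cfg["f_c"]),
            fs=float(cfg.get("fs", 44_100.0)),
            bandwidth_scale=float(cfg.get("bandwidth_scale", 2.019)),
            order=int(cfg.get("order", 4)),
            max_lag=float(cfg.get("max_lag", 0.05)),
        )
        return kernel_from_autocorrelation(gammatone_impulse_response(params), params.fs)
    raise ValueError(f"unknown kernel kind {kind!r}")
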