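"""Synthetic hippocampal theta-sequence population patterns.

Sparse binary phase ensembles xi_1, ..., xi_{T+S-1} (each neuron active with
probability f) are swept through a window of S consecutive ensembles: the
population pattern in theta cycle t is x_t = sum_{k=0}^{S-1} xi_{t+k}.
Adjacent cycles share S-1 ensembles, so pattern overlaps decay linearly with
cycle distance — the empirical counterpart of the analytic triangular kernel.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseEnsembles",
    "PatternMatrix",
    "generate_ensembles",
    "build_patterns",
    "raster",
    "patterns_to_sparse_csv",
]


@dataclass(frozen=True)
class PhaseEnsembles:
    """T+S-1 binary ensemble vectors, shape (n_phases, n_neurons)."""

    xi: np.ndarray
    n_cycles: int
    seq_length: int
    sparseness: float
    seed: int


@dataclass(frozen=True)
class PatternMatrix:
    """N x T integer pattern matrix; column t is the cycle-t population
    pattern (a neuron active in several of the S windowed ensembles counts
    multiply)."""

    X: np.ndarray
    n_neurons: int
    n_cycles: int
    seq_length: int
    sparseness: float


def generate_ensembles(n_neurons: int, n_cycles: int, seq_length: int,
                       sparseness: float, seed: int = 0) -> PhaseEnsembles:
    """Draw T+S-1 independent Bernoulli(f) ensemble vectors of length N."""
    if n_neurons < 1 or n_cycles < 1 or seq_length < 1:
        raise ValueError("n_neurons, n_cycles and seq_length must be >= 1")
    if not 0.0 < sparseness < 1.0:
        raise ValueError("sparseness must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    xi = (rng.random((n_cycles + seq_length - 1, n_neurons))
          < sparseness).astype(np.uint8)
    return PhaseEnsembles(xi, n_cycles, seq_length, sparseness, seed)


def build_patterns(ensembles: PhaseEnsembles) -> PatternMatrix:
    """Sliding-window sums x_t = sum_{k<S} xi_{t+k}, returned as N x T."""
    xi = ensembles.xi
    s = ensembles.seq_length
    csum = np.zeros((xi.shape[0] + 1, xi.shape[1]), dtype=np.int64)
    np.cumsum(xi, axis=0, out=csum[1:])
    windows = csum[s:] - csum[:-s]  # (T, N)
    return PatternMatrix(windows.T.copy(), xi.shape[1], ensembles.n_cycles,
                         s, ensembles.sparseness)


def raster(ensembles: PhaseEnsembles, first_n_neurons: int | None = None):
    """Spike-raster event list (neuron, cycle, within-cycle phase slot).

    Each active entry of ensemble xi_{t+k} fires in cycle t at phase slot k,
    so a neuron active in one ensemble appears in S consecutive cycles.
    """
    xi = ensembles.xi
    n = xi.shape[1] if first_n_neurons is None else min(first_n_neurons, xi.shape[1])
    events = []
    for t in range(ensembles.n_cycles):
        for k in range(ensembles.seq_length):
            for neuron in np.flatnonzero(xi[t + k, :n]):
                events.append((int(neuron), t, k))
    return events


def patterns_to_sparse_csv(patterns: PatternMatrix, path) -> None:
    """Export nonzero pattern entries as (neuron, cycle, count) triplets."""
    neuron, cycle = np.nonzero(patterns.X)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["neuron", "cycle", "count"])
        for i, j in zip(neuron, cycle):
            writer.writerow([int(i), int(j), int(patterns.X[i, j])])
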