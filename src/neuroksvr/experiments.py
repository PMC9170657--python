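"""Desk-scale experiment protocols on synthetic signals.

Each protocol mirrors one of the study conditions the learner was designed
for: retrieval of a low-pass noise signal from sparse observations, post-hoc
addition in arbitrary order, importance scaling (center-weighted and random),
capacity under a cutoff dimension, and multi-channel "movie" compression.
All randomness flows through explicit integer seeds and every runner can
write a machine-readable CSV plus a parameter log.
"""

from __future__ import annotations

import csv
import json
import os

import numpy as np
from scipy import stats

from .kernels import Kernel, TriangularThetaKernel
from .ksvr import FitConfig, fit_batch

__all__ = [
    "lowpass_noise",
    "synthetic_movie_signal",
    "run_retrieval_experiment",
    "run_importance_experiment",
    "run_capacity_experiment",
    "sustained_capacity_multiple",
    "run_movie_compression_demo",
    "write_results",
]


def _default_kernel() -> Kernel:
    return TriangularThetaKernel(n_neurons=10_000, seq_length=10, sparseness=0.01)


def _child_seed(seed: int, *indices: int) -> int:
    """Deterministic per-repetition seed below 2**31."""
    ss = np.random.SeedSequence([int(seed), *map(int, indices)])
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# Synthetic signals
# ---------------------------------------------------------------------------


def lowpass_noise(n_steps: int, window: int = 50, seed: int = 0) -> np.ndarray:
    """Unit-variance white Gaussian noise smoothed by a centered moving
    average of the given window (edges truncated to the available support)."""
    if not n_steps > window >= 1:
        raise ValueError("need n_steps > window >= 1")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n_steps)
    ones = np.ones(window)
    return (np.convolve(noise, ones, mode="same")
            / np.convolve(np.ones(n_steps), ones, mode="same"))


def synthetic_movie_signal(n_frames: int = 110, n_channels: int = 3,
                           window: int = 20, seed: int = 0) -> np.ndarray:
    """Smoothly varying multi-channel 'brightness' traces standing in for
    per-pixel RGB channels of a movie clip; shape (n_frames, n_channels)."""
    return np.column_stack([
        lowpass_noise(n_frames, window, _child_seed(seed, c))
        for c in range(n_channels)])


# ---------------------------------------------------------------------------
# Retrieval (sparse observation of a low-pass signal)
# ---------------------------------------------------------------------------


def run_retrieval_experiment(n_steps: int = 100, window: int = 50,
                             p_values=(5, 15, 50, 100), kernel: Kernel | None = None,
                             seed: int = 0, out_dir=None) -> dict:
    """Fit increasing numbers P of randomly positioned observations of a
    low-pass noise signal and report RMSE over all time steps per P, plus an
    order-invariance check (iterative post-hoc addition vs. joint fit)."""
    kernel = kernel or _default_kernel()
    signal = lowpass_noise(n_steps, window, seed)
    grid = np.arange(n_steps, dtype=float)
    rng = np.random.default_rng(_child_seed(seed, 1))
    results = {"P": [], "rmse": [], "signal": signal}
    predictions = {}
    for p in p_values:
        if p == 0:
            pred = np.zeros(n_steps)
        else:
            pos = np.sort(rng.choice(n_steps, size=min(p, n_steps), replace=False))
            model = fit_batch(pos.astype(float), signal[pos], config=FitConfig(kernel))
            pred = model.predict(grid)
        results["P"].append(int(p))
        results["rmse"].append(float(np.sqrt(np.mean((pred - signal) ** 2))))
        predictions[int(p)] = pred
    results["predictions"] = predictions

    # Post-hoc addition: fit 15 points, then iteratively add 35 more, and
    # compare with fitting all 50 at once.
    pos = rng.choice(n_steps, size=min(50, n_steps), replace=False).astype(float)
    joint = fit_batch(pos, signal[pos.astype(int)], config=FitConfig(kernel))
    staged = fit_batch(pos[:15], signal[pos[:15].astype(int)],
                       config=FitConfig(kernel))
    for t in pos[15:]:
        staged.add_sample(t, signal[int(t)])
    diff = np.max(np.abs(joint.predict(grid) - staged.predict(grid)))
    scale = np.max(np.abs(joint.predict(grid)))
    results["posthoc_max_rel_diff"] = float(diff / max(scale, 1e-300))
    if out_dir is not None:
        write_results(out_dir, "retrieval",
                      {"P": results["P"], "rmse": results["rmse"]},
                      {"n_steps": n_steps, "window": window, "seed": seed,
                       "p_values": list(p_values)})
    return results


# ---------------------------------------------------------------------------
# Importance scaling
# ---------------------------------------------------------------------------


def run_importance_experiment(mode: str = "random", n_steps: int | None = None,
                              n_samples: int | None = None,
                              cutoff_dimension: int = 300,
                              lam: float = 0.999, center: int | None = None,
                              window: int = 50, kernel: Kernel | None = None,
                              seed: int = 0, out_dir=None) -> dict:
    """Importance-scaling protocols.

    mode="center": fit all points of a length-100 signal with attenuation
    a_t = lam^|P* - t| around a center P*; retrieval error is smaller within
    +-10 steps of the center than far from it.

    mode="random": a 20000-step signal observed at 500 random points with
    a ~ U(0.5, 1) under cutoff 300; reports the Spearman correlation of the
    per-sample absolute retrieval error with a (negative) and with sample
    time (near zero).
    """
    kernel = kernel or _default_kernel()
    if mode == "center":
        n_steps = n_steps or 100
        center = n_steps // 2 if center is None else center
        signal = lowpass_noise(n_steps, window, seed)
        times = np.arange(n_steps, dtype=float)
        a = lam ** np.abs(center - times)
        model = fit_batch(times, signal, a,
                          config=FitConfig(kernel, cutoff_dimension=max(
                              cutoff_dimension, n_steps + 1)))
        err = np.abs(model.predict(times) - signal)
        near = np.abs(times - center) <= 10
        result = {
            "mode": mode, "center": int(center),
            "near_mean_error": float(err[near].mean()),
            "far_mean_error": float(err[~near].mean()),
            "errors": err, "importances": a, "signal": signal,
        }
    elif mode == "random":
        n_steps = n_steps or 20_000
        n_samples = n_samples or 500
        signal = lowpass_noise(n_steps, window, seed)
        rng = np.random.default_rng(_child_seed(seed, 2))
        pos = np.sort(rng.choice(n_steps, size=n_samples, replace=False))
        a = rng.uniform(0.5, 1.0, size=n_samples)
        model = fit_batch(pos.astype(float), signal[pos], a,
                          config=FitConfig(kernel, cutoff_dimension=cutoff_dimension))
        err = np.abs(model.predict(pos.astype(float)) - signal[pos])
        rho_a, p_a = stats.spearmanr(err, a)
        rho_t, p_t = stats.spearmanr(err, pos)
        result = {
            "mode": mode, "errors": err, "importances": a, "times": pos,
            "spearman_error_importance": float(rho_a),
            "p_error_importance": float(p_a),
            "spearman_error_time": float(rho_t),
            "p_error_time": float(p_t),
        }
    else:
        raise ValueError("mode must be 'center' or 'random'")
    if out_dir is not None:
        scalars = {k: v for k, v in result.items() if np.ndim(v) == 0}
        write_results(out_dir, f"importance_{mode}",
                      {k: [v] for k, v in scalars.items() if isinstance(v, float)},
                      {"mode": mode, "seed": seed, "lam": lam,
                       "cutoff_dimension": cutoff_dimension})
    return result


# ---------------------------------------------------------------------------
# Capacity under the cutoff dimension
# ---------------------------------------------------------------------------


def run_capacity_experiment(cutoffs=(100, 300), lengths=None, n_reps: int = 20,
                            kernel_length: int = 25, window: int = 100,
                            base_cutoff: int = 300, seed: int = 0,
                            out_dir=None) -> dict:
    """Reconstruction error versus signal length for different cutoff
    dimensions.

    Per repetition: a running-average-``window`` noise signal of length T is
    observed at every other time step (P = T/2) with importance ramping
    linearly toward the signal end (a_i = (i+1)/P), and fitted with a
    triangular kernel of length ``kernel_length`` under the given cutoff.
    RMSE is taken over all T time steps.  Returns mean RMSE and the 5%/95%
    quantile band over ``n_reps`` seeded repetitions.
    """
    if lengths is None:
        lengths = [m * base_cutoff for m in range(1, 11)]
    kernel = TriangularThetaKernel(n_neurons=10_000, seq_length=kernel_length,
                                   sparseness=0.01)
    mean_rmse = {dc: {} for dc in cutoffs}
    q_lo = {dc: {} for dc in cutoffs}
    q_hi = {dc: {} for dc in cutoffs}
    for dc in cutoffs:
        for length in lengths:
            rmses = np.empty(n_reps)
            # signal seeds depend on (length, rep) only, so different
            # cutoffs are compared on the same signal realizations
            for rep in range(n_reps):
                rmses[rep] = _capacity_rep(length, window, kernel, dc,
                                           _child_seed(seed, length, rep))
            mean_rmse[dc][length] = float(rmses.mean())
            q_lo[dc][length] = float(np.quantile(rmses, 0.05))
            q_hi[dc][length] = float(np.quantile(rmses, 0.95))
    result = {"lengths": list(lengths), "cutoffs": list(cutoffs),
              "mean_rmse": mean_rmse, "q05": q_lo, "q95": q_hi}
    if out_dir is not None:
        rows = {"cutoff": [], "length": [], "mean_rmse": [], "q05": [], "q95": []}
        for dc in cutoffs:
            for length in lengths:
                rows["cutoff"].append(dc)
                rows["length"].append(length)
                rows["mean_rmse"].append(mean_rmse[dc][length])
                rows["q05"].append(q_lo[dc][length])
                rows["q95"].append(q_hi[dc][length])
        write_results(out_dir, "capacity", rows,
                      {"cutoffs": list(cutoffs), "lengths": list(lengths),
                       "n_reps": n_reps, "kernel_length": kernel_length,
                       "window": window, "seed": seed})
    return result


def _capacity_rep(length: int, window: int, kernel: Kernel, cutoff: int,
                  seed: int) -> float:
    signal = lowpass_noise(length, window, seed)
    times = np.arange(0, length, 2, dtype=float)  # P = T/2
    p = times.size
    importances = (np.arange(p) + 1.0) / p  # linear ramp toward the end
    model = fit_batch(times, signal[times.astype(int)], importances,
                      config=FitConfig(kernel, cutoff_dimension=cutoff))
    pred = model.predict(np.arange(length, dtype=float))
    return float(np.sqrt(np.mean((pred - signal) ** 2)))


def sustained_capacity_multiple(capacity_result: dict, cutoff: int = 300,
                                factor: float = 2.0) -> int:
    """Largest tested multiple m of the cutoff for which mean RMSE at signal
    length m * cutoff stays within ``factor`` of the mean RMSE at length
    equal to the cutoff."""
    mean_rmse = capacity_result["mean_rmse"][cutoff]
    base = mean_rmse[cutoff]
    passing = [length / cutoff for length, rmse in mean_rmse.items()
               if rmse <= factor * base]
    return int(max(passing, default=0))


# ---------------------------------------------------------------------------
# Multi-channel (movie) compression demo
# ---------------------------------------------------------------------------


def run_movie_compression_demo(n_frames: int = 110, n_stored: int = 20,
                               n_channels: int = 3, kernel: Kernel | None = None,
                               seed: int = 0, out_dir=None) -> dict:
    """Store ``n_stored`` equally spaced frames of a synthetic multi-channel
    signal against one shared inverse and report the stored-frame percentage
    and per-channel RMSE over all frames."""
    kernel = kernel or _default_kernel()
    signal = synthetic_movie_signal(n_frames, n_channels, seed=seed)
    frames = np.unique(np.round(np.linspace(0, n_frames - 1, n_stored))).astype(int)
    model = fit_batch(frames.astype(float), signal[frames],
                      config=FitConfig(kernel, cutoff_dimension=max(301, n_stored + 1)))
    pred = model.predict(np.arange(n_frames, dtype=float))
    pred = np.atleast_2d(pred).reshape(n_frames, n_channels)
    rmse = np.sqrt(np.mean((pred - signal) ** 2, axis=0))
    result = {
        "stored_percent": 100.0 * frames.size / n_frames,
        "n_frames": n_frames, "n_stored": int(frames.size),
        "per_channel_rmse": rmse.tolist(),
        "signal": signal, "prediction": pred,
    }
    if out_dir is not None:
        write_results(out_dir, "movie_demo",
                      {"channel": list(range(n_channels)),
                       "rmse": rmse.tolist()},
                      {"n_frames": n_frames, "n_stored": int(frames.size),
                       "stored_percent": result["stored_percent"],
                       "seed": seed})
    return result


# ---------------------------------------------------------------------------
# Output plumbing
# ---------------------------------------------------------------------------


def write_results(out_dir, name: str, columns: dict, params: dict) -> None:
    """Write a results table (CSV) and a parameter log (JSON)."""
    os.makedirs(out_dir, exist_ok=True)
    keys = list(columns)
    n_rows = len(columns[keys[0]]) if keys else 0
    with open(os.path.join(out_dir, f"{name}.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(keys)
        for i in range(n_rows):
            writer.writerow([columns[k][i] for k in keys])
    with open(os.path.join(out_dir, f"{name}_params.json"), "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True)
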