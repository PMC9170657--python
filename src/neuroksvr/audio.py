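"""Sound memorization and reconstruction through cochlear frequency kernels.

A mono waveform is split by a seven-channel gammatone filterbank (center
frequencies 2^k * 200 Hz, k = 0..6, width 2.019 ERB).  In each channel the
band signal is sampled at rho_k points per center-frequency cycle
(rho = 6, 4, 3, 3, 1.5, 1, 0.25 from low to high), and the samples are
memorized by independent recursive KSVR fits in chunks of 500 points, with
the channel's autocorrelation kernel supplying the carrier fine structure
between samples.  Resynthesis divides each reconstructed band by the
channel's transfer function in the Fourier domain (with a stabilization
floor), keeps 10 Hz – 20 kHz, sums the channels and rescales to the RMS of
the reference waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import fftconvolve, resample_poly

from .kernels import (AutocorrelationKernel, GammatoneParams,
                      gammatone_impulse_response, kernel_from_autocorrelation)
from .ksvr import KSVR, FitConfig

__all__ = [
    "ChannelConfig",
    "BankConfig",
    "default_bank",
    "analyze",
    "select_sample_times",
    "ChunkFit",
    "fit_channel",
    "reconstruct_channel",
    "synthesize",
    "AudioMemory",
    "compress",
    "reconstruct",
    "filtered_reference",
    "read_wav",
    "write_wav",
    "save_memory",
    "load_memory",
]

DEFAULT_RHO = (6.0, 4.0, 3.0, 3.0, 1.5, 1.0, 0.25)


@dataclass(frozen=True)
class ChannelConfig:
    """One cochlear channel: center frequency, sampling density rho (data
    points per cycle), chunk size of the independent fits, and the gammatone
    kernel parameters."""

    f_c: float
    rho: float
    chunk_size: int = 500
    kernel: GammatoneParams = None  # filled by __post_init__ if omitted

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.chunk_size < 2:
            raise ValueError("chunk_size must be >= 2")
        if self.kernel is None:
            object.__setattr__(self, "kernel", GammatoneParams(f_c=self.f_c))


@dataclass(frozen=True)
class BankConfig:
    """Gammatone filterbank: channels with strictly increasing center
    frequencies below Nyquist, plus the synthesis band limits."""

    channels: tuple
    fs: float = 44_100.0
    f_lo: float = 10.0
    f_hi: float = 20_000.0

    def __post_init__(self):
        fcs = [ch.f_c for ch in self.channels]
        if any(b <= a for a, b in zip(fcs, fcs[1:])):
            raise ValueError("channel center frequencies must be strictly increasing")
        if any(fc >= self.fs / 2 for fc in fcs):
            raise ValueError("all center frequencies must be below Nyquist")


def default_bank(fs: float = 44_100.0, chunk_size: int = 500) -> BankConfig:
    """The seven-channel bank: f_c = 2^k * 200 Hz with the standard rho."""
    channels = tuple(
        ChannelConfig(f_c=2.0 ** k * 200.0, rho=DEFAULT_RHO[k],
                      chunk_size=chunk_size,
                      kernel=GammatoneParams(f_c=2.0 ** k * 200.0, fs=fs))
        for k in range(7))
    return BankConfig(channels=channels, fs=fs)


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------


def analyze(signal, bank: BankConfig) -> np.ndarray:
    """Filterbank analysis: per-channel band signals c_f(t), each the
    convolution of the input with the channel's gammatone impulse response
    (truncated to the input length)."""
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    out = np.empty((len(bank.channels), signal.size))
    for i, ch in enumerate(bank.channels):
        taps = gammatone_impulse_response(ch.kernel)
        out[i] = fftconvolve(signal, taps)[:signal.size]
    return out


def select_sample_times(channel: ChannelConfig, duration: float) -> np.ndarray:
    """Equally spaced sample times at rho data points per cycle: interval
    1 / (rho * f_c), covering [0, duration)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt = 1.0 / (channel.rho * channel.f_c)
    times = np.arange(0.0, duration, dt)
    return times if times.size else np.zeros(1)


# ---------------------------------------------------------------------------
# Per-channel fitting and reconstruction
# ---------------------------------------------------------------------------


@dataclass
class ChunkFit:
    """One chunk's fitted memory and the half-open time span it covers."""

    model: KSVR
    t_start: float
    t_end: float


def fit_channel(band, fs: float, times, channel: ChannelConfig,
                novelty_tolerance: float = 1e-8) -> list[ChunkFit]:
    """Fit one band signal at the selected sample times, in independent
    consecutive chunks of ``channel.chunk_size`` points with importance 1.

    Sample times are snapped to the waveform grid (nearest sample) before
    fitting.  Chunk spans partition [0, duration): each chunk predicts from
    its first sample time up to the next chunk's first sample time.
    """
    band = np.asarray(band, dtype=float)
    idx = np.unique(np.clip(np.rint(np.asarray(times, float) * fs).astype(int),
                            0, band.size - 1))
    kernel = kernel_from_autocorrelation(
        gammatone_impulse_response(channel.kernel), channel.kernel.fs)
    duration = band.size / fs
    chunks = [idx[i:i + channel.chunk_size]
              for i in range(0, idx.size, channel.chunk_size)]
    fits: list[ChunkFit] = []
    for c, chunk in enumerate(chunks):
        cfg = FitConfig(kernel=kernel, cutoff_dimension=chunk.size or 1,
                        novelty_tolerance=novelty_tolerance)
        model = KSVR(cfg).fit(chunk / fs, band[chunk])
        t_start = 0.0 if c == 0 else chunks[c][0] / fs
        t_end = duration if c == len(chunks) - 1 else chunks[c + 1][0] / fs
        fits.append(ChunkFit(model, t_start, t_end))
    return fits


def reconstruct_channel(fits: list[ChunkFit], grid_times) -> np.ndarray:
    """Concatenated per-chunk predictions on an output time grid; each grid
    point is evaluated only within the chunk whose span contains it (no
    cross-chunk kernel support), and 0 outside all spans."""
    grid_times = np.asarray(grid_times, dtype=float)
    out = np.zeros(grid_times.size)
    for chunk in fits:
        mask = (grid_times >= chunk.t_start) & (grid_times < chunk.t_end)
        if np.any(mask):
            out[mask] = chunk.model.predict(grid_times[mask])
    return out


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------


def synthesize(band_signals, bank: BankConfig, reference,
               regularization: float = 1e-6) -> np.ndarray:
    """Invert the filterbank: the channel spectra are divided by the
    gammatone transfer functions, frequencies outside [f_lo, f_hi] are
    omitted, the channels are summed and the result is rescaled to the
    reference waveform's RMS.

    The division is stabilized as a dual-frame (matched-filter) inversion:
    each band is weighted by the conjugate of its own transfer function and
    the channel sum is normalized by the bank's total power response
    sum_j |Gamma_j|^2 (plus a small relative regularizer).  Per bin this
    equals division by Gamma where one channel dominates, avoids the noise
    blow-up of a bare 1/Gamma at the filter skirts where reconstructed band
    signals carry fitting error, and counts bins covered by several
    overlapping channels once instead of once per channel.
    """
    band_signals = np.asarray(band_signals, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if band_signals.ndim != 2 or band_signals.shape[0] != len(bank.channels):
        raise ValueError("need one band signal per bank channel")
    n = band_signals.shape[1]
    if reference.size != n:
        raise ValueError("reference waveform length must match the band signals")
    # Zero-pad so the deconvolution matches the linear (not circular)
    # convolution of the analysis stage; wrap-around otherwise injects a
    # strong transient at the signal edges.
    taps_all = [gammatone_impulse_response(ch.kernel) for ch in bank.channels]
    nfft = n + max(t.size for t in taps_all)
    freqs = np.fft.rfftfreq(nfft, 1.0 / bank.fs)
    in_band = (freqs >= bank.f_lo) & (freqs <= bank.f_hi)
    numerator = np.zeros(freqs.size, dtype=complex)
    power = np.zeros(freqs.size)
    for band, taps in zip(band_signals, taps_all):
        gamma = np.fft.rfft(taps, nfft)
        numerator += np.fft.rfft(band, nfft) * np.conj(gamma)
        power += np.abs(gamma) ** 2
    floor = regularization * power.max() if power.max() > 0 else 1.0
    spectrum = np.where(in_band, numerator / (power + floor), 0.0)
    total = np.fft.irfft(spectrum, nfft)[:n]
    ref_rms = np.sqrt(np.mean(reference ** 2))
    out_rms = np.sqrt(np.mean(total ** 2))
    if out_rms > 0:
        total *= ref_rms / out_rms
    return total


# ---------------------------------------------------------------------------
# End-to-end compression / reconstruction
# ---------------------------------------------------------------------------


def _guard_length(bank: BankConfig) -> int:
    """Longest gammatone impulse response in the bank, in samples.  Inputs
    are zero-padded by this guard interval before analysis so the filter
    ring-out stays inside the analyzed window and the Fourier deconvolution
    matches a linear convolution exactly; the pad is cropped after
    synthesis."""
    return max(gammatone_impulse_response(ch.kernel).size
               for ch in bank.channels)


@dataclass
class AudioMemory:
    """A compressed sound: per-channel chunked KSVR fits plus the metadata
    needed for resynthesis (bank, lengths, reference RMS)."""

    bank: BankConfig
    channel_fits: list  # list over channels of list[ChunkFit]
    n_samples: int      # output waveform length
    reference_rms: float
    guard: int = 0      # analysis zero-pad, in samples

    @property
    def stored_sample_count(self) -> int:
        return sum(chunk.model.n_samples
                   for fits in self.channel_fits for chunk in fits)


def compress(signal, fs: float, bank: BankConfig | None = None,
             novelty_tolerance: float = 1e-8) -> AudioMemory:
    """Memorize a mono waveform: analyze, sample each channel at its rho,
    and fit each channel independently in chunks.  Inputs at a different
    sampling rate than the bank are resampled (polyphase)."""
    signal = np.asarray(signal, dtype=float)
    if bank is None:
        bank = default_bank()
    if fs != bank.fs:
        from fractions import Fraction
        frac = Fraction(int(round(bank.fs)), int(round(fs))).limit_denominator(1000)
        signal = resample_poly(signal, frac.numerator, frac.denominator)
    guard = _guard_length(bank)
    padded = np.concatenate([signal, np.zeros(guard)])
    bands = analyze(padded, bank)
    duration = padded.size / bank.fs
    channel_fits = []
    for band, ch in zip(bands, bank.channels):
        times = select_sample_times(ch, duration)
        channel_fits.append(fit_channel(band, bank.fs, times, ch,
                                        novelty_tolerance))
    return AudioMemory(bank, channel_fits, signal.size,
                       float(np.sqrt(np.mean(signal ** 2))), guard)


def reconstruct(memory: AudioMemory) -> np.ndarray:
    """Retrieve the waveform from a compressed memory: per-channel chunked
    prediction on the full (guard-padded) grid, then filterbank inversion."""
    n_padded = memory.n_samples + memory.guard
    grid = np.arange(n_padded) / memory.bank.fs
    bands = np.vstack([reconstruct_channel(fits, grid)
                       for fits in memory.channel_fits])
    reference = np.full(n_padded, memory.reference_rms)
    return synthesize(bands, memory.bank, reference)[:memory.n_samples]


def filtered_reference(signal, bank: BankConfig) -> np.ndarray:
    """Analysis–synthesis round trip without any memorization: the
    band-limited, filterbank-processed version of the input against which
    reconstructions are compared."""
    signal = np.asarray(signal, dtype=float)
    padded = np.concatenate([signal, np.zeros(_guard_length(bank))])
    return synthesize(analyze(padded, bank), bank, padded)[:signal.size]


# ---------------------------------------------------------------------------
# WAV and model I/O
# ---------------------------------------------------------------------------


def read_wav(path):
    """Read a RIFF PCM WAV as (fs, float mono waveform in [-1, 1]); stereo
    inputs are downmixed by averaging."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return fs, data.astype(float)


def write_wav(path, fs: float, signal) -> None:
    """Write a float waveform as 16-bit PCM mono, clipped to [-1, 1]."""
    signal = np.clip(np.asarray(signal, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(fs), (signal * 32767).astype(np.int16))


def save_memory(memory: AudioMemory, path) -> None:
    """Serialize a compressed sound to an .npz archive (runtime artifact)."""
    arrays = {
        "fs": np.array(memory.bank.fs),
        "n_samples": np.array(memory.n_samples),
        "guard": np.array(memory.guard),
        "reference_rms": np.array(memory.reference_rms),
        "f_c": np.array([ch.f_c for ch in memory.bank.channels]),
        "rho": np.array([ch.rho for ch in memory.bank.channels]),
        "chunk_size": np.array([ch.chunk_size for ch in memory.bank.channels]),
    }
    for i, fits in enumerate(memory.channel_fits):
        for c, chunk in enumerate(fits):
            key = f"ch{i}_chunk{c}"
            arrays[f"{key}_times"] = chunk.model.store.times
            arrays[f"{key}_targets"] = chunk.model.store.targets
            arrays[f"{key}_span"] = np.array([chunk.t_start, chunk.t_end])
    np.savez(path, **arrays)


def load_memory(path) -> AudioMemory:
    """Rebuild a compressed sound from an .npz archive by refitting the
    stored samples (cheap: the same one-shot recursion)."""
    data = np.load(path)
    fs = float(data["fs"])
    channels = tuple(
        ChannelConfig(f_c=float(fc), rho=float(rho), chunk_size=int(cs),
                      kernel=GammatoneParams(f_c=float(fc), fs=fs))
        for fc, rho, cs in zip(data["f_c"], data["rho"], data["chunk_size"]))
    bank = BankConfig(channels=channels, fs=fs)
    channel_fits = []
    for i, ch in enumerate(bank.channels):
        kernel = kernel_from_autocorrelation(
            gammatone_impulse_response(ch.kernel), fs)
        fits = []
        c = 0
        while f"ch{i}_chunk{c}_times" in data:
            key = f"ch{i}_chunk{c}"
            cfg = FitConfig(kernel=kernel,
                            cutoff_dimension=max(len(data[f"{key}_times"]), 1))
            model = KSVR(cfg).fit(data[f"{key}_times"], data[f"{key}_targets"])
            span = data[f"{key}_span"]
            fits.append(ChunkFit(model, float(span[0]), float(span[1])))
            c += 1
        channel_fits.append(fits)
    return AudioMemory(bank, channel_fits, int(data["n_samples"]),
                       float(data["reference_rms"]),
                       int(data["guard"]) if "guard" in data else 0)
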