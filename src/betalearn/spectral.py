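"""Welch PSD with dB normalization to rest, and Morlet time-frequency power.

Trial epochs span [-1, 11] s around the GO signal (STOP at 7 s, feedback at
9 s in learning trials).  Time-frequency power uses a 7-cycle complex Morlet
wavelet sampled at a 100 ms hop over 13-30 Hz, optionally z-normalized to
the pre-movement baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve, welch

__all__ = [
    "TrialEpoch",
    "TimeFreqPower",
    "welch_psd",
    "db_normalize",
    "morlet_tf",
    "baseline_z",
    "feedback_locked_measure",
    "BETA_FREQS",
]

BETA_FREQS = np.arange(13.0, 31.0)  # 13..30 Hz at 1 Hz steps

GO_S = 0.0
STOP_S = 7.0
FEEDBACK_S = 9.0
EPOCH_WINDOW_S = (-1.0, 11.0)


@dataclass(frozen=True)
class TrialEpoch:
    """Trial-locked data: trials x channels x time, GO at t = 0."""

    data: np.ndarray
    fs: float
    t_start: float = EPOCH_WINDOW_S[0]
    channels: tuple = ()

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("epoch data must be 3-d (trials, channels, time)")
        object.__setattr__(self, "data", data)
        if not self.channels:
            object.__setattr__(
                self, "channels", tuple(f"ch{i}" for i in range(data.shape[1]))
            )

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.data.shape[2]) / self.fs


@dataclass(frozen=True)
class TimeFreqPower:
    """Wavelet power: trials x channels x freqs x time points."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channels: tuple
    normalization: str = "none"

    def trial_average(self) -> np.ndarray:
        return self.power.mean(axis=0)


def welch_psd(signal, fs: float, window_s: float = 1.0, overlap: float = 0.5):
    """One-sided Welch PSD (Hann taper, density scaling).

    Returns (freqs, psd).  The signal must span at least two windows.
    """
    signal = np.asarray(signal, dtype=float)
    nperseg = int(round(window_s * fs))
    if signal.size < 2 * nperseg:
        raise ValueError("signal too short for two Welch windows")
    noverlap = int(round(nperseg * overlap))
    return welch(
        signal, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        scaling="density",
    )


def db_normalize(psd_block, psd_rest) -> np.ndarray:
    """Block PSD in dB relative to rest: 10*log10(block / rest)."""
    psd_block = np.asarray(psd_block, dtype=float)
    psd_rest = np.asarray(psd_rest, dtype=float)
    if np.any(psd_rest <= 0):
        raise ValueError("rest PSD must be strictly positive everywhere")
    return 10.0 * np.log10(psd_block / psd_rest)


def _morlet_kernel(freq: float, fs: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet, L2-normalized."""
    sigma_t = n_cycles / (2.0 * math.pi * freq)
    half = int(math.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(2j * math.pi * freq * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    return kernel / np.sqrt(np.sum(np.abs(kernel) ** 2))


def morlet_tf(
    epochs: TrialEpoch,
    freqs=BETA_FREQS,
    n_cycles: float = 7.0,
    hop_s: float = 0.1,
) -> TimeFreqPower:
    """Squared-magnitude Morlet wavelet transform at a fixed hop.

    Keeps per-trial power (trials x channels x freqs x times); callers
    average across trials and/or the beta band as needed.
    """
    freqs = np.asarray(freqs, dtype=float)
    fs = epochs.fs
    data = epochs.data
    n_trials, n_chan, n_samp = data.shape
    lowest = freqs.min()
    min_len = int(math.ceil(5.0 * n_cycles / (2 * math.pi * lowest) * fs)) * 2 + 1
    if n_samp < min_len:
        raise ValueError(
            f"epoch too short for the {lowest:g} Hz wavelet "
            f"({n_samp} < {min_len} samples)"
        )
    hop = max(1, int(round(hop_s * fs)))
    keep = np.arange(0, n_samp, hop)
    times = epochs.t_start + keep / fs

    power = np.empty((n_trials, n_chan, freqs.size, keep.size))
    flat = data.reshape(n_trials * n_chan, n_samp)
    # 2/fs makes the squared magnitude a one-sided density estimate, so the
    # band integral of a tone's power equals the tone variance (Parseval)
    scale = 2.0 / fs
    for fi, f in enumerate(freqs):
        kern = _morlet_kernel(f, fs, n_cycles)[None, :]
        conv = fftconvolve(flat, kern, mode="same", axes=1)
        p = scale * np.abs(conv) ** 2
        power[:, :, fi, :] = p[:, keep].reshape(n_trials, n_chan, keep.size)
    return TimeFreqPower(
        power=power, freqs=freqs, times=times, channels=epochs.channels
    )


def baseline_z(tf: TimeFreqPower, baseline=(-1.0, 0.0)) -> TimeFreqPower:
    """Z-normalize power to the pre-movement baseline, per channel and freq.

    The baseline mean/sd pool trials and baseline time points.  Normalization
    happens per frequency bin; band averaging, if wanted, comes after.
    """
    lo, hi = baseline
    mask = (tf.times >= lo) & (tf.times < hi)
    if not mask.any():
        raise ValueError("baseline window outside epoch")
    base = tf.power[:, :, :, mask]
    mean = base.mean(axis=(0, 3), keepdims=True)
    sd = base.std(axis=(0, 3), keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero baseline standard deviation")
    return replace(tf, power=(tf.power - mean) / sd, normalization="z-baseline")


def band_average(tf: TimeFreqPower, band=(13.0, 30.0)) -> np.ndarray:
    """Average power across the frequency band: trials x channels x time."""
    mask = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
    return tf.power[:, :, mask, :].mean(axis=2)


def feedback_locked_measure(
    series: np.ndarray,
    times: np.ndarray,
    channels: tuple,
    window_ms=(400.0, 1600.0),
    channel_set=None,
    feedback_s: float = FEEDBACK_S,
) -> np.ndarray:
    """Per-trial scalar: mean over a post-feedback window and channel set.

    Parameters
    ----------
    series : ndarray, trials x channels x time
        Band-averaged power (or a burst-rate measure) on the epoch grid.
    window_ms : (lo, hi)
        Window relative to feedback onset, milliseconds.
    channel_set : iterable of channel labels, optional
        Defaults to all channels.
    """
    series = np.asarray(series, dtype=float)
    lo = feedback_s + window_ms[0] / 1000.0
    hi = feedback_s + window_ms[1] / 1000.0
    if lo < times[0] or hi > times[-1] + 1e-9:
        raise ValueError("feedback window extends past the epoch")
    tmask = (times >= lo) & (times <= hi)
    if channel_set is None:
        cidx = np.arange(series.shape[1])
    else:
        cidx = np.array([channels.index(c) for c in channel_set])
    return series[:, cidx, :][:, :, tmask].mean(axis=(1, 2))
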