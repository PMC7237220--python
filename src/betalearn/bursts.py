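"""Beta-band oscillation-burst detection and duration statistics.

Bursts are epochs where the band amplitude envelope exceeds a rest-derived
percentile threshold for at least one oscillation cycle.  Their duration
distribution, binned log-equidistantly between 50 and 2000 ms, follows a
power law whose absolute double-log slope is the life-time exponent tau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import filtfilt, firwin, hilbert

__all__ = [
    "BurstEvent",
    "BurstDistribution",
    "band_envelope",
    "threshold_from_rest",
    "detect_bursts",
    "duration_distribution",
    "burst_rate_timecourse",
    "BETA_BAND",
]

BETA_BAND = (13.0, 30.0)
DEFAULT_MIN_DUR_MS = 50.0
DEFAULT_MERGE_GAP_MS = 50.0
DURATION_RANGE_MS = (50.0, 2000.0)
N_DURATION_BINS = 20


@dataclass(frozen=True)
class BurstEvent:
    """Above-threshold envelope excursion, half-open [onset, offset)."""

    onset_s: float
    duration_ms: float
    peak_amplitude: float
    channel: str = "ch0"

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_ms / 1000.0


@dataclass(frozen=True)
class BurstDistribution:
    bin_edges: np.ndarray   # 21 log-spaced edges, ms
    counts: np.ndarray      # 20 bins
    probability: np.ndarray
    tau: float
    fit_bins: np.ndarray    # indices of bins used for the slope fit
    n_events: int


def band_envelope(
    signal, fs: float, band=BETA_BAND, numtaps: int | None = None
) -> np.ndarray:
    """Amplitude envelope of the band-passed signal (analytic magnitude).

    Zero-phase FIR band-pass (Hamming-window design) followed by the Hilbert
    transform magnitude.  Edge samples within one filter half-length are
    contaminated by the filter transient; callers excluding them should use
    ``edge_samples(fs, band)``.
    """
    signal = np.asarray(signal, dtype=float)
    low, high = band
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band {band} outside (0, Nyquist={fs / 2})")
    if numtaps is None:
        # ~3 cycles of the low edge; forced odd for a type-I filter
        numtaps = int(3 * fs / low) | 1
    taps = firwin(numtaps, [low, high], pass_zero=False, fs=fs)
    filtered = filtfilt(taps, [1.0], signal)
    return np.abs(hilbert(filtered))


def edge_samples(fs: float, band=BETA_BAND, numtaps: int | None = None) -> int:
    """Samples at each edge affected by the (zero-phase, two-pass) transient."""
    if numtaps is None:
        numtaps = int(3 * fs / band[0]) | 1
    return numtaps


def threshold_from_rest(rest_envelope, percentile: float = 75.0) -> float:
    """Burst threshold: the stated percentile of the rest-period envelope."""
    rest_envelope = np.asarray(rest_envelope, dtype=float)
    if rest_envelope.size == 0:
        raise ValueError("rest envelope is empty")
    return float(np.percentile(rest_envelope, percentile))


def detect_bursts(
    envelope,
    fs: float,
    threshold: float,
    min_dur_ms: float = DEFAULT_MIN_DUR_MS,
    merge_gap_ms: float = DEFAULT_MERGE_GAP_MS,
    channel: str = "ch0",
) -> list[BurstEvent]:
    """Above-threshold runs, merged across sub-cycle gaps.

    Runs separated by less than ``merge_gap_ms`` are treated as one burst;
    merged runs shorter than ``min_dur_ms`` (one cycle) are discarded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    envelope = np.asarray(envelope, dtype=float)
    above = envelope > threshold
    if not above.any():
        return []
    # run starts/ends in sample indices, half-open
    padded = np.diff(above.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)

    gap_samp = merge_gap_ms / 1000.0 * fs
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < gap_samp:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    min_samp = min_dur_ms / 1000.0 * fs
    events = []
    for s, e in merged:
        if e - s < min_samp:
            continue
        events.append(
            BurstEvent(
                onset_s=s / fs,
                duration_ms=(e - s) / fs * 1000.0,
                peak_amplitude=float(envelope[s:e].max()),
                channel=channel,
            )
        )
    return events


def duration_bin_edges(
    duration_range_ms=DURATION_RANGE_MS, n_bins: int = N_DURATION_BINS
) -> np.ndarray:
    lo, hi = duration_range_ms
    return np.logspace(math.log10(lo), math.log10(hi), n_bins + 1)


def duration_distribution(
    events,
    duration_range_ms=DURATION_RANGE_MS,
    n_bins: int = N_DURATION_BINS,
    exclude_first_bin: bool = True,
) -> BurstDistribution:
    """Log-binned burst-duration histogram and its life-time exponent.

    tau is the absolute slope of the least-squares line through
    (log bin-center, log probability) over non-empty bins, excluding the
    first bin.  Raises if fewer than 3 bins support the fit.
    """
    durations = np.asarray(
        [e.duration_ms if isinstance(e, BurstEvent) else float(e) for e in events]
    )
    if durations.size == 0:
        raise ValueError("no burst events")
    edges = duration_bin_edges(duration_range_ms, n_bins)
    counts, _ = np.histogram(durations, bins=edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("no events within the duration range")
    # probability density: log-spaced bin widths grow with duration, so raw
    # bin probabilities would flatten the slope by one unit of exponent
    widths = np.diff(edges)
    prob = counts / (total * widths)

    centers = np.sqrt(edges[:-1] * edges[1:])
    usable = counts > 0
    if exclude_first_bin:
        usable[0] = False
    fit_bins = np.flatnonzero(usable)
    if fit_bins.size < 3:
        raise ValueError(
            "insufficient support: fewer than 3 non-empty bins in fit range"
        )
    slope, _ = np.polyfit(np.log10(centers[fit_bins]), np.log10(prob[fit_bins]), 1)
    return BurstDistribution(
        bin_edges=edges,
        counts=counts,
        probability=prob,
        tau=float(abs(slope)),
        fit_bins=fit_bins,
        n_events=int(total),
    )


def burst_rate_timecourse(
    events_per_trial,
    t_start: float = -1.0,
    t_end: float = 11.0,
    bin_width_s: float = 0.1,
    duration_class: str | None = None,
    brief_max_ms: float = 300.0,
    long_min_ms: float = 500.0,
):
    """Across-trial burst-onset rate (bursts/s) on an epoch-relative grid.

    Parameters
    ----------
    events_per_trial : sequence of sequences of BurstEvent
        Events with onsets in epoch-relative seconds.
    duration_class : None | "brief" | "long"
        Restrict to bursts shorter than ``brief_max_ms`` or longer than
        ``long_min_ms``; bursts between the cutoffs belong to neither class.

    Returns
    -------
    (bin_centers_s, rate_per_s, n_dropped) where ``n_dropped`` counts events
    with onsets outside the epoch window.
    """
    edges = np.arange(t_start, t_end + bin_width_s / 2, bin_width_s)
    centers = (edges[:-1] + edges[1:]) / 2
    counts = np.zeros(centers.size)
    n_trials = len(events_per_trial)
    if n_trials == 0:
        raise ValueError("no trials")
    dropped = 0
    for events in events_per_trial:
        for ev in events:
            if duration_class == "brief" and ev.duration_ms >= brief_max_ms:
                continue
            if duration_class == "long" and ev.duration_ms <= long_min_ms:
                continue
            idx = np.searchsorted(edges, ev.onset_s, side="right") - 1
            if idx < 0 or idx >= counts.size:
                dropped += 1
                continue
            counts[idx] += 1
    rate = counts / (n_trials * bin_width_s)
    return centers, rate, dropped
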