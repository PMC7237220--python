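"""Trial performance representations and the reward mapping of the timing task.

A trial is a sequence of n keystrokes, represented by its n-1 inter-keystroke
intervals (IKIs, seconds).  The rewarded quantity is the Euclidean norm of the
vector of successive IKI differences; the trial score maps the distance
between the performed and target norms onto [0, 100].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrialPerformance",
    "PerformanceMeasures",
    "iki_differences",
    "performance_norm",
    "compute_score",
    "trial_measures",
    "delta_series",
    "across_trials_cv",
    "TARGET_NORM",
]

#: Target norm of the IKI-difference vector that yields the maximal score.
TARGET_NORM = 1.9596


@dataclass(frozen=True)
class TrialPerformance:
    """One trial's timing (and optional loudness) profile.

    Parameters
    ----------
    iki : array-like of float
        Inter-keystroke intervals in seconds, length >= 2, all positive.
    kvel : array-like of float, optional
        Keystroke velocities (a.u.), one per keystroke; not used by the
        reward mapping.
    """

    iki: np.ndarray
    kvel: np.ndarray | None = None

    def __post_init__(self):
        iki = np.asarray(self.iki, dtype=float)
        if iki.ndim != 1 or iki.size < 2:
            raise ValueError("iki must be a 1-d vector of length >= 2")
        if not np.all(iki > 0):
            raise ValueError("all inter-keystroke intervals must be positive")
        object.__setattr__(self, "iki", iki)
        if self.kvel is not None:
            object.__setattr__(self, "kvel", np.asarray(self.kvel, dtype=float))


@dataclass(frozen=True)
class PerformanceMeasures:
    """Scalar summaries of a single trial."""

    cv_iki_trial: float
    log_m_iki: float
    diff_norm: float
    score: float = field(default=np.nan)


def iki_differences(p: TrialPerformance) -> np.ndarray:
    """Vector of successive IKI differences (z2-z1, z3-z2, ...)."""
    return np.diff(p.iki)


def performance_norm(p: TrialPerformance) -> float:
    """Euclidean norm of the IKI-difference vector."""
    return float(np.linalg.norm(iki_differences(p)))


def compute_score(p: TrialPerformance, target_norm: float = TARGET_NORM) -> float:
    """Trial score in [0, 100]: 100*exp(-|target_norm - performed_norm|)."""
    if target_norm <= 0:
        raise ValueError("target_norm must be positive")
    return 100.0 * math.exp(-abs(target_norm - performance_norm(p)))


def trial_measures(
    p: TrialPerformance, target_norm: float = TARGET_NORM
) -> PerformanceMeasures:
    """Within-trial CV of IKIs, log mean tempo (ms), norm and score.

    The within-trial CV uses the population standard deviation (ddof=0).
    ``log_m_iki`` is the natural log of the mean IKI expressed in
    milliseconds.
    """
    iki = p.iki
    mean = float(np.mean(iki))
    cv = float(np.std(iki, ddof=0) / mean)
    norm = performance_norm(p)
    score = 100.0 * math.exp(-abs(target_norm - norm))
    return PerformanceMeasures(
        cv_iki_trial=cv,
        log_m_iki=math.log(mean * 1000.0),
        diff_norm=norm,
        score=score,
    )


def delta_series(values) -> np.ndarray:
    """First-difference series across trials.

    Element i holds value(i+1) - value(i); the change attributed to trial
    k (k >= 2) pairs with regressors from trial k-1.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two trials for a change series")
    return np.diff(values)


def across_trials_cv(
    trials: np.ndarray,
    bin_size: int = 25,
    aggregate: str = "mean",
    ddof: int = 1,
) -> np.ndarray:
    """Across-trials CV computed in consecutive trial bins.

    Parameters
    ----------
    trials : ndarray, shape (n_trials, n_positions)
        Per-trial vectors (IKIs or keystroke velocities), one row per trial.
    bin_size : int
        Trials per bin (task default 25).
    aggregate : {"mean", "median"}
        How per-position CVs are combined within a bin.
    ddof : int
        Delta degrees of freedom for the across-trial sd (sample sd by
        default).

    Returns
    -------
    ndarray of length n_trials // bin_size; an incomplete final bin is
    dropped with a warning.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 2:
        raise ValueError("trials must be 2-d (n_trials, n_positions)")
    n = trials.shape[0]
    n_bins, rem = divmod(n, bin_size)
    if n_bins == 0:
        raise ValueError(f"need at least {bin_size} trials for one bin")
    if rem:
        warnings.warn(
            f"dropping incomplete final bin of {rem} trials", stacklevel=2
        )
    agg = {"mean": np.mean, "median": np.median}[aggregate]
    out = np.empty(n_bins)
    for b in range(n_bins):
        chunk = trials[b * bin_size : (b + 1) * bin_size]
        cvs = np.std(chunk, axis=0, ddof=ddof) / np.mean(chunk, axis=0)
        out[b] = agg(cvs)
    return out
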