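"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators: belief-driven performing agents (IKI sequences whose
trial-to-trial variability follows the winning response model), band-limited
burst signals on 1/f background with power-law burst durations, and R-peak
trains with configurable heart-rate statistics.  Every generator is
deterministic given its seed and emits ground-truth annotations alongside
the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .hgf import HGFParams, hgf_filter
from .scoring import TARGET_NORM

__all__ = [
    "AgentConfig",
    "BurstSignalConfig",
    "AgentOutput",
    "GroupDataset",
    "gen_agent_performance",
    "gen_burst_signal",
    "gen_rpeaks",
    "gen_group_dataset",
    "alternating_iki_vector",
    "solve_deviation",
]


@dataclass(frozen=True)
class AgentConfig:
    """Generative parameters of a simulated performer."""

    omega1: float = -3.0
    omega2: float = -4.0
    pi_u: float = 20.0
    beta0: float = 0.0
    beta1: float = -0.1
    beta2: float = 0.05
    zeta: float = 1e-4          # response noise variance
    n_trials: int = 200
    seq_length: int = 7         # IKIs per trial
    base_tempo_ms: float = 500.0
    cv_init: float = 0.3        # within-trial CV on the first trial
    sigma1_0: float = 0.05      # initial level-1 belief variance
    sigma2_0: float = 0.01      # initial level-2 belief variance
    seed: int = 0

    def __post_init__(self):
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")
        if self.pi_u <= 0:
            raise ValueError("pi_u must be positive")
        if self.seq_length < 2:
            raise ValueError("seq_length must be at least 2")
        if self.n_trials < 1 or self.base_tempo_ms <= 0:
            raise ValueError("invalid trial count or tempo")


@dataclass(frozen=True)
class BurstSignalConfig:
    """Parameters of the synthetic oscillatory signal."""

    fs: float = 512.0
    duration_s: float = 60.0
    band: tuple = (13.0, 30.0)
    tau_true: float = 1.5
    burst_rate_per_s: float = 0.5
    burst_amplitude: float = 5.0
    noise_exponent: float = 1.0   # power ~ 1/f^exponent
    noise_amplitude: float = 1.0  # RMS of the background
    envelope: str = "hann"        # burst packet envelope: "hann" | "rect"
    duration_range_ms: tuple = (50.0, 2000.0)
    seed: int = 0

    def __post_init__(self):
        low, high = self.band
        if not (0 < low < high < self.fs / 2):
            raise ValueError("band must satisfy 0 < low < high < fs/2")
        if self.tau_true <= 1:
            raise ValueError("tau_true must exceed 1")
        if self.envelope not in ("hann", "rect"):
            raise ValueError("envelope must be 'hann' or 'rect'")


def solve_deviation(cv: float, base_s: float, n: int) -> float:
    """Deviation magnitude d realizing a within-trial CV via alternation.

    The IKI vector alternates base+d, base-d, ...; for odd n the surplus
    +d element shifts the mean, which the solution accounts for.
    """
    r = n % 2  # excess of +d elements
    s = math.sqrt(1.0 - r * r / (n * n))
    denom = s - cv * r / n
    if denom <= 0:
        raise ValueError("requested CV not realizable by alternation")
    return cv * base_s / denom


def alternating_iki_vector(cv: float, base_s: float, n: int) -> np.ndarray:
    """IKI vector (seconds) with the requested within-trial CV."""
    d = solve_deviation(cv, base_s, n)
    signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    return base_s + d * signs


@dataclass
class AgentOutput:
    performance: pd.DataFrame     # subject, group, trial, position, iki_ms, kvel
    scores: np.ndarray            # per-trial feedback score 0-100
    trajectories: dict            # ground-truth latents and response series
    config: AgentConfig


def gen_agent_performance(
    cfg: AgentConfig,
    target_norm: float = TARGET_NORM,
    subject: str = "s1",
    group: str = "g1",
) -> AgentOutput:
    """Closed generative loop of a belief-updating performer.

    Per trial: the current within-trial CV is realized as an alternating IKI
    vector, scored against the target norm, filtered through the agent's own
    HGF, and the next trial's CV change is drawn from
    Normal(beta0 + beta1*eps1 + beta2*eps2, zeta) using the previous trial's
    pwPEs.  Infeasible CV requests (IKI <= 0 or negative CV) are clipped and
    flagged.
    """
    if target_norm <= 0:
        raise ValueError("target_norm must be positive")
    rng = np.random.default_rng(cfg.seed)
    n, m_s = cfg.n_trials, cfg.base_tempo_ms / 1000.0
    L = cfg.seq_length

    # CV giving IKI floor at 5% of base tempo; used as the clip ceiling
    d_max = 0.95 * m_s
    r = L % 2
    s = math.sqrt(1.0 - r * r / (L * L))
    cv_max = d_max * s / (m_s + d_max * r / L)
    cv_min = 1e-4

    params = None
    cvs = np.empty(n)
    scores = np.empty(n)
    delta_cv = np.zeros(n)
    eps1 = np.zeros(n)
    eps2 = np.zeros(n)
    mu1 = np.zeros(n)
    mu2 = np.zeros(n)
    clipped = np.zeros(n, dtype=bool)
    iki_rows = np.empty((n, L))
    u_so_far: list[float] = []
    noise_sd = math.sqrt(cfg.zeta)

    cv = min(max(cfg.cv_init, cv_min), cv_max)
    traj = None
    for k in range(n):
        cvs[k] = cv
        iki = alternating_iki_vector(cv, m_s, L)
        iki_rows[k] = iki
        norm = float(np.linalg.norm(np.diff(iki)))
        scores[k] = 100.0 * math.exp(-abs(target_norm - norm))
        u_so_far.append(scores[k] / 100.0)
        if params is None:
            params = HGFParams(
                omega1=cfg.omega1,
                omega2=cfg.omega2,
                pi_u=cfg.pi_u,
                mu1_0=u_so_far[0],
                sigma1_0=cfg.sigma1_0,
                mu2_0=1.0,
                sigma2_0=cfg.sigma2_0,
            )
        traj = hgf_filter(params, np.asarray(u_so_far))
        eps1[k], eps2[k] = traj.eps1[k], traj.eps2[k]
        mu1[k], mu2[k] = traj.mu1[k], traj.mu2[k]
        if k < n - 1:
            step = (
                cfg.beta0
                + cfg.beta1 * eps1[k]
                + cfg.beta2 * eps2[k]
                + noise_sd * rng.standard_normal()
            )
            delta_cv[k + 1] = step
            nxt = cv + step
            if nxt < cv_min or nxt > cv_max:
                clipped[k + 1] = True
                nxt = min(max(nxt, cv_min), cv_max)
            cv = nxt

    kvel = 64.0 + 3.0 * rng.standard_normal((n, L))
    rows = []
    for k in range(n):
        for pos in range(L):
            rows.append(
                (subject, group, k + 1, pos + 1,
                 iki_rows[k, pos] * 1000.0, kvel[k, pos])
            )
    perf = pd.DataFrame(
        rows, columns=["subject", "group", "trial", "position", "iki_ms", "kvel"]
    )
    perf["score"] = np.repeat(scores, L)

    trajectories = {
        "cv_iki_trial": cvs,
        "delta_cv": delta_cv,
        "eps1": eps1,
        "eps2": eps2,
        "mu1": mu1,
        "mu2": mu2,
        "clipped": clipped,
        "belief_trajectory": traj,
    }
    return AgentOutput(perf, scores, trajectories, cfg)


def sample_burst_durations(
    rng, n: int, tau: float, duration_range_ms=(50.0, 2000.0)
) -> np.ndarray:
    """Durations (ms) from a truncated power law by inverse-CDF sampling."""
    a, b = duration_range_ms
    u = rng.random(n)
    e = 1.0 - tau
    return (a ** e + u * (b ** e - a ** e)) ** (1.0 / e)


def gen_burst_signal(cfg: BurstSignalConfig):
    """1/f background plus band-limited burst packets at Poisson onsets.

    Returns (signal, annotations).  Annotations carry the ground-truth
    events (onset_s, duration_ms, merged flag), the raw sampled durations,
    and the noiseless packet-envelope sum (``true_envelope``).
    """
    rng = np.random.default_rng(cfg.seed)
    n_samp = int(round(cfg.fs * cfg.duration_s))
    signal = _one_over_f_noise(rng, n_samp, cfg.fs, cfg.noise_exponent,
                               cfg.noise_amplitude)

    n_bursts = rng.poisson(cfg.burst_rate_per_s * cfg.duration_s)
    events = []
    durations = np.empty(0)
    true_env = np.zeros(n_samp)
    if n_bursts > 0:
        durations = sample_burst_durations(
            rng, n_bursts, cfg.tau_true, cfg.duration_range_ms
        )
        span = np.maximum(cfg.duration_s - durations / 1000.0, 0.0)
        onsets = rng.random(n_bursts) * span
        order = np.argsort(onsets)
        onsets, durations = onsets[order], durations[order]
        freqs = rng.uniform(cfg.band[0], cfg.band[1], n_bursts)
        phases = rng.uniform(0, 2 * math.pi, n_bursts)
        for onset, dur_ms, f, ph in zip(onsets, durations, freqs, phases):
            i0 = int(round(onset * cfg.fs))
            n_dur = max(2, int(round(dur_ms / 1000.0 * cfg.fs)))
            i1 = min(i0 + n_dur, n_samp)
            t = np.arange(i1 - i0) / cfg.fs
            if cfg.envelope == "hann":
                env = np.hanning(n_dur)[: i1 - i0]
            else:
                env = np.ones(i1 - i0)
            packet = cfg.burst_amplitude * env * np.cos(2 * math.pi * f * t + ph)
            signal[i0:i1] += packet
            true_env[i0:i1] = np.maximum(true_env[i0:i1], cfg.burst_amplitude * env)
            events.append(
                {"onset_s": i0 / cfg.fs, "duration_ms": (i1 - i0) / cfg.fs * 1000.0,
                 "merged": False}
            )
        events = _merge_overlaps(events)
    annotations = {
        "events": events,
        "durations_ms": durations,
        "true_envelope": true_env,
        "config": cfg,
    }
    return signal, annotations


def _merge_overlaps(events):
    merged = []
    for ev in events:
        if merged and ev["onset_s"] < (
            merged[-1]["onset_s"] + merged[-1]["duration_ms"] / 1000.0
        ):
            prev = merged[-1]
            new_end = max(
                prev["onset_s"] + prev["duration_ms"] / 1000.0,
                ev["onset_s"] + ev["duration_ms"] / 1000.0,
            )
            prev["duration_ms"] = (new_end - prev["onset_s"]) * 1000.0
            prev["merged"] = True
        else:
            merged.append(dict(ev))
    return merged


def _one_over_f_noise(rng, n: int, fs: float, exponent: float, rms: float):
    """Spectrally shaped Gaussian noise with power ~ 1/f^exponent."""
    if rms == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    noise = np.fft.irfft(spec * shape, n=n)
    sd = noise.std()
    if sd > 0:
        noise *= rms / sd
    return noise


def gen_rpeaks(
    mean_hr_bpm: float, ibi_cv: float, duration_s: float, seed: int = 0
) -> np.ndarray:
    """R-peak times from Gaussian inter-beat intervals.

    Non-positive sampled intervals are redrawn (with a warning), so the
    resulting train is strictly increasing.
    """
    if mean_hr_bpm <= 0:
        raise ValueError("mean_hr_bpm must be positive")
    if ibi_cv < 0:
        raise ValueError("ibi_cv must be non-negative")
    rng = np.random.default_rng(seed)
    mean_ibi = 60.0 / mean_hr_bpm
    sd = ibi_cv * mean_ibi
    times = []
    t = 0.0
    resampled = 0
    while t < duration_s:
        ibi = mean_ibi + sd * rng.standard_normal() if sd > 0 else mean_ibi
        while ibi <= 0:
            resampled += 1
            ibi = mean_ibi + sd * rng.standard_normal()
        t += ibi
        if t < duration_s:
            times.append(t)
    if resampled:
        import warnings

        warnings.warn(
            f"resampled {resampled} non-positive inter-beat intervals",
            stacklevel=2,
        )
    return np.asarray(times)


@dataclass
class GroupDataset:
    """Multi-subject container with stored ground truth."""

    performances: pd.DataFrame
    scores: dict               # subject -> score series
    signals: dict              # subject -> (signal, annotations)
    rpeaks: dict               # subject -> R-peak times
    group_of: dict             # subject -> group label
    ground_truth: dict         # subject -> agent trajectories + configs
    seed: int = 0

    @property
    def subjects(self):
        return tuple(self.group_of)

    def subjects_in(self, group):
        return tuple(s for s, g in self.group_of.items() if g == group)


def gen_group_dataset(
    group_configs: dict,
    n_subjects: int,
    seed: int = 0,
    target_norm: float = TARGET_NORM,
    with_signals: bool = True,
    hr_bpm: float = 70.0,
    hr_ibi_cv: float = 0.05,
) -> GroupDataset:
    """Generate a multi-group dataset with injected group differences.

    ``group_configs`` maps group label -> dict with optional keys ``agent``
    (AgentConfig) and ``burst`` (BurstSignalConfig); group differences are
    injected by shifting those configs between groups.
    """
    if len(group_configs) < 2:
        raise ValueError("need at least 2 groups")
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects per group")
    seq = np.random.SeedSequence(seed)
    perf_frames, scores, signals, rpeaks, group_of, truth = (
        [], {}, {}, {}, {}, {}
    )
    for g_idx, (group, cfgs) in enumerate(sorted(group_configs.items())):
        agent_cfg = cfgs.get("agent", AgentConfig())
        burst_cfg = cfgs.get("burst", BurstSignalConfig())
        for s_idx in range(n_subjects):
            sid = f"{group}_s{s_idx + 1:02d}"
            child = np.random.SeedSequence(
                entropy=seed, spawn_key=(g_idx, s_idx)
            )
            s_seed = int(child.generate_state(1)[0])
            out = gen_agent_performance(
                replace(agent_cfg, seed=s_seed),
                target_norm=target_norm,
                subject=sid,
                group=group,
            )
            perf_frames.append(out.performance)
            scores[sid] = out.scores
            truth[sid] = {
                "trajectories": out.trajectories,
                "agent_config": out.config,
                "burst_config": burst_cfg,
            }
            group_of[sid] = group
            if with_signals:
                sig, ann = gen_burst_signal(replace(burst_cfg, seed=s_seed + 1))
                signals[sid] = (sig, ann)
            rpeaks[sid] = gen_rpeaks(hr_bpm, hr_ibi_cv, 60.0, seed=s_seed + 2)
    return GroupDataset(
        performances=pd.concat(perf_frames, ignore_index=True),
        scores=scores,
        signals=signals,
        rpeaks=rpeaks,
        group_of=group_of,
        ground_truth=truth,
        seed=seed,
    )
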