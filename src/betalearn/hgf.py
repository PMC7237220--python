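"""Two-level Hierarchical Gaussian Filter for continuous inputs.

The filter tracks beliefs about a hidden reward tendency (level 1) and its
log-volatility (level 2) from a series of inputs in [0, 1].  Both levels
evolve as coupled Gaussian random walks; the step variance of level 1 is
exp(kappa * x2 + omega1) and that of level 2 is exp(omega2).  Posterior
means update by precision-weighted prediction errors (pwPEs): the change in
the expectation at a level equals the pwPE at that level, exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "HGFParams",
    "BeliefTrajectory",
    "NegativePrecisionError",
    "normalize_scores",
    "default_priors",
    "hgf_filter",
    "unpack_pwpe",
]


class NegativePrecisionError(RuntimeError):
    """A precision went non-positive during filtering.

    Raised with the offending trial index; used by the fitting routines to
    reject invalid parameter proposals.
    """

    def __init__(self, trial: int, name: str, params: "HGFParams"):
        self.trial = trial
        self.name = name
        self.params = params
        super().__init__(
            f"non-positive precision {name} at trial {trial} "
            f"(omega1={params.omega1:.4g}, omega2={params.omega2:.4g}, "
            f"pi_u={params.pi_u:.4g})"
        )


@dataclass(frozen=True)
class HGFParams:
    """Perceptual-model parameters and initial values.

    kappa is fixed at 1, the drift rho at 0 and the trial step at 1 unless
    explicitly overridden.  ``pi_u`` is the (constant) precision of the
    input; its log carries a Gaussian prior during fitting.
    """

    omega1: float
    omega2: float
    pi_u: float
    mu1_0: float
    sigma1_0: float
    mu2_0: float = 1.0
    sigma2_0: float = 0.01
    kappa: float = 1.0
    rho: float = 0.0
    t_step: float = 1.0

    def __post_init__(self):
        if self.pi_u <= 0:
            raise ValueError("pi_u must be positive")
        if self.sigma1_0 <= 0 or self.sigma2_0 <= 0:
            raise ValueError("initial variances must be positive")

    @property
    def theta(self) -> float:
        """Top-level step variance exp(omega2)."""
        return math.exp(self.omega2)


@dataclass(frozen=True)
class BeliefTrajectory:
    """Per-trial belief series produced by :func:`hgf_filter`.

    All arrays have length n_trials; predictions (``*_hat``) refer to the
    state before the trial's input is seen.
    """

    u: np.ndarray
    mu1_hat: np.ndarray
    mu1: np.ndarray
    pi1_hat: np.ndarray
    pi1: np.ndarray
    mu2_hat: np.ndarray
    mu2: np.ndarray
    pi2_hat: np.ndarray
    pi2: np.ndarray
    delta_u: np.ndarray
    delta1: np.ndarray
    eps1: np.ndarray
    eps2: np.ndarray
    w1: np.ndarray
    params: HGFParams

    @property
    def sigma1(self) -> np.ndarray:
        return 1.0 / self.pi1

    @property
    def sigma2(self) -> np.ndarray:
        return 1.0 / self.pi2

    @property
    def n_trials(self) -> int:
        return len(self.u)


def normalize_scores(scores) -> np.ndarray:
    """Map feedback scores 0-100 onto filter inputs in [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    if np.any(scores < 0) or np.any(scores > 100):
        raise ValueError("scores must lie in [0, 100]")
    return scores / 100.0


def default_priors(u, n_init: int = 20) -> dict:
    """Input-dependent prior means/variances for all parameters.

    The first ``n_init`` inputs seed the priors: the prior means of omega1
    and log(sigma1_0) equal the log-variance of those inputs, the prior mean
    of log(pi_u) its negative, and mu1_0 is centred on the first input with
    the inputs' variance as prior variance.  Fixed quantities (kappa, mu2_0)
    carry zero prior variance.

    Returns a dict mapping parameter name to (prior_mean, prior_variance),
    with log-space parameters keyed as ``log_*``.
    """
    u = np.asarray(u, dtype=float)
    if u.size < n_init:
        raise ValueError(f"need at least {n_init} inputs to build priors")
    head = u[:n_init]
    var = float(np.var(head, ddof=0))
    if var <= 0:
        raise ValueError(
            "degenerate input series: first inputs have zero variance"
        )
    logvar = math.log(var)
    return {
        "log_kappa": (0.0, 0.0),
        "omega1": (logvar, 16.0),
        "omega2": (-4.0, 16.0),
        "log_pi_u": (-logvar, 4.0),
        "mu1_0": (float(head[0]), var),
        "log_sigma1_0": (logvar, 1.0),
        "mu2_0": (1.0, 0.0),
        "log_sigma2_0": (math.log(0.01), 1.0),
    }


def params_from_priors(priors: dict, **overrides) -> HGFParams:
    """Build an :class:`HGFParams` at the prior means, with overrides."""
    base = dict(
        omega1=priors["omega1"][0],
        omega2=priors["omega2"][0],
        pi_u=math.exp(priors["log_pi_u"][0]),
        mu1_0=priors["mu1_0"][0],
        sigma1_0=math.exp(priors["log_sigma1_0"][0]),
        mu2_0=priors["mu2_0"][0],
        sigma2_0=math.exp(priors["log_sigma2_0"][0]),
    )
    base.update(overrides)
    return HGFParams(**base)


def hgf_filter(params: HGFParams, u) -> BeliefTrajectory:
    """Run the two-level continuous-input filter over an input series.

    Per trial k (predictions seeded from the previous posterior):

    - level-1 prediction precision: 1 / (sigma1 + exp(kappa*mu2 + omega1))
    - input PE: delta_u = u - mu1_hat; posterior pi1 = pi1_hat + pi_u
    - mu1 = mu1_hat + (pi_u / pi1) * delta_u
    - volatility PE entering level 2 (variance-normalized):
      delta1 = (sigma1 + eps1^2) * pi1_hat_raw - 1, with pi1_hat_raw the
      reciprocal of the predicted level-1 variance
    - level-2 weight: w1 = exp(kappa*mu2 + omega1) * pi1_hat
    - pi2_hat = 1 / (sigma2 + exp(omega2));
      pi2 = pi2_hat + 0.5 * w1 * (w1 + (2*w1 - 1) * delta1)
    - mu2 = mu2_hat + 0.5 * (1 / pi2) * w1 * delta1

    Raises :class:`NegativePrecisionError` if any precision is non-positive.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("inputs must be finite")
    n = u.size
    ka, om1, om2 = params.kappa, params.omega1, params.omega2
    pi_u = params.pi_u
    t = params.t_step

    mu1_prev = params.mu1_0
    sg1_prev = params.sigma1_0
    mu2_prev = params.mu2_0
    sg2_prev = params.sigma2_0
    theta = math.exp(om2)

    out = {k: np.empty(n) for k in (
        "mu1_hat", "mu1", "pi1_hat", "pi1", "mu2_hat", "mu2",
        "pi2_hat", "pi2", "delta_u", "delta1", "eps1", "eps2", "w1",
    )}

    for k in range(n):
        # level 1
        v1 = t * math.exp(ka * mu2_prev + om1)        # predicted step variance
        sg1_hat = sg1_prev + v1
        if sg1_hat <= 0:
            raise NegativePrecisionError(k, "pi1_hat", params)
        pi1_hat = 1.0 / sg1_hat
        mu1_hat = mu1_prev + t * params.rho
        du = u[k] - mu1_hat
        pi1 = pi1_hat + pi_u
        if pi1 <= 0:
            raise NegativePrecisionError(k, "pi1", params)
        eps1 = (pi_u / pi1) * du
        mu1 = mu1_hat + eps1
        sg1 = 1.0 / pi1

        # volatility prediction error feeding level 2
        d1 = (sg1 + eps1 * eps1) / sg1_hat - 1.0
        w1 = v1 * pi1_hat

        # level 2
        sg2_hat = sg2_prev + t * theta
        if sg2_hat <= 0:
            raise NegativePrecisionError(k, "pi2_hat", params)
        pi2_hat = 1.0 / sg2_hat
        mu2_hat = mu2_prev
        pi2 = pi2_hat + 0.5 * w1 * (w1 + (2.0 * w1 - 1.0) * d1)
        if pi2 <= 0:
            raise NegativePrecisionError(k, "pi2", params)
        eps2 = 0.5 * (1.0 / pi2) * w1 * d1
        mu2 = mu2_hat + eps2

        out["mu1_hat"][k] = mu1_hat
        out["mu1"][k] = mu1
        out["pi1_hat"][k] = pi1_hat
        out["pi1"][k] = pi1
        out["mu2_hat"][k] = mu2_hat
        out["mu2"][k] = mu2
        out["pi2_hat"][k] = pi2_hat
        out["pi2"][k] = pi2
        out["delta_u"][k] = du
        out["delta1"][k] = d1
        out["eps1"][k] = eps1
        out["eps2"][k] = eps2
        out["w1"][k] = w1

        mu1_prev, sg1_prev = mu1, sg1
        mu2_prev, sg2_prev = mu2, 1.0 / pi2

    return BeliefTrajectory(u=u, params=params, **out)


def unpack_pwpe(traj: BeliefTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Return (eps1, eps2): the per-trial pwPE series at both levels."""
    return traj.eps1, traj.eps2


def trajectory_frame(traj: BeliefTrajectory):
    """Tidy long-format DataFrame (trial, quantity, value)."""
    import pandas as pd

    quantities = {
        "u": traj.u, "mu1_hat": traj.mu1_hat, "mu1": traj.mu1,
        "sigma1": traj.sigma1, "pi1": traj.pi1, "pi1_hat": traj.pi1_hat,
        "mu2_hat": traj.mu2_hat, "mu2": traj.mu2, "sigma2": traj.sigma2,
        "pi2": traj.pi2, "pi2_hat": traj.pi2_hat,
        "delta_u": traj.delta_u, "delta1": traj.delta1,
        "eps1": traj.eps1, "eps2": traj.eps2, "w1": traj.w1,
    }
    rows = []
    for name, series in quantities.items():
        for k, v in enumerate(series):
            rows.append((k + 1, name, v))
    return pd.DataFrame(rows, columns=["trial", "quantity", "value"])
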