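"""Linear response models linking belief trajectories to performance changes.

Eight models arise from two response families (change in within-trial IKI
variability vs. change in log mean tempo) crossed with four predictor pairs
drawn from the previous trial's belief quantities.  Fitting is joint MAP
over perceptual and response parameters with Gaussian priors in estimation
space; the log model evidence is a Laplace approximation around the MAP.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .hgf import (
    BeliefTrajectory,
    HGFParams,
    NegativePrecisionError,
    default_priors,
    hgf_filter,
)

__all__ = [
    "ResponseModelSpec",
    "FittedModel",
    "enumerate_models",
    "predicted_response",
    "log_likelihood",
    "fit_model",
    "residual_diagnostics",
]

CV_FAMILY = "cv_family"
TEMPO_FAMILY = "tempo_family"

#: Predictor pairs for models 1-4 within each family.
PREDICTOR_SETS = (
    ("mu1", "eps1"),
    ("mu1", "mu2"),
    ("mu2", "eps2"),
    ("eps1", "eps2"),
)


@dataclass(frozen=True)
class ResponseModelSpec:
    family: str
    predictors: tuple[str, str]
    response_definition: str

    @property
    def name(self) -> str:
        idx = PREDICTOR_SETS.index(self.predictors) + 1
        fam = 1 if self.family == CV_FAMILY else 2
        return f"HGF{fam}{idx}"


def enumerate_models() -> list[ResponseModelSpec]:
    """All eight response-model specifications."""
    specs = []
    for family, response in (
        (CV_FAMILY, "delta_cv_iki_trial"),
        (TEMPO_FAMILY, "delta_log_m_iki"),
    ):
        for pred in PREDICTOR_SETS:
            specs.append(ResponseModelSpec(family, pred, response))
    return specs


def winning_spec() -> ResponseModelSpec:
    """The model explaining delta-cvIKI by previous-trial pwPEs."""
    return ResponseModelSpec(CV_FAMILY, ("eps1", "eps2"), "delta_cv_iki_trial")


def _predictor_series(traj: BeliefTrajectory, name: str) -> np.ndarray:
    return getattr(traj, name)


def predicted_response(
    spec: ResponseModelSpec, traj: BeliefTrajectory, betas
) -> np.ndarray:
    """Model prediction for trials 2..n from previous-trial quantities.

    betas = (beta0, beta1, beta2).  Returns a series of length n-1 aligned
    with the response at trials 2..n.
    """
    b0, b1, b2 = betas
    q1 = _predictor_series(traj, spec.predictors[0])[:-1]
    q2 = _predictor_series(traj, spec.predictors[1])[:-1]
    return b0 + b1 * q1 + b2 * q2


def log_likelihood(y, y_hat, zeta: float) -> float:
    """Sum of Normal log-densities of y around y_hat with variance zeta."""
    if zeta <= 0:
        raise ValueError("zeta (noise variance) must be positive")
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("response and prediction lengths differ")
    resid = y - y_hat
    n = y.size
    return float(
        -0.5 * n * math.log(2.0 * math.pi * zeta)
        - 0.5 * np.dot(resid, resid) / zeta
    )


@dataclass
class FittedModel:
    spec: ResponseModelSpec
    map_params: dict
    lme: float
    residuals: np.ndarray
    traj: BeliefTrajectory
    converged: bool
    log_joint: float
    n_trials: int
    priors: dict = field(repr=False, default_factory=dict)


# free parameter order in the optimizer vector
_FREE = ("omega1", "omega2", "log_pi_u", "beta0", "beta1", "beta2", "log_zeta")


def _build_priors(u, y, perceptual_priors=None) -> dict:
    priors = dict(perceptual_priors or default_priors(u))
    y = np.asarray(y, dtype=float)
    priors.setdefault("beta0", (float(np.mean(y)), 4.0))
    priors.setdefault("beta1", (0.0, 4.0))
    priors.setdefault("beta2", (0.0, 4.0))
    # noise variance prior centred on the observed response variance
    vy = max(float(np.var(y, ddof=0)), 1e-12)
    priors.setdefault("log_zeta", (math.log(vy), 4.0))
    return priors


def _log_joint(theta, u, y, spec, priors):
    om1, om2, log_pi_u, b0, b1, b2, log_zeta = theta
    if not np.all(np.isfinite(theta)):
        return -np.inf
    if abs(log_pi_u) > 50 or abs(log_zeta) > 50 or abs(om2) > 50:
        return -np.inf
    params = HGFParams(
        omega1=om1,
        omega2=om2,
        pi_u=math.exp(log_pi_u),
        mu1_0=priors["mu1_0"][0],
        sigma1_0=math.exp(priors["log_sigma1_0"][0]),
        mu2_0=priors["mu2_0"][0],
        sigma2_0=math.exp(priors["log_sigma2_0"][0]),
    )
    try:
        traj = hgf_filter(params, u)
    except (NegativePrecisionError, OverflowError):
        return -np.inf
    y_hat = predicted_response(spec, traj, (b0, b1, b2))
    try:
        ll = log_likelihood(y, y_hat, math.exp(log_zeta))
    except OverflowError:
        return -np.inf
    lp = 0.0
    for name, value in zip(_FREE, theta):
        mean, var = priors[name]
        if var > 0:
            lp += -0.5 * math.log(2.0 * math.pi * var) - 0.5 * (value - mean) ** 2 / var
    total = ll + lp
    return total if np.isfinite(total) else -np.inf


def fit_model(
    u,
    y,
    spec: ResponseModelSpec,
    priors: dict | None = None,
    n_starts: int = 8,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 4000,
) -> FittedModel:
    """Joint MAP fit of perceptual + response parameters.

    Parameters
    ----------
    u : array-like
        Normalized input series (one per trial, length n).
    y : array-like
        Response series for trials 2..n (length n-1): the first trial has no
        defined change and is excluded from the likelihood.
    spec : ResponseModelSpec
    priors : dict, optional
        Mapping name -> (prior mean, prior variance); defaults derived from
        the inputs and responses.
    n_starts : int
        Multi-start count for the simplex optimizer (first start at the
        prior means, remainder drawn from down-scaled priors).
    """
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size != u.size - 1:
        raise ValueError("y must have length len(u) - 1")
    if u.size < 30:
        warnings.warn("fewer than 30 trials: fit may be unstable", stacklevel=2)
    priors = _build_priors(u, y, priors)

    rng = np.random.default_rng(seed)
    theta0 = np.array([priors[name][0] for name in _FREE])
    scales = np.array([math.sqrt(max(priors[name][1], 1e-6)) for name in _FREE])

    # moment-matched start: OLS betas on the trajectory at prior-mean
    # perceptual parameters, noise from the residual variance
    starts = [theta0]
    ols = _ols_start(theta0, u, y, spec, priors)
    if ols is not None:
        starts.insert(0, ols)

    def neg(theta):
        return -_log_joint(theta, u, y, spec, priors)

    best = None
    for s in range(n_starts):
        if s < len(starts):
            start = starts[s]
        else:
            start = theta0 + 0.25 * scales * rng.standard_normal(7)
        if not np.isfinite(neg(start)):
            continue
        res = minimize(
            neg,
            start,
            method="Nelder-Mead",
            options={"xatol": tol, "fatol": tol, "maxiter": max_iter},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("no valid parameter region found for this model/data")

    theta = best.x
    lj = -best.fun
    map_params = dict(zip(_FREE, theta))
    params = HGFParams(
        omega1=theta[0],
        omega2=theta[1],
        pi_u=math.exp(theta[2]),
        mu1_0=priors["mu1_0"][0],
        sigma1_0=math.exp(priors["log_sigma1_0"][0]),
        mu2_0=priors["mu2_0"][0],
        sigma2_0=math.exp(priors["log_sigma2_0"][0]),
    )
    traj = hgf_filter(params, u)
    y_hat = predicted_response(spec, traj, theta[3:6])
    residuals = y - y_hat

    lme = _laplace_lme(theta, lj, u, y, spec, priors)
    return FittedModel(
        spec=spec,
        map_params=map_params,
        lme=lme,
        residuals=residuals,
        traj=traj,
        converged=bool(best.success),
        log_joint=lj,
        n_trials=y.size,
        priors=priors,
    )


def _ols_start(theta0, u, y, spec, priors):
    """Initial point with betas/zeta from OLS at prior-mean perceptual params."""
    params = HGFParams(
        omega1=theta0[0],
        omega2=theta0[1],
        pi_u=math.exp(theta0[2]),
        mu1_0=priors["mu1_0"][0],
        sigma1_0=math.exp(priors["log_sigma1_0"][0]),
        mu2_0=priors["mu2_0"][0],
        sigma2_0=math.exp(priors["log_sigma2_0"][0]),
    )
    try:
        traj = hgf_filter(params, u)
    except NegativePrecisionError:
        return None
    q1 = _predictor_series(traj, spec.predictors[0])[:-1]
    q2 = _predictor_series(traj, spec.predictors[1])[:-1]
    X = np.column_stack([np.ones_like(q1), q1, q2])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3 or not np.all(np.isfinite(coef)):
        return None
    resid = y - X @ coef
    var = max(float(np.var(resid, ddof=0)), 1e-12)
    start = np.array(theta0, dtype=float)
    start[3:6] = coef
    start[6] = math.log(var)
    return start


def _laplace_lme(theta, log_joint, u, y, spec, priors, h: float = 1e-4) -> float:
    """Laplace approximation: log_joint + d/2 log(2 pi) - 1/2 log det(H).

    H is the finite-difference Hessian of the negative log joint at the MAP.
    A non-positive-definite Hessian (flat or saddle directions) falls back to
    regularizing the diagonal.
    """
    d = len(theta)
    hess = np.empty((d, d))
    f0 = -_log_joint(theta, u, y, spec, priors)
    steps = h * np.maximum(1.0, np.abs(theta))

    def f(t):
        v = -_log_joint(t, u, y, spec, priors)
        return v if np.isfinite(v) else f0 + 1e6

    for i in range(d):
        ei = np.zeros(d)
        ei[i] = steps[i]
        for j in range(i, d):
            ej = np.zeros(d)
            ej[j] = steps[j]
            if i == j:
                fij = (f(theta + ei) - 2 * f0 + f(theta - ei)) / steps[i] ** 2
            else:
                fij = (
                    f(theta + ei + ej)
                    - f(theta + ei - ej)
                    - f(theta - ei + ej)
                    + f(theta - ei - ej)
                ) / (4 * steps[i] * steps[j])
            hess[i, j] = hess[j, i] = fij

    sign, logdet = np.linalg.slogdet(hess)
    if sign <= 0 or not np.isfinite(logdet):
        hess = hess + np.eye(d) * (1e-6 + abs(np.min(np.linalg.eigvalsh(hess))))
        sign, logdet = np.linalg.slogdet(hess)
        if sign <= 0:
            return float(log_joint)  # degenerate curvature: fall back to joint
    return float(log_joint + 0.5 * d * math.log(2.0 * math.pi) - 0.5 * logdet)


def residual_diagnostics(fm: FittedModel) -> dict:
    """Trial-averaged residual, its SEM, and the lag-1 autocorrelation."""
    r = np.asarray(fm.residuals, dtype=float)
    n = r.size
    mean = float(np.mean(r))
    sem = float(np.std(r, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    if n > 2 and np.std(r) > 0:
        rc = np.corrcoef(r[:-1], r[1:])[0, 1]
    else:
        rc = float("nan")
    return {"mean_residual": mean, "sem": sem, "lag1_autocorr": float(rc)}
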