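"""Trial-wise regression of feedback-locked beta measures on pwPEs.

Per subject, the feedback-locked measure (power or burst rate) is explained
as a linear function of an intercept and the two precision-weighted
prediction errors from the same trial; coefficients feed the group-level
nonparametric tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LinkRegressionResult",
    "check_regressor_independence",
    "fit_link_regression",
]


@dataclass(frozen=True)
class LinkRegressionResult:
    beta0: float
    beta1: float
    beta2: float
    stderr: tuple  # (se0, se1, se2)
    n_trials: int
    regressor_correlation: float

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2])

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Per-coefficient t confidence intervals, rows (lo, hi)."""
        df = self.n_trials - 3
        tcrit = stats.t.ppf(0.5 + level / 2, df)
        c = self.coefficients
        se = np.asarray(self.stderr)
        return np.column_stack([c - tcrit * se, c + tcrit * se])


def check_regressor_independence(
    eps1, eps2, flag_threshold: float = 0.7
) -> tuple[float, float, bool]:
    """Pearson correlation between the two pwPE regressors.

    Returns (r, p, flagged); flagged when |r| exceeds the collinearity
    threshold.
    """
    eps1 = np.asarray(eps1, dtype=float)
    eps2 = np.asarray(eps2, dtype=float)
    if eps1.shape != eps2.shape:
        raise ValueError("regressors must have equal length")
    if np.std(eps1) == 0 or np.std(eps2) == 0:
        raise ValueError("constant regressor")
    r, p = stats.pearsonr(eps1, eps2)
    return float(r), float(p), bool(abs(r) >= flag_threshold)


def fit_link_regression(y, eps1, eps2) -> LinkRegressionResult:
    """OLS of the per-trial measure on [1, eps1, eps2]."""
    y = np.asarray(y, dtype=float)
    eps1 = np.asarray(eps1, dtype=float)
    eps2 = np.asarray(eps2, dtype=float)
    if not (y.shape == eps1.shape == eps2.shape):
        raise ValueError("misaligned trial series")
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 trials for a reported fit")
    X = np.column_stack([np.ones(n), eps1, eps2])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design (collinear regressors)")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = resid @ resid / (n - 3)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    if np.std(eps1) > 0 and np.std(eps2) > 0:
        r = float(stats.pearsonr(eps1, eps2)[0])
    else:
        r = float("nan")
    return LinkRegressionResult(
        beta0=float(coef[0]),
        beta1=float(coef[1]),
        beta2=float(coef[2]),
        stderr=tuple(se),
        n_trials=n,
        regressor_correlation=r,
    )
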