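"""Random-effects Bayesian model selection over per-subject log evidences.

Family-level evidence aggregates member-model evidences under a uniform
within-family prior; the random-effects step fits a Dirichlet over model
frequencies by variational updates and reports expected frequencies and
exceedance probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, logsumexp

__all__ = ["EvidenceMatrix", "BmsResult", "family_log_evidence", "rfx_bms"]


@dataclass(frozen=True)
class EvidenceMatrix:
    """Subjects x models log-evidence matrix with labels and family map."""

    lme: np.ndarray
    model_labels: tuple
    family_partition: dict  # model label -> family label

    def __post_init__(self):
        lme = np.asarray(self.lme, dtype=float)
        if lme.ndim != 2:
            raise ValueError("lme must be 2-d (subjects x models)")
        if lme.shape[1] != len(self.model_labels):
            raise ValueError("label count does not match lme columns")
        if not np.all(np.isfinite(lme)):
            raise ValueError("missing or non-finite log evidences")
        missing = [m for m in self.model_labels if m not in self.family_partition]
        if missing:
            raise ValueError(f"models without a family: {missing}")
        object.__setattr__(self, "lme", lme)


@dataclass(frozen=True)
class BmsResult:
    dirichlet_alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance_probabilities: np.ndarray
    labels: tuple
    n_iterations: int


def family_log_evidence(em: EvidenceMatrix):
    """Per-subject log family evidence under a uniform within-family prior.

    LFE = logsumexp(member LMEs) - log(n_members), per subject and family.

    Returns (lfe matrix subjects x families, family labels).
    """
    families = sorted(set(em.family_partition.values()))
    cols = {
        fam: [i for i, m in enumerate(em.model_labels)
              if em.family_partition[m] == fam]
        for fam in families
    }
    for fam, idx in cols.items():
        if not idx:
            raise ValueError(f"empty family: {fam}")
    out = np.empty((em.lme.shape[0], len(families)))
    for j, fam in enumerate(families):
        idx = cols[fam]
        out[:, j] = logsumexp(em.lme[:, idx], axis=1) - np.log(len(idx))
    return out, tuple(families)


def rfx_bms(
    lme,
    labels=None,
    alpha0: float = 1.0,
    n_samples: int = 1_000_000,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> BmsResult:
    """Random-effects BMS by variational Dirichlet updates.

    Iterates posterior model assignments g_nk proportional to
    exp(lme_nk + digamma(alpha_k) - digamma(sum alpha)), then
    alpha = alpha0 + sum_n g_nk, to convergence.  Exceedance probabilities
    are Monte-Carlo estimates from the posterior Dirichlet.
    """
    lme = np.asarray(lme, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 2 or lme.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 models")
    n_sub, n_mod = lme.shape
    if labels is None:
        labels = tuple(f"m{k + 1}" for k in range(n_mod))

    alpha = np.full(n_mod, float(alpha0))
    for it in range(max_iter):
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    else:
        raise RuntimeError(
            f"BMS did not converge after {max_iter} iterations "
            f"(last alpha={alpha})"
        )

    expected = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=n_mod) / n_samples
    return BmsResult(
        dirichlet_alpha=alpha,
        expected_frequencies=expected,
        exceedance_probabilities=xp,
        labels=tuple(labels),
        n_iterations=it + 1,
    )
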