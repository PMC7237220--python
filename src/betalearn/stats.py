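"""Nonparametric inference used throughout the pipeline.

Permutation tests (label shuffling / sign flipping), the two-stage adaptive
FDR step-up, probability-of-superiority effect sizes with bootstrap CIs,
rank correlation, heart-rate-variability summaries, and the pointwise
time-course test that produces significance masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PermTestResult",
    "EffectSize",
    "permutation_test",
    "fdr_adaptive",
    "effect_size_delta",
    "spearman_rho",
    "hrv_metrics",
    "pointwise_timecourse_test",
]


@dataclass(frozen=True)
class PermTestResult:
    statistic: float
    p: float
    n_permutations: int
    paired: bool
    seed: int | None
    exact: bool = False


@dataclass(frozen=True)
class EffectSize:
    delta: float
    kind: str  # "independent" or "dependent"
    ci95: tuple
    n_ties: int


def _mean_diff(a, b):
    return float(np.mean(a) - np.mean(b))


def _t_stat(a, b):
    na, nb = len(a), len(b)
    sp = math.sqrt(
        ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1))
        / (na + nb - 2)
    )
    if sp == 0:
        return 0.0
    return _mean_diff(a, b) / (sp * math.sqrt(1 / na + 1 / nb))


def permutation_test(
    a,
    b,
    paired: bool = False,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "mean_diff",
    exact: bool = False,
) -> PermTestResult:
    """Two-sample permutation test on the difference of means.

    Independent samples permute group labels; paired samples flip signs of
    the within-pair differences.  p = (1 + #{|null| >= |obs|}) / (n_perm + 1)
    so that p can never be zero.  ``exact=True`` enumerates the full null
    (all label assignments, or all sign patterns when paired) and uses
    p = #{|null| >= |obs|} / n_total, which includes the identity
    permutation and is therefore also bounded away from zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    if paired and a.size != b.size:
        raise ValueError("paired test needs equal sample sizes")
    stat_fn = {"mean_diff": _mean_diff, "t": _t_stat}[statistic]
    obs = stat_fn(a, b)

    if exact:
        null = _exact_null(a, b, paired, stat_fn)
        p = float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
        return PermTestResult(obs, p, len(null), paired, None, exact=True)

    if n_perm < 1000:
        raise ValueError("n_perm must be at least 1000")
    rng = np.random.default_rng(seed)
    count = 0
    if paired:
        d = a - b
        for _ in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=d.size)
            if abs(np.mean(signs * d)) >= abs(obs) - 1e-12:
                count += 1
    else:
        pooled = np.concatenate([a, b])
        na = a.size
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(stat_fn(perm[:na], perm[na:])) >= abs(obs) - 1e-12:
                count += 1
    p = (1 + count) / (n_perm + 1)
    return PermTestResult(obs, p, n_perm, paired, seed)


def _exact_null(a, b, paired, stat_fn):
    if paired:
        d = a - b
        n = d.size
        if n > 20:
            raise ValueError("exact paired enumeration limited to n <= 20")
        null = []
        for bits in range(2 ** n):
            signs = np.array([1.0 if bits >> i & 1 else -1.0 for i in range(n)])
            null.append(np.mean(signs * d))
        return np.array(null)
    pooled = np.concatenate([a, b])
    na = a.size
    idx = np.arange(pooled.size)
    if math.comb(pooled.size, na) > 500_000:
        raise ValueError("exact enumeration too large")
    null = []
    for comb in combinations(idx, na):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        null.append(stat_fn(pooled[mask], pooled[~mask]))
    return np.array(null)


def fdr_adaptive(pvals, q: float = 0.05):
    """Two-stage adaptive linear step-up FDR control.

    Stage 1: Benjamini-Hochberg at q' = q / (1 + q) estimates the number of
    true nulls m0 = m - r1.  Stage 2: BH at q' * m / m0.  Returns
    (p_threshold, rejection mask); the threshold is the largest rejected
    p-value (0.0 when nothing is rejected).
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return 0.0, np.zeros(0, dtype=bool)
    if np.any(pvals <= 0) or np.any(pvals > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = pvals.size
    q1 = q / (1.0 + q)

    def bh_mask(level):
        order = np.argsort(pvals)
        ranked = pvals[order]
        crit = level * np.arange(1, m + 1) / m
        below = np.flatnonzero(ranked <= crit)
        mask = np.zeros(m, dtype=bool)
        if below.size:
            mask[order[: below[-1] + 1]] = True
        return mask

    r1 = int(bh_mask(q1).sum())
    if r1 == 0:
        return 0.0, np.zeros(m, dtype=bool)
    m0 = m - r1
    if m0 == 0:
        return 1.0, np.ones(m, dtype=bool)
    mask = bh_mask(q1 * m / m0)
    thresh = float(pvals[mask].max()) if mask.any() else 0.0
    return thresh, mask


def effect_size_delta(
    a,
    b,
    dependent: bool = False,
    n_boot: int = 5000,
    seed: int = 0,
) -> EffectSize:
    """Probability of superiority P(A > B) with tie correction.

    Independent samples compare all len(a) * len(b) cross-pairs; dependent
    samples compare within pairs.  Ties are removed from the denominator.
    The 95% CI is a seeded percentile bootstrap.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if dependent and a.size != b.size:
        raise ValueError("dependent effect size needs equal sample sizes")

    def delta_of(x, y):
        if dependent:
            gt = np.sum(x > y)
            ties = np.sum(x == y)
            denom = x.size - ties
        else:
            diff = x[:, None] - y[None, :]
            gt = np.sum(diff > 0)
            ties = np.sum(diff == 0)
            denom = x.size * y.size - ties
        if denom == 0:
            raise ValueError("undefined effect size: all comparisons tied")
        return gt / denom, int(ties)

    delta, n_ties = delta_of(a, b)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        if dependent:
            idx = rng.integers(0, a.size, a.size)
            xa, xb = a[idx], b[idx]
        else:
            xa = a[rng.integers(0, a.size, a.size)]
            xb = b[rng.integers(0, b.size, b.size)]
        try:
            boots[i], _ = delta_of(xa, xb)
        except ValueError:
            boots[i] = np.nan
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return EffectSize(
        delta=float(delta),
        kind="dependent" if dependent else "independent",
        ci95=(float(lo), float(hi)),
        n_ties=n_ties,
    )


def spearman_rho(x, y, n_perm: int = 10_000, seed: int = 0):
    """Tie-aware Spearman rank correlation with a permutation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need equal-length series of at least 5 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input")
    rx, ry = rankdata(x), rankdata(y)

    def pearson(u, v):
        u = u - u.mean()
        v = v - v.mean()
        return float(u @ v / math.sqrt((u @ u) * (v @ v)))

    rho = pearson(rx, ry)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if abs(pearson(rx, rng.permutation(ry))) >= abs(rho) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return rho, p


def hrv_metrics(rpeaks):
    """Coefficient of variation of the inter-beat interval and mean HR (bpm)."""
    rpeaks = np.asarray(rpeaks, dtype=float)
    if rpeaks.size < 3:
        raise ValueError("need at least 3 R-peaks")
    ibi = np.diff(rpeaks)
    if np.any(ibi <= 0):
        raise ValueError("non-monotonic R-peak times")
    mean_ibi = float(np.mean(ibi))
    cv = float(np.std(ibi, ddof=1) / mean_ibi)
    return cv, 60.0 / mean_ibi


def pointwise_timecourse_test(
    group_a,
    group_b,
    n_perm: int = 10_000,
    q: float = 0.05,
    seed: int = 0,
):
    """Per-timepoint permutation tests with adaptive FDR over time.

    Parameters
    ----------
    group_a, group_b : ndarray, subjects x timepoints
        Channel-averaged series per subject on a common time grid.

    Returns
    -------
    (mask, pvals, p_threshold): the per-timepoint significance mask after
    FDR control, the raw p-values, and the adapted threshold.
    """
    group_a = np.asarray(group_a, dtype=float)
    group_b = np.asarray(group_b, dtype=float)
    if group_a.ndim != 2 or group_b.ndim != 2:
        raise ValueError("group series must be 2-d (subjects x timepoints)")
    if group_a.shape[1] != group_b.shape[1]:
        raise ValueError("time grids differ between groups")
    n_t = group_a.shape[1]
    pvals = np.empty(n_t)
    for t in range(n_t):
        res = permutation_test(
            group_a[:, t], group_b[:, t], n_perm=n_perm, seed=seed + t
        )
        pvals[t] = res.p
    thresh, mask = fdr_adaptive(pvals, q=q)
    return mask, pvals, thresh
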