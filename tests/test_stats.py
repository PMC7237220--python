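import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import rankdata

from betalearn.stats import (
    effect_size_delta,
    fdr_adaptive,
    hrv_metrics,
    permutation_test,
    pointwise_timecourse_test,
    spearman_rho,
)


class TestPermutationTest:
    def test_identical_samples_high_p(self, rng):
        a = rng.standard_normal(10)
        res = permutation_test(a, a.copy(), n_perm=1000, seed=0)
        assert res.p > 0.5

    def test_p_never_zero(self, rng):
        a = rng.standard_normal(8) + 100
        b = rng.standard_normal(8)
        res = permutation_test(a, b, n_perm=1000, seed=0)
        assert res.p >= 1.0 / 1001

    def test_type_i_calibration(self):
        """Null rejection rate at alpha=0.05 lands in [0.03, 0.07]."""
        rejections = 0
        n_rep = 300
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            a, b = r.standard_normal((2, 12))
            res = permutation_test(a, b, n_perm=1000, seed=seed)
            rejections += res.p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_exact_matches_bruteforce_oracle(self, rng):
        a = rng.standard_normal(5)
        b = rng.standard_normal(5) + 1.0
        res = permutation_test(a, b, exact=True)
        pooled = np.concatenate([a, b])
        obs = a.mean() - b.mean()
        null = []
        for comb in combinations(range(10), 5):
            mask = np.zeros(10, dtype=bool)
            mask[list(comb)] = True
            null.append(pooled[mask].mean() - pooled[~mask].mean())
        expected = np.mean(np.abs(null) >= abs(obs) - 1e-12)
        assert res.p == pytest.approx(expected)
        assert res.n_permutations == math.comb(10, 5)

    def test_sampled_approximates_exact(self, rng):
        a = rng.standard_normal(5)
        b = rng.standard_normal(5) + 1.5
        exact = permutation_test(a, b, exact=True).p
        sampled = permutation_test(a, b, n_perm=20_000, seed=1).p
        assert sampled == pytest.approx(exact, abs=0.02)

    def test_paired_sign_flip(self, rng):
        a = rng.standard_normal(10)
        b = a + 2.0
        res = permutation_test(a, b, paired=True, n_perm=2000, seed=0)
        assert res.p < 0.01

    def test_paired_exact_enumeration(self, rng):
        a = rng.standard_normal(6)
        b = a + rng.standard_normal(6)
        res = permutation_test(a, b, paired=True, exact=True)
        d = a - b
        null = []
        for bits in range(2 ** 6):
            signs = np.array([1.0 if bits >> i & 1 else -1.0 for i in range(6)])
            null.append(np.mean(signs * d))
        expected = np.mean(np.abs(null) >= abs(np.mean(d)) - 1e-12)
        assert res.p == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([], [1.0])

    def test_seed_reproducible(self, rng):
        a, b = rng.standard_normal((2, 10))
        assert (
            permutation_test(a, b, seed=5).p == permutation_test(a, b, seed=5).p
        )


class TestFdrAdaptive:
    def test_all_ones_no_rejection(self):
        thresh, mask = fdr_adaptive(np.ones(20))
        assert thresh == 0.0 and not mask.any()

    def test_single_small_p_rejected(self):
        thresh, mask = fdr_adaptive(np.array([0.01]))
        assert mask[0]

    def test_superset_of_bh(self, rng):
        """Adaptive two-stage rejects at least what plain BH rejects."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            p = np.concatenate([r.uniform(0, 1, 40), r.uniform(0, 0.002, 10)])
            _, mask = fdr_adaptive(p, q=0.05)
            bh = _plain_bh(p, 0.05)
            assert np.all(mask[bh])

    def test_fdr_controlled_on_mixture(self):
        """Empirical FDR <= q over the stated null/alternative mixture."""
        q = 0.05
        fdp = []
        for seed in range(500):
            r = np.random.default_rng(seed)
            null_p = r.uniform(0, 1, 80)
            alt_p = r.uniform(0, 1e-4, 20)
            p = np.concatenate([null_p, alt_p])
            _, mask = fdr_adaptive(p, q=q)
            n_rej = mask.sum()
            fdp.append(mask[:80].sum() / max(n_rej, 1))
        assert np.mean(fdp) <= q + 0.01

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            fdr_adaptive(np.array([0.0, 0.5]))


def _plain_bh(pvals, q):
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order]
    below = np.flatnonzero(ranked <= q * np.arange(1, m + 1) / m)
    mask = np.zeros(m, dtype=bool)
    if below.size:
        mask[order[: below[-1] + 1]] = True
    return mask


class TestEffectSize:
    def test_complete_separation(self):
        es = effect_size_delta([5.0, 6.0, 7.0], [1.0, 2.0], n_boot=100)
        assert es.delta == 1.0

    def test_null_delta_half(self, rng):
        a, b = rng.standard_normal((2, 300))
        es = effect_size_delta(a, b, n_boot=200, seed=0)
        assert es.delta == pytest.approx(0.5, abs=0.05)

    def test_bruteforce_oracle_independent(self, rng):
        a = rng.integers(0, 10, 8).astype(float)
        b = rng.integers(0, 10, 6).astype(float)
        es = effect_size_delta(a, b, n_boot=100, seed=0)
        gt = sum(x > y for x in a for y in b)
        ties = sum(x == y for x in a for y in b)
        denom = len(a) * len(b) - ties
        if denom:
            assert es.delta == pytest.approx(gt / denom)
            assert es.n_ties == ties

    def test_bruteforce_oracle_dependent(self, rng):
        a = rng.integers(0, 5, 10).astype(float)
        b = rng.integers(0, 5, 10).astype(float)
        try:
            es = effect_size_delta(a, b, dependent=True, n_boot=100, seed=0)
        except ValueError:
            return  # all tied: legitimately undefined
        gt = sum(x > y for x, y in zip(a, b))
        ties = sum(x == y for x, y in zip(a, b))
        assert es.delta == pytest.approx(gt / (10 - ties))

    def test_monotone_transform_invariance(self, rng):
        a = rng.random(20)
        b = rng.random(15)
        d1 = effect_size_delta(a, b, n_boot=50, seed=0).delta
        d2 = effect_size_delta(np.exp(a), np.exp(b), n_boot=50, seed=0).delta
        assert d1 == d2

    def test_ci_brackets_delta(self, rng):
        a = rng.standard_normal(30) + 0.5
        b = rng.standard_normal(30)
        es = effect_size_delta(a, b, n_boot=2000, seed=0)
        assert es.ci95[0] <= es.delta <= es.ci95[1]

    def test_all_tied_undefined(self):
        with pytest.raises(ValueError, match="tied"):
            effect_size_delta([1.0, 1.0], [1.0, 1.0], n_boot=10)


class TestSpearman:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        rho, p = spearman_rho(x, x ** 3, n_perm=1000, seed=0)
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_perfect_negative(self):
        x = np.arange(10.0)
        rho, _ = spearman_rho(x, -x, n_perm=1000, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_rank_then_pearson_oracle(self, rng):
        x = rng.random(15)
        y = rng.random(15)
        rho, _ = spearman_rho(x, y, n_perm=1000, seed=0)
        rx, ry = rankdata(x), rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, rel=1e-10)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho(np.ones(10), np.arange(10.0))


class TestHrv:
    def test_regular_train(self):
        cv, hr = hrv_metrics(np.arange(0.0, 60.0, 1.0))
        assert cv == 0.0 and hr == pytest.approx(60.0)

    def test_generator_roundtrip(self):
        from betalearn.synth import gen_rpeaks

        peaks = gen_rpeaks(70.0, 0.05, 600.0, seed=0)
        cv, hr = hrv_metrics(peaks)
        assert cv == pytest.approx(0.05, rel=0.1)
        assert hr == pytest.approx(70.0, rel=0.05)

    def test_interval_scaling(self, rng):
        ibi = np.abs(rng.standard_normal(100)) * 0.1 + 0.8
        peaks = np.cumsum(ibi)
        cv1, hr1 = hrv_metrics(peaks)
        cv2, hr2 = hrv_metrics(2 * peaks)
        assert cv2 == pytest.approx(cv1)
        assert hr2 == pytest.approx(hr1 / 2)

    def test_nonmonotonic_rejected(self):
        with pytest.raises(ValueError):
            hrv_metrics(np.array([0.0, 1.0, 0.5]))


class TestPointwiseTimecourse:
    def test_single_timepoint_reduction(self, rng):
        a = rng.standard_normal((10, 1)) + 3
        b = rng.standard_normal((10, 1))
        mask, pvals, _ = pointwise_timecourse_test(a, b, n_perm=2000, seed=0)
        single = permutation_test(a[:, 0], b[:, 0], n_perm=2000, seed=0)
        assert pvals[0] == pytest.approx(single.p)
        assert mask[0]

    def test_injected_window_detected(self, rng):
        n_t = 30
        a = rng.standard_normal((12, n_t))
        b = rng.standard_normal((12, n_t))
        a[:, 10:20] += 3.0
        mask, _, _ = pointwise_timecourse_test(a, b, n_perm=2000, seed=0)
        assert mask[10:20].sum() >= 8
        assert mask[:10].sum() + mask[20:].sum() <= 2

    def test_null_mostly_empty(self):
        empties = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            a = r.standard_normal((8, 10))
            b = r.standard_normal((8, 10))
            mask, _, _ = pointwise_timecourse_test(a, b, n_perm=1000, seed=seed)
            empties += not mask.any()
        assert empties >= 33  # ~95% of replicates

    def test_grid_mismatch(self, rng):
        with pytest.raises(ValueError):
            pointwise_timecourse_test(
                rng.standard_normal((5, 10)), rng.standard_normal((5, 12))
            )
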