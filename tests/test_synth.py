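import math
from dataclasses import replace

import numpy as np
import pytest

from betalearn.scoring import TARGET_NORM, TrialPerformance, compute_score
from betalearn.synth import (
    AgentConfig,
    BurstSignalConfig,
    alternating_iki_vector,
    gen_agent_performance,
    gen_burst_signal,
    gen_group_dataset,
    gen_rpeaks,
    sample_burst_durations,
    solve_deviation,
)


class TestAlternatingIki:
    def test_cv_realized(self):
        for cv in (0.05, 0.2, 0.5):
            for n in (6, 7):
                iki = alternating_iki_vector(cv, 0.5, n)
                realized = np.std(iki) / np.mean(iki)
                assert realized == pytest.approx(cv, rel=1e-9)

    def test_all_positive(self):
        iki = alternating_iki_vector(0.7, 0.5, 7)
        assert np.all(iki > 0)

    def test_infeasible_cv_raises(self):
        with pytest.raises(ValueError):
            solve_deviation(8.0, 0.5, 7)


class TestAgentGenerator:
    def test_no_update_agent_constant(self):
        cfg = AgentConfig(beta0=0.0, beta1=0.0, beta2=0.0, zeta=1e-12,
                          n_trials=40, seed=0)
        out = gen_agent_performance(cfg)
        cvs = out.trajectories["cv_iki_trial"]
        assert np.ptp(cvs) < 1e-4
        assert np.ptp(out.scores) < 0.1

    def test_determinism(self):
        cfg = AgentConfig(n_trials=50, seed=42)
        a = gen_agent_performance(cfg)
        b = gen_agent_performance(cfg)
        np.testing.assert_array_equal(a.scores, b.scores)
        assert a.performance.equals(b.performance)

    def test_score_matches_scoring_oracle(self):
        out = gen_agent_performance(AgentConfig(n_trials=30, seed=1))
        perf = out.performance
        for trial, chunk in perf.groupby("trial"):
            p = TrialPerformance(chunk["iki_ms"].to_numpy() / 1000.0)
            assert compute_score(p, TARGET_NORM) == pytest.approx(
                out.scores[trial - 1], rel=1e-9
            )

    def test_converged_agent_scores_approach_100(self):
        """An agent sitting at the target-matching CV scores near 100."""
        L, m = 7, 0.5
        d_star = TARGET_NORM / (2 * math.sqrt(L - 1))
        s = math.sqrt(1 - 1 / L ** 2)
        cv_star = d_star * s / (m + d_star / L)
        cfg = AgentConfig(beta0=0.0, beta1=0.0, beta2=0.0, zeta=1e-12,
                          cv_init=cv_star, n_trials=20, seed=0)
        out = gen_agent_performance(cfg)
        assert np.all(out.scores > 99.9)

    def test_clipping_flagged(self):
        cfg = AgentConfig(beta0=-0.2, beta1=0.0, beta2=0.0, zeta=1e-10,
                          cv_init=0.3, n_trials=20, seed=0)
        out = gen_agent_performance(cfg)
        assert out.trajectories["clipped"].any()
        assert np.all(out.performance["iki_ms"] > 0)

    def test_response_model_consistency(self):
        """Unclipped delta-cv steps follow the generative linear rule."""
        cfg = AgentConfig(beta0=0.01, beta1=-0.1, beta2=0.05, zeta=1e-12,
                          n_trials=60, cv_init=0.4, seed=9)
        out = gen_agent_performance(cfg)
        tr = out.trajectories
        cvs = tr["cv_iki_trial"]
        for k in range(1, 60):
            if tr["clipped"][k]:
                continue
            expected = 0.01 - 0.1 * tr["eps1"][k - 1] + 0.05 * tr["eps2"][k - 1]
            assert cvs[k] - cvs[k - 1] == pytest.approx(expected, abs=1e-5)

    def test_performance_table_schema(self):
        out = gen_agent_performance(AgentConfig(n_trials=10, seed=0))
        assert list(out.performance.columns) == [
            "subject", "group", "trial", "position", "iki_ms", "kvel", "score",
        ]
        assert len(out.performance) == 10 * 7


class TestBurstSignalGenerator:
    def test_zero_rate_empty(self):
        sig, ann = gen_burst_signal(BurstSignalConfig(burst_rate_per_s=0.0, seed=0))
        assert ann["events"] == []

    def test_duration_slope_matches_tau(self, rng):
        d = sample_burst_durations(rng, 5000, 1.5)
        from betalearn.bursts import duration_distribution

        dist = duration_distribution(d)
        assert dist.tau == pytest.approx(1.5, abs=0.1)

    def test_determinism(self):
        cfg = BurstSignalConfig(seed=7, duration_s=10.0)
        a, _ = gen_burst_signal(cfg)
        b, _ = gen_burst_signal(cfg)
        np.testing.assert_array_equal(a, b)

    def test_overlap_merge_flagged(self):
        cfg = BurstSignalConfig(burst_rate_per_s=5.0, duration_s=10.0, seed=0)
        _, ann = gen_burst_signal(cfg)
        assert any(ev["merged"] for ev in ann["events"])
        ends = [e["onset_s"] + e["duration_ms"] / 1000 for e in ann["events"]]
        onsets = [e["onset_s"] for e in ann["events"]]
        assert all(o >= e - 1e-9 for o, e in zip(onsets[1:], ends[:-1]))

    def test_noise_spectrum_slope(self):
        from betalearn.spectral import welch_psd

        cfg = BurstSignalConfig(burst_rate_per_s=0.0, noise_exponent=1.0,
                                duration_s=120.0, seed=3)
        sig, _ = gen_burst_signal(cfg)
        f, p = welch_psd(sig, cfg.fs)
        m = (f >= 1) & (f <= 100)
        slope = np.polyfit(np.log10(f[m]), np.log10(p[m]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.3)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            BurstSignalConfig(tau_true=0.9)
        with pytest.raises(ValueError):
            BurstSignalConfig(band=(30.0, 13.0))


class TestRpeaks:
    def test_regular_when_cv_zero(self):
        peaks = gen_rpeaks(60.0, 0.0, 60.0, seed=0)
        assert len(peaks) in (59, 60)
        np.testing.assert_allclose(np.diff(peaks), 1.0)

    def test_rate_identity(self):
        peaks = gen_rpeaks(60.0, 0.02, 60.0, seed=1)
        assert abs(len(peaks) - 60) <= 3

    def test_cv_recovered_large_n(self):
        peaks = gen_rpeaks(70.0, 0.08, 500 * 60 / 70, seed=2)
        ibi = np.diff(peaks)
        cv = np.std(ibi, ddof=1) / np.mean(ibi)
        assert cv == pytest.approx(0.08, rel=0.05)

    def test_resampling_warns(self):
        with pytest.warns(UserWarning, match="resampled"):
            gen_rpeaks(60.0, 1.5, 30.0, seed=0)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            gen_rpeaks(-10.0, 0.05, 60.0)
        with pytest.raises(ValueError):
            gen_rpeaks(60.0, -0.1, 60.0)


@pytest.fixture(scope="module")
def dataset():
    groups = {
        "control": {"agent": AgentConfig(n_trials=30),
                    "burst": BurstSignalConfig(duration_s=10.0)},
        "anx1": {"agent": AgentConfig(n_trials=30, omega2=-3.0),
                 "burst": BurstSignalConfig(duration_s=10.0, tau_true=1.3)},
    }
    return gen_group_dataset(groups, n_subjects=3, seed=5)


class TestGroupDataset:

    def test_structure(self, dataset):
        assert len(dataset.subjects) == 6
        assert set(dataset.group_of.values()) == {"control", "anx1"}
        assert len(dataset.subjects_in("control")) == 3

    def test_determinism(self):
        groups = {
            "a": {"agent": AgentConfig(n_trials=25)},
            "b": {"agent": AgentConfig(n_trials=25)},
        }
        d1 = gen_group_dataset(groups, 2, seed=1, with_signals=False)
        d2 = gen_group_dataset(groups, 2, seed=1, with_signals=False)
        assert d1.performances.equals(d2.performances)
        for s in d1.subjects:
            np.testing.assert_array_equal(d1.scores[s], d2.scores[s])

    def test_ground_truth_stored(self, dataset):
        for sid in dataset.subjects:
            gt = dataset.ground_truth[sid]
            assert "trajectories" in gt and "agent_config" in gt
            assert gt["burst_config"].tau_true in (1.5, 1.3)

    def test_minimums_enforced(self):
        with pytest.raises(ValueError):
            gen_group_dataset({"only": {}}, 3)
        with pytest.raises(ValueError):
            gen_group_dataset({"a": {}, "b": {}}, 1)

    def test_injected_tau_difference_detectable(self):
        """tau shift of 0.3 at n=8/group is found by the permutation test."""
        from betalearn.bursts import duration_distribution
        from betalearn.stats import permutation_test

        taus = {"lo": [], "hi": []}
        for label, tau in (("lo", 1.3), ("hi", 1.6)):
            for i in range(8):
                r = np.random.default_rng(100 * (label == "hi") + i)
                d = sample_burst_durations(r, 2000, tau)
                taus[label].append(duration_distribution(d).tau)
        res = permutation_test(
            np.array(taus["lo"]), np.array(taus["hi"]), n_perm=2000, seed=0
        )
        assert res.p < 0.05
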