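"""Config-driven end-to-end runs over a synthetic (or ingested) dataset.

Stages: simulate -> score -> fit -> select -> burst -> spectral -> link ->
stats -> report.  Each stage reads its upstream outputs from the run
directory and records what it did in ``manifest.json``; task and analysis
constants default to the study's printed values and live in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import bms, bursts, io, linking, respmodels, scoring, spectral, stats, synth

logger = logging.getLogger("betalearn.pipeline")

STAGES = (
    "simulate", "score", "fit", "select", "burst", "spectral", "link",
    "stats", "report",
)

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": list(STAGES),
    "n_subjects": 4,
    "n_trials": 60,
    "groups": {
        "control": {},
        "anx1": {"omega2": -3.0, "tau_true": 1.4},
    },
    # task constants
    "target_norm": scoring.TARGET_NORM,
    "markers_s": {"go": 0.0, "stop": 7.0, "feedback": 9.0},
    "bin_size": 25,
    # analysis constants
    "band_hz": [13.0, 30.0],
    "burst_percentile": 75.0,
    "feedback_window_ms": [400.0, 1600.0],
    "q_fdr": 0.05,
    "n_perm": 2000,
    "fit_n_starts": 2,
    "fit_models": "winning",  # "winning" | "all"
}


def load_config(path=None, overrides=None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        import yaml

        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg.update(user)
    if overrides:
        cfg.update(overrides)
    unknown = [s for s in cfg["stages"] if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    return cfg


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineRun:
    def __init__(self, config: dict, out_dir):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"stages": {}, "config": config}

    def _record(self, stage: str, outputs: list[Path]):
        self.manifest["stages"][stage] = {
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {p.name: _file_hash(p) for p in outputs},
        }
        self.manifest["config"] = self.config
        self.manifest_path.write_text(
            json.dumps(self.manifest, indent=2, default=str)
        )

    def _require(self, stage: str, path: Path) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"missing upstream output {path.name}: run stage '{stage}' first"
            )
        return path

    # ------------------------------------------------------------------ stages

    def simulate(self):
        cfg = self.config
        group_cfgs = {}
        for name, shifts in cfg["groups"].items():
            agent_kwargs = {
                k: v for k, v in shifts.items()
                if k in synth.AgentConfig.__dataclass_fields__
            }
            burst_kwargs = {
                k: v for k, v in shifts.items()
                if k in synth.BurstSignalConfig.__dataclass_fields__
            }
            group_cfgs[name] = {
                "agent": synth.AgentConfig(n_trials=cfg["n_trials"], **agent_kwargs),
                "burst": synth.BurstSignalConfig(
                    duration_s=30.0, band=tuple(cfg["band_hz"]), **burst_kwargs
                ),
            }
        ds = synth.gen_group_dataset(
            group_cfgs, cfg["n_subjects"], seed=cfg["seed"],
            target_norm=cfg["target_norm"],
        )
        io.write_performance_csv(ds.performances, self.out / "performance.csv")
        sig_dir = self.out / "signals"
        sig_dir.mkdir(exist_ok=True)
        truth = {}
        for sid, (sig, ann) in ds.signals.items():
            io.write_signal(
                sig, ann["config"].fs, sig_dir / f"{sid}.bin",
                markers={"events": ann["events"]},
            )
            truth[sid] = {
                "group": ds.group_of[sid],
                "tau_true": ann["config"].tau_true,
                "agent": ds.ground_truth[sid]["agent_config"],
                "n_true_bursts": len(ann["events"]),
            }
        io.write_json(truth, self.out / "ground_truth.json")
        rp = {sid: list(v) for sid, v in ds.rpeaks.items()}
        io.write_json(rp, self.out / "rpeaks.json")
        logger.info("simulated %d subjects", len(ds.group_of))
        self._record("simulate", [self.out / "performance.csv",
                                  self.out / "ground_truth.json"])

    def score(self):
        perf = io.read_performance_csv(
            self._require("simulate", self.out / "performance.csv")
        )
        rows = []
        for (sid, trial), chunk in perf.groupby(["subject", "trial"]):
            p = scoring.TrialPerformance(chunk["iki_ms"].to_numpy() / 1000.0)
            meas = scoring.trial_measures(p, self.config["target_norm"])
            rows.append(
                (sid, chunk["group"].iloc[0], trial, meas.cv_iki_trial,
                 meas.log_m_iki, meas.diff_norm, meas.score)
            )
        df = pd.DataFrame(
            rows,
            columns=["subject", "group", "trial", "cv_iki_trial",
                     "log_m_iki", "diff_norm", "score"],
        ).sort_values(["subject", "trial"])
        df.to_csv(self.out / "trial_measures.csv", index=False)
        self._record("score", [self.out / "trial_measures.csv"])

    def fit(self):
        meas = pd.read_csv(
            self._require("score", self.out / "trial_measures.csv")
        )
        if self.config["fit_models"] == "all":
            specs = respmodels.enumerate_models()
        else:
            specs = [respmodels.winning_spec()]
        rows, params = [], {}
        for sid, chunk in meas.groupby("subject"):
            chunk = chunk.sort_values("trial")
            u = chunk["score"].to_numpy() / 100.0
            for spec in specs:
                col = ("cv_iki_trial" if spec.family == respmodels.CV_FAMILY
                       else "log_m_iki")
                y = np.diff(chunk[col].to_numpy())
                fm = respmodels.fit_model(
                    u, y, spec,
                    n_starts=self.config["fit_n_starts"],
                    seed=self.config["seed"],
                )
                rows.append((sid, spec.name, fm.lme))
                params.setdefault(sid, {})[spec.name] = {
                    "map": fm.map_params, "converged": fm.converged,
                    "diagnostics": respmodels.residual_diagnostics(fm),
                }
        pd.DataFrame(rows, columns=["subject", "model", "lme"]).to_csv(
            self.out / "evidence.csv", index=False
        )
        io.write_json(params, self.out / "fitted_params.json")
        self._record("fit", [self.out / "evidence.csv",
                             self.out / "fitted_params.json"])

    def select(self):
        ev = pd.read_csv(self._require("fit", self.out / "evidence.csv"))
        wide = ev.pivot(index="subject", columns="model", values="lme")
        labels = tuple(wide.columns)
        result = {"models": labels}
        if len(labels) >= 2:
            em = bms.EvidenceMatrix(
                wide.to_numpy(), labels,
                {m: ("cv_family" if m.startswith("HGF1") else "tempo_family")
                 for m in labels},
            )
            lfe, fams = bms.family_log_evidence(em)
            if len(fams) >= 2:
                fam_res = bms.rfx_bms(
                    lfe, labels=fams, seed=self.config["seed"],
                    n_samples=100_000,
                )
                result["family"] = {
                    "labels": fams,
                    "expected_frequencies": fam_res.expected_frequencies,
                    "exceedance_probabilities": fam_res.exceedance_probabilities,
                }
            mod_res = bms.rfx_bms(
                wide.to_numpy(), labels=labels, seed=self.config["seed"],
                n_samples=100_000,
            )
            result["model"] = {
                "labels": labels,
                "expected_frequencies": mod_res.expected_frequencies,
                "exceedance_probabilities": mod_res.exceedance_probabilities,
            }
        else:
            result["note"] = "single model fitted; BMS skipped"
        io.write_json(result, self.out / "bms.json")
        self._record("select", [self.out / "bms.json"])

    def burst(self):
        sig_dir = self._require("simulate", self.out / "signals")
        band = tuple(self.config["band_hz"])
        rows, taus = [], {}
        for bin_path in sorted(sig_dir.glob("*.bin")):
            sid = bin_path.stem
            sig, sidecar = io.read_signal(bin_path)
            fs = sidecar["fs"]
            env = bursts.band_envelope(sig, fs, band)
            edge = bursts.edge_samples(fs, band)
            interior = env[edge:-edge]
            thr = bursts.threshold_from_rest(
                interior, self.config["burst_percentile"]
            )
            events = bursts.detect_bursts(interior, fs, thr, channel=sid)
            for ev in events:
                rows.append((sid, ev.onset_s, ev.duration_ms, ev.peak_amplitude))
            try:
                dist = bursts.duration_distribution(events)
                taus[sid] = {"tau": dist.tau, "n_events": dist.n_events}
            except ValueError as exc:
                taus[sid] = {"tau": None, "error": str(exc)}
        pd.DataFrame(
            rows, columns=["subject", "onset_s", "duration_ms", "peak"]
        ).to_csv(self.out / "burst_events.csv", index=False)
        io.write_json(taus, self.out / "burst_tau.json")
        self._record("burst", [self.out / "burst_events.csv",
                               self.out / "burst_tau.json"])

    def spectral(self):
        sig_dir = self._require("simulate", self.out / "signals")
        rows = []
        for bin_path in sorted(sig_dir.glob("*.bin")):
            sid = bin_path.stem
            sig, sidecar = io.read_signal(bin_path)
            freqs, psd = spectral.welch_psd(sig, sidecar["fs"])
            for f, p in zip(freqs, psd):
                rows.append((sid, f, p))
        pd.DataFrame(rows, columns=["subject", "freq_hz", "psd"]).to_csv(
            self.out / "psd.csv", index=False
        )
        self._record("spectral", [self.out / "psd.csv"])

    def link(self):
        """Regress a per-trial envelope measure on the fitted pwPEs."""
        params = json.loads(
            self._require("fit", self.out / "fitted_params.json").read_text()
        )
        meas = pd.read_csv(
            self._require("score", self.out / "trial_measures.csv")
        )
        sig_dir = self._require("simulate", self.out / "signals")
        band = tuple(self.config["band_hz"])
        results = {}
        for sid, chunk in meas.groupby("subject"):
            bin_path = sig_dir / f"{sid}.bin"
            if not bin_path.exists():
                continue
            chunk = chunk.sort_values("trial")
            u = chunk["score"].to_numpy() / 100.0
            from .hgf import HGFParams, default_priors, hgf_filter
            import math as _math

            mp = params[sid][next(iter(params[sid]))]["map"]
            pri = default_priors(u)
            traj = hgf_filter(
                HGFParams(
                    omega1=mp["omega1"], omega2=mp["omega2"],
                    pi_u=_math.exp(mp["log_pi_u"]),
                    mu1_0=pri["mu1_0"][0],
                    sigma1_0=_math.exp(pri["log_sigma1_0"][0]),
                ),
                u,
            )
            sig, sidecar = io.read_signal(bin_path)
            fs = sidecar["fs"]
            env = bursts.band_envelope(sig, fs, band)
            # pseudo-epochs: slice the continuous record into trial segments
            n_trials = len(u)
            seg = len(env) // n_trials
            measure = env[: seg * n_trials].reshape(n_trials, seg).mean(axis=1)
            res = linking.fit_link_regression(measure, traj.eps1, traj.eps2)
            results[sid] = {
                "beta0": res.beta0, "beta1": res.beta1, "beta2": res.beta2,
                "stderr": res.stderr, "n_trials": res.n_trials,
                "regressor_correlation": res.regressor_correlation,
            }
        io.write_json(results, self.out / "link_regression.json")
        self._record("link", [self.out / "link_regression.json"])

    def stats(self):
        meas = pd.read_csv(
            self._require("score", self.out / "trial_measures.csv")
        )
        taus = json.loads(
            self._require("burst", self.out / "burst_tau.json").read_text()
        )
        rp = json.loads(
            self._require("simulate", self.out / "rpeaks.json").read_text()
        )
        truth = json.loads(
            self._require("simulate", self.out / "ground_truth.json").read_text()
        )
        groups = sorted({v["group"] for v in truth.values()})
        by_group = {
            g: [sid for sid, v in truth.items() if v["group"] == g]
            for g in groups
        }
        mean_score = meas.groupby("subject")["score"].mean()
        out = {}
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                a_scores = mean_score[by_group[ga]].to_numpy()
                b_scores = mean_score[by_group[gb]].to_numpy()
                res = stats.permutation_test(
                    a_scores, b_scores, n_perm=self.config["n_perm"],
                    seed=self.config["seed"],
                )
                comp = {"score": {"stat": res.statistic, "p": res.p}}
                ta = [taus[s]["tau"] for s in by_group[ga]
                      if taus.get(s, {}).get("tau") is not None]
                tb = [taus[s]["tau"] for s in by_group[gb]
                      if taus.get(s, {}).get("tau") is not None]
                if len(ta) >= 2 and len(tb) >= 2:
                    rt = stats.permutation_test(
                        np.array(ta), np.array(tb),
                        n_perm=self.config["n_perm"], seed=self.config["seed"],
                    )
                    comp["tau"] = {"stat": rt.statistic, "p": rt.p}
                ha = [stats.hrv_metrics(np.array(rp[s]))[0] for s in by_group[ga]]
                hb = [stats.hrv_metrics(np.array(rp[s]))[0] for s in by_group[gb]]
                rh = stats.permutation_test(
                    np.array(ha), np.array(hb), n_perm=self.config["n_perm"],
                    seed=self.config["seed"],
                )
                comp["hrv_cv"] = {"stat": rh.statistic, "p": rh.p}
                out[f"{ga}_vs_{gb}"] = comp
        io.write_json(out, self.out / "group_stats.json")
        self._record("stats", [self.out / "group_stats.json"])

    def report(self):
        report = {
            "stages_completed": sorted(self.manifest["stages"]),
            "seed": self.config["seed"],
        }
        for name in ("bms.json", "burst_tau.json", "group_stats.json"):
            p = self.out / name
            if p.exists():
                report[name.removesuffix(".json")] = json.loads(p.read_text())
        io.write_json(report, self.out / "report.json")
        self._record("report", [self.out / "report.json"])


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the enabled stages in dependency order; returns the run dir."""
    run = PipelineRun(config, out_dir)
    for stage in STAGES:
        if stage in config["stages"]:
            logger.info("running stage %s", stage)
            getattr(run, stage)()
    return run.out


def validate_inputs(performance_csv, strict: bool = False) -> list[str]:
    """Schema and invariant checks on a performance table."""
    violations = []
    try:
        df = io.read_performance_csv(performance_csv)
    except Exception as exc:  # noqa: BLE001
        violations.append(f"unreadable performance table: {exc}")
        if strict:
            raise
        return violations
    bad = df.index[df["iki_ms"] <= 0]
    for i in bad:
        violations.append(f"row {i}: non-positive IKI {df.loc[i, 'iki_ms']}")
    if "score" in df.columns:
        bad = df.index[(df["score"] < 0) | (df["score"] > 100)]
        for i in bad:
            violations.append(f"row {i}: score outside [0, 100]")
    if strict and violations:
        raise ValueError("; ".join(violations))
    return violations
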