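# betalearn

Analysis toolkit for reward-based motor sequence learning experiments,
exercised end to end on synthetic data with known ground truth. It covers:

- **Task scoring** (`betalearn.scoring`) — trial performance measures from
  inter-keystroke intervals (IKIs): within-trial CV, log mean tempo, the
  Euclidean norm of successive IKI differences, and the reward mapping
  `score = 100·exp(−|target − performed norm|)` (target norm 1.9596).
- **Hierarchical Gaussian filtering** (`betalearn.hgf`) — a two-level HGF for
  continuous inputs (normalized feedback scores) producing belief
  trajectories and precision-weighted prediction errors (pwPEs); priors are
  seeded from the first 20 inputs.
- **Response models** (`betalearn.respmodels`) — the 8 linear models (2
  response families × 4 predictor pairs) mapping previous-trial belief
  quantities to performance changes; joint MAP fitting (Nelder–Mead
  multi-start with an OLS-informed start) and Laplace log model evidence.
- **Model selection** (`betalearn.bms`) — log family evidence and
  random-effects Bayesian model selection (variational Dirichlet updates,
  Monte-Carlo exceedance probabilities).
- **Burst dynamics** (`betalearn.bursts`) — beta-band amplitude-envelope
  burst detection (75th-percentile rest threshold, 50 ms cycle/gap rules),
  log-binned duration distributions, and the life-time exponent τ.
- **Spectral power** (`betalearn.spectral`) — Welch PSD with dB
  normalization to rest, 7-cycle Morlet time-frequency power with baseline
  z-normalization, and feedback-locked measures (400–1600 ms window).
- **Neural linking** (`betalearn.linking`) — per-subject OLS of
  feedback-locked beta measures on the two pwPE regressors.
- **Group statistics** (`betalearn.stats`) — permutation tests (with exact
  enumeration), two-stage adaptive FDR, probability-of-superiority effect
  sizes (Δ, Δdep) with bootstrap CIs, Spearman rank correlation, HRV, and
  pointwise time-course tests.
- **Synthetic data** (`betalearn.synth`) — generative agents driven by the
  winning response model, 1/f signals with power-law burst durations, R-peak
  trains, and multi-group datasets; all deterministic under a seed and
  emitted with ground truth.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (printed-value
checks, Kalman-limit oracle, parameter/exponent recovery, detection
exactness, BMS behavior, FDR calibration, CI coverage, permutation
equivalence). The full suite runs in a few minutes on one CPU.

## CLI

The pipeline runs end to end over a synthetic dataset
(simulate → score → fit → select → burst → spectral → link → stats → report):

```sh
betalearn run --seed 1 --out runs/demo
betalearn run --stages simulate,score --out runs/partial
betalearn validate runs/demo/performance.csv
betalearn -v run --config my_config.yaml --out runs/custom
```

Each stage writes CSV/JSON outputs plus a `manifest.json` recording seeds
and output hashes. Task and analysis constants (target norm, GO/STOP/
feedback markers at 0/7/9 s, 13–30 Hz band, 25-trial bins, q = 0.05) default
to the study's values and are all overridable via a YAML config.

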