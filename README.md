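# sleepwake

Epoch-by-epoch sleep–wake scoring from wrist actigraphy, and the tooling to
benchmark scoring algorithms against polysomnography (PSG) ground truth.

Wrist-worn actigraphs summarize movement as an *activity count* per fixed
epoch (30 s here). Scoring algorithms decide, per epoch, whether the wearer
was asleep (1) or awake (0); validation studies compare those decisions to
technician-scored PSG stages collapsed to binary (stages 1–4 and REM →
sleep, stage 0 → wake; sleep is the positive class). This package is for
sleep researchers and method developers who want to run that comparison
end-to-end — on their own epoch tables, on the MESA Sleep overlap files, or
on fully synthetic cohorts that need no restricted data.

## What is implemented

* **Traditional scorers** — Webster, Cole–Kripke, Oakley (the Actiwatch
  device algorithm at θ = 40), Scripps Clinic, Sadeh, and Sazonov, from the
  canonical published coefficient sets. The weighted-sum family computes
  `score_t = P · Σ_i w_i · c_{t+i}` over a fixed offset window and thresholds
  it (e.g. Cole–Kripke: `D = 0.001·(106 c₋₄ + 54 c₋₃ + 58 c₋₂ + 76 c₋₁ +
  230 c₀ + 74 c₊₁ + 67 c₊₂)`, sleep iff `D < 1`). Sadeh thresholds
  `PS = 7.601 − 0.065·AVG − 1.08·NAT − 0.056·SD − 0.703·LG` at 0; Sazonov is
  the one causal scorer, a linear form over rolling maxima of recent counts.
* **Webster's rescoring rules** R1–R5, applied sequentially, with the
  either-flank reading of "surrounded" as default and the stricter
  both-flanks variant behind `flank_mode="and"`.
* **Features and classifiers** — a 370-column sliding-window summary-
  statistic schema plus subject-level cross-validated classical models
  (logistic regression, linear SVM, perceptron, extra trees) and a raw-count
  window model.
* **Metrics** — accuracy/sensitivity/specificity/precision/F1 (sleep
  positive), WASO in minutes (wake strictly after the first PSG sleep
  epoch), sleep efficiency in percent, per-subject cohort summaries
  (mean ± 1.96·SEM), MAE against ground truth, paired two-tailed t-tests,
  and metric–metric Pearson correlations.
* **Synthetic cohorts** — a seeded semi-Markov sleep-architecture simulator
  with zero-inflated-gamma count emissions, PSG-night plus day-wear
  structure, naps, and a noisy expert-annotation channel.
* **Benchmark harness** — cohort exclusion filters, the Night and Night&Day
  tasks, four baselines (always-sleep, always-wake, device, manual
  annotation), a ground-truth oracle row, and report/significance output.

## Worked example

```python
>>> from sleepwake import (SimulationConfig, generate_subject,
...                        build_task_night, score, epoch_metrics)
>>> night = build_task_night(generate_subject(SimulationConfig(seed=9), 0))
>>> em = epoch_metrics(score("cole_kripke", night.counts).predictions, night.truth)
>>> round(em.accuracy, 1), round(em.sensitivity, 1), round(em.specificity, 1)
(84.6, 73.2, 100.0)
```

The `examples/` scripts each demonstrate one capability; for instance
`python examples/01_traditional_scorers.py` prints

```
subject synth-9-0000: 1183 night epochs, 57.3% asleep by PSG

algorithm      accuracy   sens   spec     f1
webster            98.0   97.3   98.8   98.2
cole_kripke        84.6   73.2  100.0   84.5
oakley             98.8   98.1   99.8   99.0
scripps            96.6   94.8   99.0   97.0
sadeh              98.0   96.8   99.6   98.2
sazonov            74.5   55.5  100.0   71.3
```

— one simulated overnight PSG recording scored by all six algorithms.
Sensitivity is the share of true sleep detected, specificity the share of
true wake; the high-sensitivity/lower-specificity pattern of the
weighted-sum scorers and Sazonov's inverted trade-off are the signatures
these algorithms show on real cohorts. `examples/04_night_benchmark.py`
runs the whole harness and prints the per-method cohort table with WASO
and sleep-efficiency errors and baseline significance tests.

A thin CLI wraps the same library calls:

```bash
sleepwake simulate --subjects 10 --seed 1 --out cohort.csv
sleepwake score -a cole_kripke --rescore --out scored.csv cohort.csv
sleepwake benchmark --task night --rescore --out report.csv cohort.csv
```

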