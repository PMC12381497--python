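# hiberlitter

Analysis pipeline for diet–hibernation–reproduction studies of food-storing
hibernators (built around the common hamster, *Cricetus cricetus*): torpor
phenology from implanted temperature loggers, nutritional intake from
feeding logs, and reproductive output from daily body temperature combined
with capture–recapture pup growth. It is aimed at ecophysiologists and
conservation biologists who monitor hibernators with iButton-style loggers
and trapping, and who need the whole chain — detection, accounting,
assignment, statistics — reproducible and testable.

## What it computes

* **Torpor bouts and phenology** — a bout is body temperature < 30 °C for
  ≥ 24 h (both configurable). At the 135-min logger sampling this means
  ≥ 11 consecutive sub-threshold samples. Isolated bouts starting more than
  15 days after the main hibernation period are excluded; per animal the
  pipeline reports total torpor time, bout count and the first-to-last-bout
  window.
* **Daily intake** — per-crop consumed mass per weighing interval is folded
  into daily food (g/d), energy (kJ/d) and macronutrient (g/d) intakes per
  period, plus the two-crop preference fraction and its signed-rank test
  against indifference.
* **Parturitions and litters** — births are abrupt rises (≥ 1 °C) in mean
  daily body temperature; detected events are numbered (litter 1, 2, …).
  Certain first-litter pups anchor per (diet, sex) linear growth models
  (mass = a + b·age); back-projected birth dates assign every pup to its
  mother's most likely parturition, keeping zero-pup litters as evidence of
  pup mortality.
* **Statistics** — one-way lm / Kruskal–Wallis comparisons with an
  auto-screen, Tukey and Dunn post hocs, Poisson GLMs for counts, random-
  intercept mixed models with marginal R² (variance decomposition
  R²m = σ²_fixed / (σ²_fixed + σ²_intercept + σ²_residual)), and AICc
  subset selection (AICc = AIC + 2k(k+1)/(n−k−1)).
* **Synthetic cohorts** — a generator emits winter traces, reproduction
  traces, capture–recapture records and feeding logs with known ground
  truth, so every stage has a recovery test.

## Worked example

```python
from hiberlitter.hibernation import (
    detect_torpor_bouts, exclude_isolated_bouts, summarize_hibernation)
from hiberlitter.synthetic import CohortConfig, simulate_winter_trace

config = CohortConfig(seed=42, n_females_per_group=1)
trace, true_bouts = simulate_winter_trace(config, 0)
bouts = detect_torpor_bouts(trace, threshold=30.0, min_duration=24.0)
retained, excluded = exclude_isolated_bouts(bouts, max_gap=15.0)
summary = summarize_hibernation(trace.animal_id, retained, len(excluded))
```

Running `python examples/01_torpor_detection.py` (the same computation)
prints:

```
animal W01: 20 torpor bouts (20 in ground truth)
total torpor      : 1809.0 h
hibernation window: 2021-10-23 -> 2022-01-16 (84.3 d)
first three bouts : 87.8 h (min 9.2 degC), 54.0 h (min 9.4 degC), 58.5 h (min 9.2 degC)
```

The detector recovered all 20 simulated bouts; this female spent 1809 h in
torpor between her first bout (23 Oct) and the end of her last retained
bout. The other scripts in `examples/` walk through intake accounting and
preference testing, parturition detection with litter assignment, the
statistical battery, and the one-call pipeline:

```bash
python examples/05_full_pipeline.py     # simulate + analyse a 32-female cohort
hiberlitter run-all --seed 42 --out-dir out/run   # same, from the shell
```

## Layout

```
src/hiberlitter/
  trace_io.py      validated CSV readers/writers, record types
  hibernation.py   torpor-bout detection, exclusion rule, phenology
  nutrition.py     intake accounting, preference fraction and test
  reproduction.py  parturition detection, growth models, litter assignment
  stats_report.py  comparisons, post hocs, GLM/mixed models, AICc
  synthetic.py     cohort generator with ground truth
  evaluate.py      recovery metrics (event matching, assignment accuracy)
  pipeline.py      run_all orchestration + deterministic manifest
  cli.py           thin command-line wrapper
examples/          one narrative script per capability
docs/methods.md    models, conventions, design choices, limitations
```
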