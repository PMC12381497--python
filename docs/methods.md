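# Methods

`hiberlitter` implements the computational chain of a mesocosm diet
experiment on the common hamster (*Cricetus cricetus*), a food-storing
hibernator: winter phenology from implanted temperature loggers, nutritional
intake from feeding logs, and reproductive output from daily body
temperature plus capture–recapture growth of pups. This note records the
models, the conventions where a choice had to be made, and what the
synthetic cohort does and does not emulate.

## Torpor-bout detection

A torpor bout is a maximal run of consecutive logger samples with body
temperature strictly below a threshold (default 30 °C) spanning at least a
minimum duration (default 24 h). Conventions:

* **Duration.** Each sample represents the interval it opens, so a run of
  k samples at the 135-min sampling period spans k × 135 min. At the
  defaults, a bout therefore requires ≥ 11 consecutive sub-threshold
  samples (1485 min ≥ 1440); 10 samples (1350 min) is not a bout.
* **Strict threshold.** A reading of exactly 30.00 °C is euthermic.
* **No merging.** Any single at-or-above-threshold sample terminates a run;
  arousals are not modelled explicitly.
* **Logger gaps.** Missing readings are kept as absent samples on the
  implied time grid and terminate runs. This is conservative: missing data
  can split a bout in two, but can never fabricate torpor.

The main hibernation period is grown greedily forward from the first bout:
a bout is retained while it starts within 15 days of the end of the last
retained bout; once the chain breaks, all later (isolated) bouts are
excluded. An alternative definition (longest chain) was considered and
rejected as needlessly complex for traces whose main period begins, as
here, at the first bout. Exclusion is idempotent, and the per-animal
summary reports total torpor (the primary phenology metric), bout count,
and the first-to-last-bout window.

## Intake accounting

Feeding logs carry the *net consumed mass* of each crop per weighing
interval; any offered/refused/hoard-change correction is upstream of this
contract. Per-crop daily intake within a named period (hibernation vs
post-hibernation, split per animal) is the summed interval mass overlapping
the period divided by period length, with boundary-straddling intervals
apportioned pro-rata by days. Energy and macronutrient intakes are linear
images of per-crop intakes through a dry-mass composition table; everything
is conserved to numerical precision by construction and tested to 1e-9.

For two-crop diets the preference fraction is the focal crop's share of
total intake. The cohort-level test of preference against indifference is
an exact two-sided Wilcoxon signed-rank test of the per-animal fractions
against 0.5 — the standard one-sample nonparametric location test for this
design.

## Parturition detection

Parturition appears as an abrupt rise (~1 °C) in mean daily body
temperature when gestation ends. Daily means use only days with ≥ 50 % of
scheduled samples recorded. The detector scores each day d by the contrast
between a post window starting at d and a baseline (pre) window ending at
d−1:

* pre window 12 d, post windows 2–4 d (the maximum contrast over post
  lengths is taken); a candidate requires contrast ≥ the jump threshold
  (default 1.0 °C);
* competing candidates are ranked by the noise-normalized contrast
  (contrast / √(1/pre + 1/post)) and accepted greedily, suppressing any
  candidate within a refractory period (default 18 d, the minimal
  gestation) of an accepted event;
* accepted events are numbered by date: litter 1, 2, …

Setting pre = post = 1 recovers plain previous-day differencing. The
windowed defaults exist because day-level noise of realistic size
(sd ≈ 0.2 °C) makes single-day differencing miss ~25 % of 1.2 °C steps,
while a 12-day baseline — which always fits inside the 18-day gestation,
so it costs no specificity — pushes per-event power to ≈ 0.96. Short post
windows are scored alongside the 4-day one because a birth followed by a
short inter-litter gap (< 22 d) has only a few elevated days before the
next gestation depresses the mean again; normalizing by window s.e. keeps
those short windows from mislocalizing events under noise.

## Growth models and litter assignment

Pups whose first capture precedes `second parturition + emergence age`
(default 18 d) cannot have emerged from any later litter and are *certain*
first-litter pups with a known birth date. Their pooled (age, mass) capture
points anchor one OLS mass-on-age line per (diet group, sex); an
under-populated stratum falls back to the sexes-pooled group fit with a
warning. The intercept is a free parameter of the linear emergence-phase
model — a surrogate for emergence mass, not neonatal mass.

Two guards protect the anchor fit from a real failure mode of the chain —
a missed first parturition silently shifting every "certain" birth date:

1. a physical-consistency screen drops pups that would have been captured
   before their assumed birth plus emergence age;
2. the fit is trimmed once at 3 robust standard deviations (1.4826 × MAD)
   around a Theil–Sen reference line before the final OLS. The Theil–Sen
   initialization matters: a misdated litter produces a *clustered* offset
   (tens of grams) that drags a plain OLS line far enough to hide its own
   outliers.

Inferred age at first capture is `(mass − intercept) / slope`, rounded to
the nearest day (clamped at 0 with a warning if mass < intercept); birth is
capture date minus age. Each pup goes to its mother's parturition nearest
the inferred birth date, ties toward the earlier litter. Every detected
parturition yields a litter record; parturitions with no attributed pup are
kept as zero-pup (failed) litters. Derived metrics: pups per female,
successful litters, litter size by litter number, inter-litter intervals,
first-parturition dates, pup sex ratio. Adults are summarized by season
mean mass; pups are censored at their first capture strictly above 140 g
(removal from the enclosure).

## Statistical battery

* `compare_groups`: one-way F test (parametric) or Kruskal–Wallis with tie
  correction (nonparametric); `auto` mode screens OLS residual normality
  (Shapiro–Wilk) and variance homogeneity (Levene) at α = 0.05 and uses
  the parametric test only if both pass. Calibration: type-I error within
  0.05 ± 0.01 at 10,000 null replicates for both modes.
* `posthoc`: Tukey HSD (scipy) or Dunn's rank-based z tests with tie
  correction, Holm-adjusted by default (Bonferroni and unadjusted
  available). Dunn is implemented in-package.
* `count_model`: Poisson log-link GLM with a likelihood-ratio group test
  and per-group rates ± s.e.m.; saturated/degenerate designs raise.
* `mixed_model`: random-intercept model; Gaussian via REML (MixedLM),
  Poisson via a variational-Bayes mixed GLM. Marginal R² follows the
  variance-decomposition convention: fixed-effect variance over fixed +
  random-intercept + residual, where the Poisson residual term uses the
  log-link lognormal approximation ln(1 + 1/λ̄) (recorded in the result's
  metadata).
* `aicc_rank`: exhaustive predictor-subset enumeration ranked by
  AICc = AIC + 2k(k+1)/(n−k−1), with the R-style parameter count for
  Gaussian models (residual variance counts in k) and Akaike weights.
* `simple_regression`: OLS slope, R², and slope t test.

All tests are two-sided at α = 0.05; dispersion is reported as s.e.m.

## Synthetic cohort

The generator emulates the study's structure — 4 diet groups (wheat W,
wheat–soybean WS, rapeseed–fava RF, maize–lablab ML) × 8 females, winter
19 Oct–19 Apr in 10 °C cages, reproduction season 19 Apr–19 Oct in
mesocosms — with fully specified ground truth. Phenomenology, not
mechanism:

* **Winter traces.** Euthermic Gaussian noise (37.0 ± 0.3 °C) outside
  bouts; in-bout temperature at ambient (10 °C) with 1-sample entry/exit
  ramps; all values quantized to the 0.06 °C logger resolution after noise,
  so detectors face realistic discretization. Bout schedule: onset ~4 d
  into winter, Poisson bout count (mean 16), lognormal durations (median
  3.5 d), arousals 12 ± 3 h. Bout count/duration distributions are a
  simulator convention chosen so per-animal torpor totals span roughly
  0–2700 h; they are not field estimates. True bouts are computed by
  scanning the noiseless profile with the same run convention the detector
  uses, so truth and detection share one definition.
* **Reproduction traces.** A 36.5 °C baseline whose daily mean drops by the
  parturition jump (default 1.2 °C) during each 18-day gestation and
  returns to baseline on the birth day; day-level noise sd 0.2 °C plus
  small within-day noise. 1–4 litters per female, first birth ~24 May
  (ML delayed 16 d), inter-litter intervals 30 ± 5 d with a 19-day floor.
* **Pups and trapping.** Litter sizes Poisson (first litters larger, scaled
  per group; zero-pup litters arise naturally), sex ratio 63.3 % male,
  linear growth (2.0–3.0 g/d by group, +0.35 g/d for males) from a 10 g
  model intercept with 5 g mass noise, emergence at 18 d, 1–2 trapping
  sessions per week shared across enclosures, 140 g removal rule, 10 % of
  pups disperse (flagged in truth). Adults are captured ~1/3 of sessions
  at group-level season masses.
* **Feeding.** Weekly intervals at period means 3.45 / 7.60 g/day
  (hibernation / post-hibernation, split at each animal's own true
  hibernation end) with 0.6 g/day animal- and interval-level spread; the
  paper-style preference fraction (0.65 soy for WS, 0.65 maize for ML, 0.5
  for RF) is drawn per interval with sd 0.10 around a per-animal mean
  (sd 0.02). The small between-animal spread is what makes the cohort mean
  recoverable to ±0.03 with 8 animals × 26 weeks, which is the generator's
  stated recovery contract.

Identical config + seed give byte-identical output files.

**What passing tests do and do not show.** The generator's traces have
stationary noise, instantaneous torpor transitions, no logger drift or
failure (unless gaps are injected), gestation depressions of fixed depth,
and exactly linear pup growth. Recovery results on this cohort demonstrate
the pipeline's correctness under its stated model — not field performance
on real loggers, where transition dynamics, shallow torpor, behavioural
temperature variation and nonlinear growth will erode the margins reported
here.

## Pipeline and determinism

`run_all` executes data → hibernation → nutrition → reproduction → stats,
writing CSV report tables, a plain-text summary, a run log and a JSON
manifest (config hash, seed, version, per-file checksums, record counts).
Stage failures abort with the stage name. The manifest deliberately
contains no wall-clock fields, so a rerun with the same config and seed is
byte-identical across every output except the log; timing lives only in
the log.

## Problem sizes used by the test suite

Checks run at sizes chosen to give stable statistics: 1,000 random traces
(≤ 2,000 samples) for detector/oracle equivalence; 100 females for
parturition recall/precision; 55 pups × 3 captures per stratum for growth
recovery; the default 32-female cohort for end-to-end assignment; 10,000
null replicates for type-I calibration; 500 replicates at n = 200 for
marginal-R² recovery.

## Known limitations

* The parturition detector assumes gestation depresses the daily mean for
  ≥ pre-window days; species with shorter or shallower gestational
  hypothermia need smaller windows (configurable) and will lose power.
* A birth followed by an inter-litter gap under ~20 days can still be
  masked by its successor's gestation (only a 1-day elevated plateau).
* The Poisson mixed model is variational, not maximum likelihood; its
  p-values and R²m are approximations.
* Maternity is an input (the study resolved it genetically); the package
  does not infer parentage.
* Growth is modelled as linear over the trappable age range; the intercept
  has no biological meaning below emergence age.
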