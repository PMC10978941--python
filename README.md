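# pmdarith

Single-neuron and population analysis of **arithmetic-to-motor coding in
dorsal premotor cortex (PMd)**, with a synthetic task and spike-train
generator that makes every stage verifiable against planted ground truth.

The package is aimed at systems neuroscientists analysing single-unit
recordings from numerical-operation tasks: a monkey transforms a
*preoperational* numerosity (0–6 items) into a remembered *target* (1–4) by
incremental addition or subtraction with hand-held devices, under block-wise
rules that map hands to operations (rule 1: left adds; rule 2 reversed). A
second, instructed task (+/− cues over preoperational numerosities 1–3)
dissociates arithmetic from magnitude comparison.

## What it computes

* **Trial model** (`pmdarith.task`) — factor labels per trial: arithmetic
  (addition/subtraction), hand (left/right), step (1/2), derived from
  conditions and the active rule; minimum-step trial filters; the 19-pair
  condition set.
* **Behaviour** (`pmdarith.behavior`) — selection-rate matrices, exact
  upper-tail binomial tests vs chance, Gaussian tuning fits whose σ indexes
  decision noise, the numerical size-effect regression (σ vs target), exact
  McNemar consistency tests, and the reaction-time congruency contrast.
* **Encoding** (`pmdarith.encoding`) — per cell and 100-ms bin,
  `rate = β₀ + β₁·arithmetic + β₂·hand + β₃·step + β₄·stimulus` with
  significance at p < 0.01; *coding histories* (cumulative factor sets per
  period); the instructed-task filter (`rate = β₀ + β₅·instruction`); cell
  categories and the exclusive-arithmetic tracking with McNemar statistics.
* **Population ROC** (`pmdarith.roc`) — sliding-window AUC selectivity per
  factor (0.5 = none; >0.5 prefers addition/right/1-step), 95% confidence
  ellipses of the AUC cloud (χ²₀.₉₅(2) = 5.991 contour), relative-variance
  time courses, permutation selection of simultaneous arithmetic×hand coders
  and their quadrant time courses (the addition↔right-hand bias).
* **Decoding** (`pmdarith.decoding`) — balanced pseudopopulations (10 trials
  per target×arithmetic×hand condition, 160 pseudotrials), temporal
  cross-training with a linear maximum-margin classifier under tenfold CV
  (24×24 = 576 train/test windows), 1000-shuffle permutation significance,
  cross-operation classifier reuse (addition↔right mapping) and
  prospective/diagonal/retrospective binomial summaries.
* **Synthetic data** (`pmdarith.synth`) — Poisson spike counts from planted
  cell profiles (baseline × (1 + Σ gain·sign·window)), behavioural choices
  with a numerical size effect, and named presets (`paper_like`, `null`,
  `snarc_reuse`, `uncoupled`, `static_code`) with ground-truth tables.

## Worked example

```bash
python examples/06_cross_operation.py
```

builds a 36-cell population whose early arithmetic code is re-expressed late
as a matched-sign hand code, trains arithmetic classifiers at every 100-ms
window and reuses them to score hand labels:

```
diagonal     :   0/24 windows significant (0.0%), binomial p = 1
prospective  : 113/276 windows significant (40.9%), binomial p = 1.52e-71
retrospective:   9/276 windows significant (3.3%), binomial p = 0.936
```

Prospective transfer far above the 5% pixel-chance level while the diagonal
and retrospective regions stay at chance is the signature of motor-code
reuse: the arithmetic classifier predicts *future* hand use. The other
examples (`examples/01`–`05`) walk through simulation, the behavioural
battery, coding histories, ROC population dynamics and within-system
decoding the same way.

A thin CLI wraps the full pipeline:

```bash
pmdarith all --preset paper_like --seed 7 --outdir run1
```

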