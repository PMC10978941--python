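# Methods

This note documents the models, conventions and numerical choices behind
`pmdarith`, and what the synthetic benchmarks do and do not establish.

## Task and trial model

Trials follow the fixed epoch schedule fixation 800 ms → target 700 ms →
delay 1 1000 ms → preoperational numerosity 700 ms → delay 2 1000 ms → Go.
All neural analyses use the **concern period**: preoperational onset through
700 ms after Go, 2400 ms split into 24 half-open 100-ms bins `[t, t+100)`.
Bins 0–16 are aligned to preoperational onset and 17–23 to Go; with the
canonical timing (Go at +1700 ms) the two stretches tile seamlessly.
Analysis periods: preoperational = bins 0–6, delay 2 = bins 7–16,
operation = bins 17–23.

The numerical condition set is every (target 1–4, preoperational 0–6) pair
with |target − preop| ≤ 2 *including* matched (hold) pairs — exactly 19
pairs. Hold trials and |Δ| > 2 trials carry `valid=False` labels and drop
out of factor-labelled analyses; the set is configurable
(`task.enumerate_conditions`). Analyses use correct trials executed with the
minimum number of device uses; the optional extreme-preoperational exclusion
drops preop ∈ {0, 5, 6} (the forced-choice conditions). Factor labels:
arithmetic = sign(target − preop) (instructed task: the cue), hand = the
device the rule assigns to that operation, step = |Δ| ∈ {1, 2} (instructed:
the executed single step).

## Synthetic generator (the study conditions)

**Rate model.** Each cell has baseline rate b (default 10 spikes/s) and
per-factor effects (gain g, window [on, off) ms):
`rate(bin) = max(0, b·(1 + Σ_f g_f·s_f(trial)·1[bin ∈ window_f]))`, with
s_f = +1 when the trial matches the preferred level (positive gain ⇒
addition / right / 1-step / standard). Counts per bin are Poisson(rate × 0.1 s),
one RNG stream per (master seed, cell id) so populations are bit-reproducible
and invariant to population size. Default |g| = 0.5: a 15 vs 5 spikes/s
contrast, a strong but realistic premotor effect size. Reaction-time jitter
is not applied to bin alignment (Go is fixed at 1700 ms after preoperational
onset), since operation-period bins are Go-aligned anyway.

**Population composition** (`paper_like`, 539 cells by default, fractions
scale to any size): 125/539 arithmetic-selective, split into 16 purely
arithmetic throughout (window 100–2400 ms), 35 transitioning to hand
(arithmetic 100–700, hand 1700–2200), 16 transitioning to step (step
2100–2400), and 58 simultaneous arithmetic+hand coders (arithmetic
100–1700, hand 400–2100). 72 further cells carry the arithmetic contrast in
the numerical task only (`comparison_only`) — the instructed-task filter
should reject them. Hand-related cells during the preoperational period
total 83 (58 simultaneous + 25 hand-only) and step-related 89. A
`snarc_fraction` (default 0.7) of cells with both arithmetic and hand
effects have matching signs under the addition↔right convention. The window
layout makes the planted dominant axis arithmetic in the early
preoperational bins, hand in the operation period and step in the last
~300 ms, which is what the ellipse and relative-variance benchmarks check.

**Behaviour.** Numerical-task choices are `round(N(target, σ(target)))`
clipped to 0–6 with σ(t) = 0.3 + 0.12·t: ~77% correct at target 1 falling
to ~47% at target 4 (chance 25%), a realistic size effect. Instructed
choices step once in the cued direction with 5% lapses and 15% two-step
overshoots (magnitude-independent spread, so no size effect). RTs are
Normal(450, 60²) ms with a 30-ms congruency advantage for
addition-by-right / subtraction-by-left responses. Behavioural statistics in
tests use trial-only simulations (~4000 trials), matching the fact that
behavioural datasets are far larger than any single cell's trial count.

**Decoding presets** use exactly balanced trial sets (reps per
target×arithmetic×hand condition with feasible steps and the rule chosen to
realise the hand): `snarc_reuse` plants arithmetic at 100–1700 ms and a
matched-sign hand code at 1700–2400 ms; `uncoupled` uses the same windows
with the four sign pairs cycled exactly (counterbalanced, so the
population-level arithmetic→hand transfer cancels by construction rather
than only in expectation — with iid signs a 36-cell population can transfer
by chance imbalance); `static_code` plants a constant arithmetic code;
`null` plants nothing (200 cells, 160 trials).

**What the generator does not emulate:** trial-to-trial rate correlations
and shared noise, non-Poisson spiking, rate drift, RT-locked response
transients, error-trial activity, and eye movements. Passing benchmarks
therefore establish correctness and calibration of the *analysis chain*,
not robustness to those real-data features.

## Encoding analysis

OLS per cell × bin of firing rate (count/0.1 s) on four dummy regressors
(addition/right/1-step/standard = 1; the significance pattern is invariant
to the assignment). Two-sided coefficient t-tests; a factor is significant
in a bin at p < 0.01. No multiple-comparison correction is applied across
bins — the coding-history rule is deliberately "any significant bin per
period", with a stricter most-significant-bins (`dominant`) rule available.
A consequence worth knowing: over the 17 post-preoperational bins × 2 motor
factors, a truly static arithmetic cell has a 1 − 0.99³⁴ ≈ 29% chance of
picking up a spurious motor flag, so cumulative exclusive-arithmetic counts
always erode at α-level even without planted transitions (cumulative
histories can only lose exclusivity; the McNemar discordance is one-sided by
construction). The benchmarks therefore compare the *size* of the drop
against this closed-form floor. Factors with fewer than 5 trials per level
(configurable) are unestimable and reported NaN, not imputed. The
instructed-task filter regresses instruction-period bins 0–6 on the +/− cue
and keeps candidates significant in ≥1 bin.

## ROC and population summaries

AUC is the normalised Mann–Whitney U (ties count ½), computed for all
cells × bins from one tie-averaged rank matrix. Confidence ellipses are
sample mean/covariance with the 95% contour at Mahalanobis² = 5.991; θ is
the principal-axis angle folded into [0°, 90°] relative to the first-named
factor, so axis exchange maps θ → 90° − θ. Relative variance divides each
bin's across-cell AUC variance by the factor's mean variance over bins
(series mean exactly 1). Simultaneous-coder selection uses, per factor, the
concern-period max |AUC − 0.5| against 1000 label-shuffle nulls (shuffles
reuse the rank matrix, so the null is one tensor contraction);
p = (1 + #{null ≥ obs})/(1 + n_perm), selection at p < 0.05 on both
factors. Cells at exactly AUC = 0.5 on an axis are excluded from that bin's
quadrant partition. Within right-hand coders the per-bin binomial test is
upper-tail on addition preference (left-hand: on subtraction); series-level
significance counts p < 0.05 bins against a 5% chance rate.

## Decoding

The classifier is a linear maximum-margin model
(scikit-learn `LinearSVC`, C = 1.0, primal liblinear, tol = 10⁻²,
max_iter = 2000); the loose tolerance changes pixel accuracies by < 4
percentage points on separable data and nothing systematically, while
making the tens of thousands of permutation refits tractable. Features are
per-cell z-scores using training-split statistics only. The fold partition
(tenfold, stratified by the 16-way condition) is fixed per grid so all 576
pixels share splits; each pseudotrial is scored by the fold that held it
out. Permutation significance shuffles labels once per replicate and reuses
the shuffle across pixels (per-pixel shuffles would be 576× the cost). The
null refits the classifier on shuffled training labels each replicate; for
cross-operation grids the refit predictions are scored against the true
mapped test labels. The refit matters there: classifier weight-estimation
noise projects onto the alternative code's direction, producing incidental
"transfer" whose variance is independent of population size — a null that
holds predictions fixed and shuffles only the tested labels (available as
`refit=False`) does not see that variance and is anti-conservative at the
series level. A pixel is significant when observed
accuracy strictly exceeds the round(0.05·n_perm)-th highest null value
(ties non-significant), and p = (1 + #{null ≥ obs})/(1 + n_perm). The
cross-operation mapping must be a bijection; the identity mapping
reproduces the within-system grid bit-exactly, and reversing the mapping
complements every accuracy (a → 1 − a).

## Problem sizes in the benchmarks

Chosen to keep the default suite within desk-scale runtimes: null
calibrations at 200 cells × 160 trials with n_perm = 200; classification
recovery at 450 cells (single run) and 160 cells (50 runs); dynamics at the
full 539 cells (single run); cross-operation asymmetry at 36 cells on a
12×12 bin subgrid, 20 runs (plus 5 counterbalanced-control runs); the
shuffled-label null mean at 72 cells × 160 pseudotrials × 1000 shuffles.

## Known limitations

* Inclusion in a pseudopopulation is per cell via an availability mask, but
  synthetic sessions share one trial pool, so inclusion is effectively
  population-wide there.
* Gaussian tuning fits need ≥3 populated choice bins; extreme clipped rows
  (e.g. instructed preop 1 with a minus cue) are flagged unconverged and
  excluded from the size-effect regression.
* The exact McNemar test on cumulative coding histories is structurally
  one-sided (see above); its p-value quantifies the drop but the symmetric
  null can never be literally true for cumulative sets.
* The quadrant time course assigns preference by AUC sign per bin;
  significance-based assignment is a reasonable alternative the analysis
  does not implement.
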