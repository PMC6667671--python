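# Methods

## Generative observer model

Each two-alternative trial draws an internal response
x ~ N(+M/2, σ_I) when the true alternative is A and N(−M/2, σ_I) when it is
B. The observer responds "A" iff x ≥ 0 (an unbiased criterion; the
probability-zero tie goes to A). The confidence variable is
c = x + ε, ε ~ N(0, σ_II); σ_II = 0 makes decision and confidence share one
signal (single-stage model), σ_II > 0 adds an independent confidence stage
(dual-stage model). Ratings 1–4 are assigned by which quartile of the
pooled |c| distribution the trial falls in, so each rating is used on 25%
of trials up to rounding; ties at a boundary take the lower rating. Stage-1
and stage-2 noise use separate RNG streams derived from one seed, so
changing σ_II with a fixed seed cannot alter any decision.

Closed forms used throughout: accuracy = Φ(M/2σ_I); Type-I AUC
= Φ(M/(σ_I√2)). Everything the model produces depends only on the ratios
M/σ_I and σ_II/σ_I (scale invariance), which is what makes "Type-II AUC at
clamped Type-I AUC" a one-parameter family in σ_II/σ_I.

A model variant is exposed in which learning multiplies M (signal
enhancement) instead of shrinking σ_I; the two are indistinguishable in
Type-I terms (only M/σ_I matters) but differ in how Type-II behaves when
σ_II is fixed in absolute units.

### Estimator bias worth knowing about

The rating ROC has 7 interior points (Type-I) or 3 (Type-II); its
trapezoidal area is a slightly *negatively* biased estimator of the
underlying continuous ROC area (deficit up to ≈ 0.005 near AUC 0.92–0.98,
larger if ratings are noisy). Tests therefore compare the continuous-score
Mann–Whitney AUC against the Gaussian closed form, and the rating
trapezoid against its own analytic expectation (computable exactly from
normal CDFs at the population quartile boundaries). For the same reason,
adding stage-2 noise leaves response-level hits and false alarms exactly
unchanged but compresses the Type-I rating trapezoid slightly (≤ 0.05 at
σ_II ≤ σ_I) by scrambling the rating-level criteria.

## AUC surfaces and their correlation

`compute_surface` simulates each cell of an (M, σ_I) grid with its own
deterministic child seed (5,000 trials per alternative by default) and
records both AUCs; cells with no errors have undefined Type-II AUC and are
stored as missing. The default grid — 65 levels of M over [0, 6.5] × 65
levels of σ_I over [0.5, 2] — was chosen so that the single-stage surface
correlation is ≈ 0.99 and the dual-stage correlations at
σ_II = 0.5/0.75/1 are ≈ 0.97/0.93/0.89, the canonical pattern of
progressive decoupling. The single-stage value is insensitive to the
ranges, but the dual-stage values are sensitive to the σ_I range, because
that range sets the spread of σ_II/σ_I across the grid (e.g. σ_I ∈ [1, 2]
raises the three correlations to ≈ 0.98/0.97/0.95). Both ranges are plain
arguments, and surfaces export to a flat table for inspection.

## QUEST staircase

The posterior over thresholds T lives on a discrete grid (201 points;
1–100% morph, or −3–0 log10 contrast difference) with a Gaussian prior.
The psychometric model is the Watson–Pelli Weibull
ψ(d) = γ + (1−γ−δ)(1 − exp(−10^{β(d+ε)})), with ε set so ψ(0) equals the
target accuracy (0.75); T is therefore directly the 75%-correct intensity,
trials are placed at the posterior mode (mean/median exposed as options),
and the mode is also the offline threshold estimate. Per-task parameters:
β = 0.1, δ = 0.05, γ = 0.5 on the percent-morph scale for the identity
task (β kept as printed even though it is atypically shallow for a
Weibull slope), and β = 3.5 on the log-contrast scale for the contrast
task. Morph intensities are rounded to the nearest 2% and capped at 100%
(floored at 2%); contrast thresholds are linearized as 10^T and both
stimuli sit at midpoint ± difference/2.

Because Bayesian updates are pointwise products, rebuilding a posterior
from a trial window equals sequential updating on those trials — the
block-to-block mode exploits this: intensity is fixed within each 20-trial
block and recomputed between blocks from the trailing 80 trials of that
condition (day 1 block 1 uses the last 80 pre-training trials, block 2 the
last 60 pre-training + 20 block-1 trials, and so on). Baseline blocks on
days 2–3 run trial-to-trial from a posterior seeded with the trailing
window; pre/post staircases are independent 40-trial runs from the fresh
prior.

**Prior placement matters.** The prior is centred near the anticipated
threshold (35 ± 15% morph; −0.8 ± 0.5 log contrast), as experimenters do
from piloting. This is not cosmetic: the Gaussian observer's psychometric
function is several times shallower than the β = 0.1 Weibull the staircase
assumes, so corrections undershoot and a staircase started far above
threshold (say at 50% morph) takes days to descend, dragging accuracy — and
hence Type-I AUC — down across sessions and destroying the clamp the
protocol exists to provide. With a threshold-anchored prior, a static
observer is clamped at 75 ± 1% from the first day.

## Synthetic observers and learning

Physical stimulus difference maps linearly to internal separation,
M = gain × difference (gain 0.045 per % morph; 10 per unit linear
contrast difference — both place the 75% threshold at a mid-range
intensity: ≈ 30% morph, ≈ −0.87 log contrast). Learning is an exponential
decay of σ_I over cumulative training blocks t (12/day):
σ_I(t) = σ_end + (σ_start − σ_end)e^{−t/τ}, with σ_start = 1,
σ_end = 0.1 and τ = 52 (identity) / 60 (contrast). These values give
(i) a ≈ 40–45% pre-to-post threshold drop, and (ii) a near-constant
*relative* learning rate (≈ 1.7 → 1.5% per block) across the three days,
because the floor sits far below the range the experiment reaches. The
second property is essential: the staircase tracks a moving threshold with
a lag proportional to the learning rate, so a rate that decays within the
experiment (a floor inside the measured range) produces a spurious
downward Type-I trend, while a steady rate yields a constant small
elevation and a flat Type-I — the signature the clamped design is meant to
produce. Faster learning is not an option either way: it strengthens the
Type-II decline but inflates the tracking lag and its day-1 ramp, which
surfaces as spurious Type-I trends. Calibration therefore keeps learning
slow and instead places σ_II where metacognition is most sensitive.

Scenarios couple σ_II to σ_I: `identity` keeps σ_II constant at 0.85 —
the steepest region of the measured Type-II-AUC-versus-(σ_II/σ_I) curve
at clamped accuracy, giving a decline of ≈ 0.017 AUC/day as σ_II/σ_I
grows; `contrast` shrinks σ_II proportionally (ratio constant,
metacognition flat); `static` learns nothing. Untrained conditions appear
only pre/post, and their σ_I improvement is the trained improvement times
a transfer fraction (default 0.67).

Confidence quartile boundaries are maintained per condition from a running
window of the last 200 confidence-variable magnitudes (refreshed per trial
in staircase phases, per block in fixed-intensity blocks), seeded
analytically from the folded Gaussian-mixture quantiles until 40 trials
accumulate. This emulates an observer who keeps using the whole rating
scale as difficulty shifts; without it, quartiles over a drifting
intensity distribution are undefined.

Cohorts draw per-subject multiplicative log-normal jitter (CV 0.2, unit
mean) on the gain and on the noise scale (jittering σ_start, σ_end and
σ_II together, so each subject's learning *ratio* — and hence the
metacognitive trajectory — is preserved while thresholds vary).
Trained-set assignment alternates deterministically, giving exact
counterbalancing for even cohort sizes.

### What the generator does and does not emulate

It reproduces the design's trial counts, the staircase dynamics, quartile
confidence use, set transfer, and the three qualitative training patterns.
It does not model attention lapses beyond δ, sequential dependencies,
fatigue, criterion drift, or non-Gaussian internal noise; psychometric
shape mismatch between observer and staircase is present (Gaussian vs
Weibull) but only in the benign direction described above. Passing tests
therefore validate the *machinery* on a plausible observer population, not
any claim about real subjects.

## Statistical analysis

Per-block measures: QUEST-mode threshold from the block's own 20 trials,
Type-I and Type-II AUC, and confidence mean/variance (sample variance,
n−1) split by correctness. A 20-trial block at 75% accuracy has no
incorrect trials with probability ≈ 0.3%, and such blocks are common
enough across a cohort that the policy matters: undefined Type-II AUCs are
recorded as missing and dropped listwise from trend models, never imputed
at 0.5, which would bias training slopes toward null.

Pre/post thresholds: posterior mode per 40-trial staircase, averaged over
each condition's two staircases, then over the set's two conditions.
Percent improvement is (pre − post)/pre × 100 and TI is the untrained to
trained improvement ratio (undefined when the trained improvement is 0).
Single-subject TI has a noisy denominator; cohort inference uses one-tailed
one-sample t-tests of TI against 0 and 1, and pre-vs-post one-tailed
Wilcoxon signed-rank tests per set.

Day trends use linear mixed models on block-level data: fixed linear day
effect, by-subject random intercept and slope, maximum likelihood, and a
χ²(1) likelihood-ratio test against the model without the fixed day term.
The between-set random intercept of the full nested design is omitted — it
has two levels and synthetic sets are exchangeable — and fits fall back to
random intercepts only when the random-slope fit does not converge (the
fallback is flagged in the result). Optimization uses Powell's method;
statsmodels' gradient-based optimizers frequently stall on these variance
surfaces, which silently destroys LRT power.

A secondary analysis pools each day's 480 training trials into single
daily AUCs; pooling across blocks with different intensities is legitimate
for the rating ROC because ratings are calibrated within condition.

## Problem sizes and runtime

Default simulation sizes were chosen for desk-scale reproducibility: 5,000
trials per alternative per surface cell (MC SE on a cell AUC ≈ 0.003–0.006),
65×65 = 4,225 cells per surface, 20-subject cohorts (≈ 2,400 trials per
subject), and 20–25 replicate runs where rates are estimated. A full
surface takes a few seconds; a cohort with mixed-model analysis a few
seconds more; the acceptance script about a minute.

## Known limitations

* The identity-task staircase inherits the printed shallow β = 0.1, so its
  threshold estimates are information-poor per trial; estimates from 40
  trials carry meaningful noise, which inflates TI spread exactly as seen
  in real data of this design.
* The rating-trapezoid AUC bias (above) means surface values are a few
  thousandths below the continuous-model ideal; correlations are
  essentially unaffected.
* The mixed models treat day as linear; with three days this is a
  two-degree contrast and cannot detect non-monotone change.
* Exact reproduction of human effect sizes is out of reach by design — the
  synthetic effect sizes are free parameters documented here, chosen once
  for detectability at the stated cohort sizes.
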