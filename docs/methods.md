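# Methods

## Data model

A sleep log is a 14-day diary of one child's sleep periods plus three daily
flags (breakfast eaten, woke by self, parent-reported night wakings). The
working representation is a 14 × 288 binary epoch grid — 5-minute epochs,
0 = asleep, 1 = awake — with a *logical day* anchored at 03:00 covering
decimal hours [3.0, 27.0). The anchor keeps both transition windows (wake
3–10 h, bed 18–26 h) inside one logical day, and represents times after
midnight on a 24h-extended scale (1:27 am → 25.45), so bed-time statistics
are computed on a continuous scale with no wraparound.

Rasterization resolves intervals on a 1-minute mask (diary times are whole
minutes, so this is exact) and marks an epoch asleep iff all five of its
minutes are covered; partial coverage counts as awake. This is deterministic
and conservative: a recorded 22-minute nap contributes at most 4 asleep
epochs. Overlapping intervals are treated as contradictory records and
rejected. A logical day with no interval rows and no flag row is *missing*;
features average over non-missing days, and screening rejects children with
more than 3 missing days (configurable — the study population excluded
incomplete records without stating a threshold, so a tolerant default was
chosen).

The nocturnal window 19:00–09:00 spans two logical days, so only the 13
night windows fully inside a 14-day log are used for nocturnal statistics;
no extrapolation past the recorded span is attempted. The final night is
clipped at the grid edge (27:00 of day 14).

## Sleep variables

Ten variables per child:

| variable | definition | units / range |
|---|---|---|
| wake_up_time | `c` of the rising sigmoid fit, window (3, 10) | decimal hours |
| wake_up_time_variation | `d` of the same fit | hours, > 0 |
| bed_time | `c` of the falling fit, window (18, 26) | decimal hours, 24h-extended |
| bed_time_variation | `d` of the same fit | hours, < 0 |
| total_sleep_duration | mean asleep time per logical day | h, [0, 24] |
| nocturnal_sleep_duration | mean asleep time in 19:00–09:00 | h, [0, 14] |
| night_wakings | mean awakenings per night | count ≥ 0 |
| evening_nap | mean sleep episodes intersecting 15:00–19:00 | count/day |
| breakfast, self_awake | mean of the daily binary flags | fraction [0, 1] |

The *sleep–wake rate* curve is the per-epoch mean of the awake state over
observed days. The four-parameter logistic
`y = a + (b − a)/(1 + e^{(c−x)/d})` is fitted to it by bounded nonlinear
least squares (Gaussian maximum likelihood on the averaged curve, which is
the object being modeled; per-day Bernoulli likelihoods are not used).
`c` is the point-symmetry time — where sleep and wake are equally likely —
and `d` measures day-to-day schedule spread: for transition times i.i.d.
normal with SD σ, the rate curve is a normal CDF, and the best logistic
match has |d| = σ·√3/π (variance matching of the logistic and normal). For
a constant schedule the curve degenerates to a step and |d| → 0. Wake fits
constrain d ∈ [10⁻⁴, 2]; bed fits reuse the same machinery with
d ∈ [−2, −10⁻⁴] rather than mirroring the curve, which makes the reported
bed-time variation negative by convention.

Numerical choices: parameters start at a₀ = 0, b₀ = 1 (the asymptote roles
follow the sign of d, so this start serves both directions), c₀ = the first
grid time where the rate crosses 0.5 (window midpoint if it never does),
|d₀| = 0.25; bounds a, b ∈ [−0.2, 1.2], c within the window. Nonlinear
logistic fits are sensitive to starting values, so the estimate is
stabilized by refitting `n_repeats = 100` times with i.i.d. uniform jitter
on [−0.01, +0.01] added to every rate value and averaging the converged
repeats (an initial unjittered fit warm-starts the repeats). Fewer than 50%
converged repeats, or a curve with range < 0.1 (no transition in the
window), is a fit failure reported with the offending variable's name. With
jitter 0 the procedure is exactly reproducible regardless of seed; with the
default jitter the across-seed SD of `c` is below 0.01 h.

Night wakings prefer the parent-reported nightly counts when present for at
least half the nights — clinically reported counts are what the screening
variable means — and otherwise fall back to counting maximal awake runs
strictly between sleep onset (first asleep epoch after 19:00) and final
awakening (last asleep epoch before 09:00). Evening nap is an episode
count, not a time fraction: its observed population maximum (1.62/day)
exceeds 1, which a fraction cannot reach.

## Age groups and classification

Nine developmental age groups: 0–2, 3–5, 6–9, 10–14, 15–18, 19–47, 48–59,
60–71, 72–83 months. For groups 1–8 the packaged bank holds Fisher linear
classification functions — per class, coefficients Σ⁻¹μ_g and constant
−½μ_gᵀΣ⁻¹μ_g + ln π_g — transcribed at their published 3-decimal precision.
Judgment is 1 ("no severe disorder") iff y1 > y0; the measure-zero tie is
resolved to 0 so borderline cases surface for review. Group 0 raises an
"unsupported group" error: newborn sleep is too irregular and the reference
sample too small for a classifier, so those children are referred for
direct clinical review. The group-6 variable set follows the coefficient
tables (wake-up-time variation) where the surrounding narrative text
disagrees; tables are taken as authoritative.

Bank files use the canonical feature field names (human-readable labels are
also accepted and mapped on load), and `save → load` round-trips
coefficients bit-exactly via `repr` serialization.

## Training pipeline

Two-group discriminant analysis per age group:

1. **Stepwise selection.** At each step the candidate minimizing Wilks'
   lambda Λ = det(W)/det(T) enters if its partial
   F = (n−2−p)·(Λ_p/Λ_{p+1} − 1) ≥ F_enter; then any included variable
   whose partial F fell below F_remove leaves. Defaults F_enter = 3.84,
   F_remove = 2.71 (conventional stepwise defaults; only the Wilks
   criterion and the 20-step cap are prescribed), both configurable.
   Variables with pooled within-group variance < 10⁻¹² are dropped from
   candidacy before selection (singularity guard). Note the type-I
   consequence of F_enter = 3.84 ≈ the 5% point of F(1, ∞): each truly
   uninformative variable still enters with ~5% probability, so on null
   data the selection frequency matches the per-step type-I rate rather
   than zero.
2. **Canonical statistics.** For two groups W⁻¹B has rank 1, so the
   eigenvalue is computed as λ = tr(W⁻¹B); Λ = 1/(1+λ),
   R = √(λ/(1+λ)), and Bartlett's χ² = −(n−1−(p+2)/2)·ln Λ with p degrees
   of freedom, p = number of selected variables.
3. **Fisher functions.** Pooled within-group covariance W/(n−2); priors
   default to equal (making the rule identical to Mahalanobis
   nearest-centroid, and to the canonical-projection midpoint rule),
   optionally proportional to group sizes. Retrained constants cannot be
   expected to match the published bank numerically: the published
   coefficients come from a clinical dataset that is not redistributable.
4. **Leave-one-out accuracy** ("cross-validation" in screening parlance):
   each case is classified by Fisher functions refitted on the other n−1
   cases; a fold whose training set loses a class is an error.

## Synthetic cohorts

The generator emulates the study conditions: children per age group × class
keeping a 14-day diary. Each child draws a habitual bed and wake time from
the group profile (`*_between_sd`, default 0.45/0.40 h), then 14 nightly
times around those habits (`*_day_sd`), Poisson night wakings placed
uniformly inside the night (10–15 min each), Bernoulli evening naps
(45 min) and daily flags. The two dispersion scales matter: the day-to-day
SD is what the variation parameters |d| track, while the between-child SD
sets the class overlap that training sees; the observed population SDs
(e.g. bed time 0.69 h across children vs. a mean variation of 0.26) imply
both are present, and collapsing them to one scale would make
leave-one-out accuracy degenerate (every child's 14-day mean would pin its
class almost exactly).

Non-severe profiles are anchored at the modal 19–47-month group to the
observed population means (wake 6.84, bed 21.44) and shifted along the
known developmental gradients for other ages (younger: earlier bed, more
night wakings, more naps, less breakfast routine). Severe profiles violate
the clinical severity criteria at the generative level — habitual sleep
onset 23:00 (> 22:30), 3.5 expected wakings/night (> 3), day-to-day SD
1.1 h (> 60 min) — so labels are noiseless class indicators. Day 0 is
given the tail of the night in progress (sleep from 03:00 to the first
waking) so all 14 days contribute a wake transition, as a real diary
would. Day-level draws are independent (no autocorrelation): the variation
features measure only marginal day-to-day spread. Per-child seeds derive
from (global seed, group, label, index), so results are independent of
cohort ordering.

What passing synthetic tests does *not* show: real diaries have weekly
structure, reporting error, age-dependent nap architecture and correlated
nights, none of which are modeled; accuracies obtained on synthetic
cohorts say nothing about clinical accuracy on real populations.

## Verification and problem sizes

The acceptance script (`scripts/acceptance.py`) recomputes: the published
statistics' internal identities (8 age groups; agreement ≤ 0.2% is
limited by the 3-decimal printed inputs); the group-1 Fisher scores at bed
time 21.0/23.0 and the implied decision boundary 22.292 (exact to printed
precision); sigmoid recovery (exact curves to 10⁻³, step inputs to one
epoch with d ≤ 0.02, the σ√3/π relation within 15% on 500 simulated
days); oracle equivalence on 1,000 random small datasets (Λ vs. explicit
det-ratio to 10⁻¹⁰, Fisher vs. Mahalanobis labels, stepwise vs.
exhaustive same-size best subset on 200 replicates of p = 4, n = 60); and
an end-to-end run on a 400 + 400 cohort whose classes differ only in
habitual bed time (21.4 vs. 23.0, between-child SD 0.5) — leave-one-out
accuracy is compared against the analytic two-class Bayes rate
Φ(Δ/2σ̂) at the realized feature moments, and a sweep of deterministic
sleepers in 5-minute steps locates the screening flip boundary to
rasterization resolution. These problem sizes keep the full script at a
few minutes on one CPU while leaving Monte-Carlo noise well inside the
stated tolerances.

## Known limitations

- The sigmoid windows are fixed; a child who routinely wakes before 03:00
  or falls asleep after 02:00 cannot be characterized and is reported as a
  fit failure rather than extrapolated.
- Whether the population night-waking statistic was parent-reported or
  grid-derived is not documented; the reported column is preferred when
  present, which is a choice, and the two can differ when parents
  under-report brief awakenings.
- The published coefficient bank is applied exactly as printed; no
  recalibration to local populations is attempted, and probability
  calibration / ROC analysis is out of scope.
- Retraining is procedure-faithful, not coefficient-faithful: the exact
  stepwise thresholds and priors behind the published bank are not
  documented, and the clinical training data are unavailable.
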