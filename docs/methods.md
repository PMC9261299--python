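# Methods

## The movement clock

`accelage` estimates biological age from one week of minute-level
accelerometer intensity counts of the kind collected by hip/thigh-worn
ActiGraph-type devices in large surveys (NHANES 2003–2006 layout:
participant id, calibration flag, day 1–7, minute index, intensity).

**Quality control.** A participant's week enters the model only if (a)
every record carries the calibrated status code, (b) all 7 × 1440
minutes are present, (c) every day has at least 10% of minutes with a
strictly positive count (≥ 144 of 1440; ties pass), and (d) the
participant is 18 or older. The 10% rule is evaluated per day — all
seven days must pass — and the exclusion log records the first rule that
fired for each dropped week, so the per-week alternative reading stays
auditable.

**Features.** Each retained week is reduced to 336 numbers: for every
(day, hour) cell, the maximum intensity (counts) and the sample variance
(counts², denominator n − 1) of that hour's 60 minutes. Hours are clock
hours of the wear day (hour *h* covers minutes [60h, 60h + 60)). The
column order is fixed: all `max_d{day}_h{hour}` day-major/hour-minor,
then all `var_d{day}_h{hour}`. Sample rather than population variance is
a documented, reproducibility-relevant choice; the two differ by a
factor 59/60 and would not change any rank-based result.

**Regressor.** A random forest (default 500 trees, a third of the
features considered per split — the classic regression default —
`n_jobs=1`, seed-fixed) is trained on features centered and scaled with
training-set statistics only; the standardization parameters are frozen
on the fitted clock and reapplied unchanged at prediction time, so no
information leaks from evaluation data. Constant features get scale 1
with a logged warning. Feature importance is the percent increase of
held-out MSE when one feature column is permuted (%IncMSE), averaged
over `n_repeats` (default 10) permutations; computing it on held-out
data rather than out-of-bag keeps the measure model-agnostic.

**Normalization and delta-age.** Tree ensembles compress the age range
(young overpredicted, old underpredicted), so raw predictions are
rescaled against peers:

    norm_i = raw_i / median({raw_j : |chron_j − chron_i| ≤ w}) × chron_i
    delta_age_i = norm_i − chron_i

with peers including the individual themself. Positive delta-age means
movement that looks older than one's peers (accelerated aging). The
peer window *w* defaults to ±2 years and is configurable. With *w* = 0
(peers = the same-age group) the formula *forces* the median delta-age
inside every age group to zero (odd group sizes; even sizes bracket
zero), and a clock whose only error is a scale factor is corrected
exactly. With *w* > 0 these identities hold only approximately near the
ends of the age range, where peer windows are asymmetric; the identity
checks therefore run at *w* = 0, the pipeline default stays ±2 for
robustness to thin age groups.

A genuine limitation at the top of the range: ages are top-coded at 85
("85+"), so the clock's response to effective age flattens there and
delta-age shrinks toward zero for the oldest participants — no amount of
median rescaling restores a slope the training labels never contained.
Consequently the oldest, highest-mortality participants concentrate in
the "normal" aging class, which inflates that class's death rate. The
accelerated-vs-decelerated contrast is unaffected.

## Mortality association

Participants aged ≥ 60 (where deaths are frequent enough) are split on
the quartiles of delta-age: top quartile accelerated, bottom quartile
decelerated, middle half normal (linear-interpolation quantiles; ties at
a cutpoint go to the extreme class so extremes are never empty). The
association with vital status is a Pearson chi-square test of equal
death proportions across the three classes (df = 2, no continuity
correction — the classic 3-sample equality-of-proportions test);
participants with unknown vital status are excluded and counted in the
log. Decade-resolved tests compare delta-age between deceased and alive
within half-open decade bins ([18,30), [30,40), …, [80,85+]; [30,40) is
the "4th decade of life") using the equal-variance two-sample t-test
(a Welch switch exists but the equal-variance form is the default);
bins with fewer than two members on a side are flagged untestable, not
errors. Cause-of-death groups (≥ 2 members) are compared against the
presumed-alive (not recorded deceased, or deceased with no cause found)
by mean delta-age shift with the same t-test, sorted by shift.

## Nutrient and drug screens

**Nutrients.** For every dietary component and every decade bin, the
Pearson correlation between intake and delta-age (cells need ≥ 3
observations and nonzero intake variance; anything else is left missing
and logged, never imputed). Benjamini–Hochberg adjustment is applied
within each decade bin across nutrients — the correction scope is a
config option since pooling across bins is equally defensible. The
nutrient × decade correlation profiles are grouped by agglomerative
hierarchical clustering (Euclidean distance, complete linkage, cut at
k = 5), dropping profiles with missing cells. A complementary
extreme-group test compares intake between strongly decelerated
(delta < −10 y) and strongly accelerated (delta > +10 y) participants
with the equal-variance t-test; identical constant intake on both sides
is reported as t = 0, p = 1.

**Drugs.** Restricted to ages 70–85+ (where prescription use is
prevalent), each drug with at least one user is tested by a two-sample
Kolmogorov–Smirnov comparison of its users' delta-ages against the
*whole* subset's delta-ages — users included in the comparison
population, the conservative reading; a users-vs-nonusers switch
exists. A participant contributes once per distinct drug. Drug names
are normalized on ingestion (uppercase, trimmed, trailing salt suffixes
such as MESYLATE stripped) so salt variants merge. Each row carries the
median shift (users minus comparison population), the KS p, the
BH-adjusted p across all drugs tested, and

    rank_score = log10(ks_p) × sign(median_shift).

Because log10(p) < 0, *decelerating* drugs (negative shift) get
*positive* scores; "most decelerating" = largest rank_score, and the
screen table is sorted that way.

## The synthetic cohort generator

The generator exists so that every stage has a recoverable ground
truth without any survey download. One latent variable ties the tables
together: frailty *f* ~ Normal(0, `frailty_sd`) shifts a participant's
effective movement age to age + *f*; movement, mortality, nutrient
intakes and the planted drug effect are all functions of it, so each
downstream association is a testable consequence of one knob.

* **Activity.** Minute counts follow a zero-inflated negative binomial:
  a minute is active with probability wake(hour) × (1 − 0.006·(e − 18))
  (near zero in sleep hours), and an active minute's count is
  gamma-Poisson with mean base · circadian(hour) · exp(−0.012·(e − 18)),
  where e is effective age. Older effective age thus lowers both hourly
  maxima and variances, most visibly in the high-activity afternoon. A
  per-person log-normal multiplier (`lifestyle_sd` = 0.05) adds
  age-independent sedentary-vs-sporty heterogeneity so the clock is not
  artificially perfect.
* **Mortality.** Death is Bernoulli with logit −13.75 + 0.18·e, giving
  a ~35% death fraction among 60+ and a hazard that responds to frailty
  as strongly as to calendar age; ~2% of participants are
  linkage-ineligible (unknown vital status). Among the deceased, a
  respiratory cause label is assigned with probability increasing in
  frailty, the rest uniformly.
* **Nutrients.** A planted component's intake is
  base + β(decade) · (−f/`frailty_sd`) · 0.5·sd + Normal(0, sd) noise,
  so β = 1 contributes half a nutrient-SD of frailty-linked signal
  regardless of the frailty scale. The default table has one
  late-peaking fiber-like component (β maximal in the [50,60) bin), one
  moderate companion, and eleven null components.
* **Drugs.** Each drug has a usage rate (interpreted at age 70+,
  tapering linearly for younger participants, matching the rise of
  prescription counts with age) and a frailty shift; the default table
  plants one geroprotector, DOXAZOSIN, at 2% usage and −6 y shift —
  users' frailty drops by six years *before* activity, mortality and
  diet are drawn, so the effect propagates end to end — plus twelve
  null drugs at realistic usage rates. A fraction of prescription rows
  carry a salt suffix to exercise name normalization.

One RNG stream per output table (spawned from the master seed) keeps
tables independent: resizing the drug table never perturbs activity
draws, and a fixed seed reproduces byte-identical files.

**Choosing the default conditions.** The planted effect sizes (−6 y
drug shift at 2% usage; the late-peaking nutrient profile) are the
generator's reference conditions. Detectability analysis during design
fixed the remaining free knobs: delta-age transmits frailty with slope
≈ 0.6–0.8, so the population delta spread is bounded below by
slope × `frailty_sd`, and a −6 y shift can only be a reliably
top-ranked KS hit if `frailty_sd` is well below 6 — hence the default
`frailty_sd` = 3 y with `lifestyle_sd` = 0.05. These defaults make the
synthetic clock cleaner (held-out r ≈ 0.95, RMSE ≈ 5 y) than clocks
trained on real survey data (r ≈ 0.7–0.75, RMSE ≈ 13–14 y raw); the
generator is a validation instrument, not a facsimile of survey noise.
Passing recovery tests therefore demonstrates the pipeline's
correctness and statistical calibration, not that effects of this size
would be detectable in real cohorts at these sample sizes.

**Fixture.** `make_fixture()` emits a deterministic n = 30 bundle with
one planted violator per QC rule: a day with exactly 143/1440 (9.93%)
nonzero minutes, an age-17 participant, and an uncalibrated week. It is
generated at call time (the activity table alone is ~300k rows, too
large to commit as a file) and is byte-stable under a fixed seed.

## Problem sizes and numerical choices

The standard run trains on a cohort of 1,500 (70/30 split, stratified
on age-quantile bins so both subsets span the age range) and analyses a
separate validation cohort of 2,500 — mirroring a two-survey-cycle
design and matching the scale of the real validation cycle. The
ten-seed planted-recovery checks use validation cohorts of 8,000
(≈ 1,900 participants aged 70+, ≈ 35 planted-drug users), sized so the
planted drug's KS evidence dominates the twelve null drugs' uniform
p-values in essentially every seed. The null-calibration check uses a
signal-free cohort of 700 (frailty and both activity-age slopes zeroed)
and 1,000 replicate death draws for the rejection-rate estimate; being
a 95%-band check, the |r| criterion itself is expected to fail on ~5%
of seeds by construction.

Other numerical choices: quantiles use linear interpolation; the KS
test uses SciPy's exact/asymptotic switching; Pearson correlations and
t-tests come from SciPy, BH from statsmodels, the forest and
permutation importance from scikit-learn — each behind a package
function with an independent elementary oracle in the test suite
(explicit Pearson chi-square formula, brute-force step-up BH, the
n(n+1)/12 closed form for the variance of consecutive integers).
Degenerate inputs are first-class: zero-variance vectors, nonpositive
peer medians, empty aging classes and out-of-range p-values raise typed
errors rather than propagating NaNs.

SAS transport (XPT v5) files are read via pandas; writing — needed only
for synthetic data and round-trip tests — uses the package's own
minimal writer (IBM hexadecimal floats, fixed-width character fields,
fixed header timestamp for byte-identical output). Magnitudes below
16⁻⁶⁵ underflow to zero, the documented floor of the IBM format; the
observation block's tail padding is chosen by simulating the reader's
record-count heuristic so padding can never masquerade as data.

## Known limitations

* Real wear-time artifacts (non-wear bouts, device spikes, seasonality,
  survey weights) are out of scope; zeros are the only non-wear proxy.
* The clock saturates at the top-coded age (see above), so delta-age is
  least informative exactly where mortality is highest.
* The screens are associational; no dose–response or causal modelling.
* The synthetic generator's noise level is deliberately optimistic (see
  "Choosing the default conditions").
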