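# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, in the order the pipeline uses them.

## Scientific setting

When items in a briefly flashed array are spatially clustered into small
subgroups, adults estimate the total numerosity more precisely than when the
same number of items is scattered at random — the *groupitizing* advantage.
The leading account is that clustered arrays recruit two attention-dependent
mechanisms on top of the Approximate Number System (ANS): the subitizing
system (which enumerates up to ~4 subgroups and their contents in parallel)
and fast arithmetic on the subitized subgroups. The dual-task design
implemented here probes that account: observers estimate grouped and
ungrouped arrays either with full attention (single task, with or without
to-be-ignored distractors) or while performing a concurrent auditory
bisection, visuo-spatial conjunction, or mental-arithmetic task. If
groupitizing depends on attention and calculation, concurrent load should
inflate estimation noise *more* for grouped than for ungrouped arrays.

The chain of derived quantities:

* **Weber fraction** (per participant × task × arrangement × numerosity):
  `Wf = SD_i / N`, where `SD_i` is the sample SD of responses to numerosity
  `N`. Under scalar variability this is a numerosity-free precision index;
  the **summary Wf** is its unweighted mean over numerosities 5–8, the
  range where the grouping advantage is expressed.
* **Attentional cost** (per participant × arrangement × dual task):
  `AC = (Wf_DT − Wf_ST) / (Wf_ST + Wf_DT) × 100`. Sum-normalization bounds
  AC in (−100, 100), makes it antisymmetric in its arguments, and
  equals `100·tanh(½·ln(Wf_DT / Wf_ST))` — a bounded log-ratio.
* **Delta attentional cost**: `ΔAC = AC_grouped − AC_ungrouped`, positive
  when the concurrent task hurts grouped arrays more. This is the
  headline statistic.

The single-task reference `Wf_ST` for grouped arrays is the grouped single
task *with ignored distractors* (matching the visual stimulation of the
dual tasks); for ungrouped arrays it is the plain single task, because no
ungrouped-with-distractors condition exists in the design. Reports state
the reference explicitly.

## Stimulus geometry (`stimuli`)

Ungrouped arrays draw item positions without replacement from the centers
of a square-cell tiling of the stimulus area: 6° × 6° of visual angle at
0.54° cell pitch gives an 11 × 11 = 121-cell tiling (as many whole cells as
fit per axis, centered on fixation). Cells whose centers fall strictly
inside the 2.73° × 1.64° fixation exclusion rectangle (a 5 × 3 block) are
removed, leaving **106** positions — the only tiling consistent with all of
the design's printed counts.

Grouped arrays place each subgroup in its own quadrant. The four quadrants
(1.64° wide × 2.2° tall) are centered on the diagonals at 3.0° eccentricity,
i.e. at (±3/√2, ±3/√2); the diagonal placement is a package choice — only
the ~3° eccentricity is constrained — and is exposed as a parameter. Each
quadrant holds a 3-column × 4-row slot grid (12 slots, matching the
quadrant's aspect ratio); subgroup→quadrant assignment is drawn first
(without replacement, in the order the subgroup sizes are listed), then item
slots within each quadrant. One integer seed fully determines an array.

The configuration table holds the 36 partitions used in the design (three
per numerosity 5–16, each into 2–4 subgroups of 1–5 items); a block of 36
trials presents each entry once.

## Synthetic observers (`observer`)

The generator's defaults *are* the study conditions; they are calibrated
once, to the group-level values the analysis is expected to recover, and are
not tuned per run.

**Response model.** The internal estimate for numerosity `N` is
`N·(1+b) + ε`, `ε ~ Normal(0, σ)`; the verbal response is the estimate
rounded to the nearest integer, clamped at 1. Rounding a continuous value to
the integer lattice adds ≈1/12 to its variance, so the generator uses
`σ = sqrt((wf·N)² − 1/12)`: the *observable* response SD then equals `wf·N`
and the pipeline's `SD/N` estimator recovers the generating Weber fraction
without a discretization bias (Monte Carlo residual ≤ ~3% at the smallest
noise level, `wf·N ≈ 0.45`, where the lattice correction is least accurate;
below the rounding floor σ collapses to 0). The bias default `b = 0.07`
puts mean perceived numerosity over 5–8 near 6.96, the observed single-task
level; the generator applies the same bias to both arrangements, so it does
not emulate the small grouped/ungrouped accuracy differences in real data.

**Condition means.** Single-task Weber fractions default to 0.09 (grouped,
with or without ignored distractors) and 0.11 (ungrouped). Dual-task Wfs are
the single-task values times a fold increase: grouped 1.6 / 2.3 / 2.0 and
ungrouped 1.3 / 1.5 / 1.3 for the auditory, visuo-spatial and arithmetic
tasks. Dual-task inflation is multiplicative per participant (fold applied
to the participant's own single-task Wf).

**Heterogeneity.** Each participant draws one mean-one log-normal precision
factor per *task family* — the single tasks share one factor; each dual task
has its own — with total log-scale SD 0.3 and cross-family correlation
ρ = 0.5 (a shared-ability component plus a family-specific susceptibility,
applied to both arrangements of the family). ρ is set from the implied
correlation structure: with per-cell Wf estimation noise from 12 trials per
cell, within-task correlations of the 5–8 grouped Wfs come out ≈ 0.67 and
between-task (visuo-spatial vs arithmetic) ≈ 0.33, so the correlation
matrix of the eight PCA variables has two eigenvalues above 1 and the two
retained components carry ≈ 73–75% of the variance, the structure the
interference analysis must exercise. A single factor shared by *all*
conditions (the simplest alternative) makes all eight variables equally
correlated and collapses the PCA to one component.

**Lapses and response times.** With probability λ = 0.006 a trial is a
lapse: the response is uniform on 1..3N and the RT is shifted by +1.2 log
units. Clean RTs are log-normal (location 6.6 log-ms ≈ 735 ms, scale 0.15)
*truncated at ±2.3 SD* — a paced, experimenter-keyed session produces no
extreme RTs except on lapse trials. The truncation bound is chosen so the
3-sample-SD filter threshold (≈ 2.8σ after truncation shrinks the sample
SD) clears the bound by ≈ 4 standard errors of the SD estimator: on clean
data the RT rule then almost never fires, and with lapses the filter
removes essentially exactly the λ = 0.6% of planted trials. Concurrent-task
correctness is independent Bernoulli per dual-task trial (0.82 / 0.94 /
0.96 for auditory / visuo-spatial / arithmetic); no response-interference
coupling is modeled.

**What the generator does not emulate.** Sequential effects, RT–accuracy
coupling, numerosity-dependent response bias, arrangement-specific bias,
and the heavier between-participant spread of real attentional costs
(printed AC SDs are ~25–33 percentage points; simulated ~13–19). Passing
tests therefore certify the *pipeline* under the stated statistical
structure, not every feature of real observers. One consequence worth
naming: because AC is a concave (tanh) function of the log Wf ratio,
participant-specific factors and Wf estimation noise attenuate mean
estimated AC a few points below its noise-free value, so simulated group
ACs sit slightly below the fold-implied ceiling — an estimator property,
not a bug, and one that affects real data equally.

## Outlier filter (`precision`)

Trials are removed when the response deviates more than k = 3 sample SDs
from its cell mean (cell = participant × task × arrangement × numerosity) or
the log RT deviates more than 3 SDs from its participant × task mean (RT
pooled over numerosity and arrangement, since RT does not scale with N the
way responses do). Both rules are two-sided; SDs use the n−1 denominator;
cells with zero SD remove nothing. The sweep repeats until no trial exceeds
the criterion, making the filter a fixed point of itself: with integer
responses a single sweep is not (a 12-trial cell with two deviants can lose
the farther one and leave a lone deviant at exactly 10/√11 ≈ 3.015 SDs).
In practice the first sweep does all the work and convergence costs one or
two extra sweeps removing a handful of trials; at the calibrated defaults
the removal fraction is ≈ 0.6%. Cells left with fewer than two trials are
dropped with a warning rather than imputed.

## Statistics (`stats`)

**Repeated-measures ANOVA.** Balanced fully within-subject designs with any
number of factors, computed from the classical sums-of-squares
decomposition on subject × cell means; each term's error stratum is its
interaction with subjects. η² is SS_term / SS_total. Sphericity is handled
per term: orthonormal contrast scores (Kronecker products of per-factor
Helmert contrasts) give the covariance matrix from which Mauchly's W (χ²
approximation) and the Greenhouse–Geisser ε are computed; the GG-corrected
p (df scaled by ε, clipped to [1/df, 1]) is reported alongside the
uncorrected p, with the Mauchly p < .05 flag marking where the correction
is conventionally applied. Two-level terms have trivial sphericity (ε = 1).
The implementation is cross-checked in the tests against a hand-coded SS
oracle, against pingouin (one and two factors) and statsmodels AnovaRM
(three factors); pingouin itself stops at two within factors, which the
three-way perceived-numerosity analysis exceeds — the reason the ANOVA is
implemented here rather than delegated.

**t tests and effect sizes.** Paired and one-sample t tests use scipy;
Bonferroni adjustment is `p_bonf = min(1, m·p)` with the family size m an
explicit argument (m = 3 for the ΔAC tests against zero, giving the
adjusted α = 0.05/3 ≈ 0.017). Cohen's d defaults to d_z = t/√n (mean
difference over the SD of differences), the convention consistent with the
reference results; a pooled-SD paired d (`d_av`) is exposed alongside
because conventions differ between software packages.

**Bayes factors.** t tests get the JZS default Bayes factor: Cauchy(0, r)
prior on the standardized effect with r = √2/2 (the field default; the
reference analysis does not state its prior), computed by adaptive
quadrature over the variance-inflation parameter g (InverseGamma(1/2, r²/2)
prior), with the integrand normalized by the null likelihood for numerical
range. Reported as log10(BF10). The tests check it against an independent
quadrature route (noncentral-t likelihood integrated over the Cauchy prior
on effect size) to 10⁻³ log units. ANOVA terms get *inclusion* Bayes
factors via the BIC approximation: every marginality-closed sub-model is
fit by OLS with a fixed subject factor, BICs become model weights, and each
term is compared across matched models (models containing the term but no
higher-order interaction involving it, against the same models without it).
This approximates the MCMC model-averaged inclusion BF of GUI statistics
packages; agreement is qualitative, not digit-for-digit.

**PCA with oblimin rotation.** Eigendecomposition of the correlation
matrix; components with eigenvalue > 1 are retained (Kaiser criterion, at
least one); retained loadings (eigenvector × √eigenvalue) are rotated with
direct oblimin (γ = 0, quartimin criterion) via the oblique
gradient-projection algorithm, implemented here because no installed
package provides oblimin. Sign convention: each component's
largest-magnitude loading is positive. Constant variables raise an error
naming the column.

**Power.** `required_sample_size` finds the smallest n whose two-tailed
paired t test reaches the target power, using exact noncentral-t power with
noncentrality d·√n; `implied_effect_size` inverts the same curve by
bisection (the a-priori calculation behind n = 28 at α = 0.05/28 and power
0.95 used an effect size that was never printed; the inverse makes it
explicit: d ≈ 0.99).

## Orchestration and problem sizes

`run_end_to_end` chains simulation → filter → cells → Wf → summary → AC →
ΔAC → statistics, logs one line per stage with in/out counts, and writes
result tables, a human-readable report and a provenance record (full config
+ seed, sufficient for an exact rerun) as plain CSV/JSON text. Stage
failures propagate wrapped with the stage name.

Default problem sizes: 28 participants × 1296 trials. The test suite's
Monte Carlo checks use 20 replicate cohorts of 28 participants;
`scripts/acceptance.py` averages 5 replicate cohorts derived from its
`--seed`. These replicate counts balance the standard error of group means
(≈ 1–3% relative for condition Wfs) against runtime; a single cohort
simulates and analyzes in about one second.

## Known limitations

* The RM-ANOVA requires complete balanced designs (missing cells raise an
  error naming the cell); unbalanced data must be completed or subset first.
* Inclusion Bayes factors inherit the BIC approximation's unit-information
  prior; they are comparable across terms, not calibrated posteriors.
* The Mauchly χ² approximation is poor when subjects barely exceed the
  contrast dimension; with a singular contrast covariance the test reports
  W = 0, p = 0 and falls back to the GG-corrected p.
* The simulator's bounded-RT model intentionally puts all RT outliers in
  the lapse process; it cannot be used to study RT distributions.
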