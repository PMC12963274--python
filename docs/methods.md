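# Methods

This note documents the models and procedures implemented in `gaitcontext`,
the defaults they ship with, the design choices that were genuinely open,
and what the synthetic-cohort validation does and does not demonstrate.

## Walking bouts from stride events

Input is a table of gait cycles (strides): start time, duration, length.
One stride is one full gait cycle, i.e. two steps; all step counts are
`2 × strides`. Per-foot bookkeeping is deliberately not modeled — foot
labels rarely survive into stride-level exports, and a fixed convention
keeps every count testable.

Validity filters: stride duration in `[0.2, 3.0]` s (both endpoints
inclusive, a literal reading of "between") and stride length strictly
greater than `0.15` m. Bouts split where the gap between consecutive
strides (next start − previous end) is *strictly* greater than `3.0` s; a
gap of exactly 3 s does not split. Candidate bouts need at least
`min_strides_per_bout = 3` gait cycles (≈ 6 foot contacts), the closest
testable analogue of "at least two consecutive strides of both feet".

Duration classes nest: ">10 s" means d > 10 strictly; "10–30 s" means
10 < d ≤ 30; ">30 s" and ">60 s" likewise strict. Classes overlap by design
(a 45 s bout is in ">10 s" and ">30 s"). Gait outcomes (speed, stride
length, stride duration, cadence) are only estimated from bouts > 10 s;
activity outcomes (steps, minutes, bout counts) use every bout.

Segmentation is validated against a brute-force oracle that enumerates all
gaps and splits explicitly, over tens of thousands of randomized sequences
that deliberately include gaps of exactly 3.0 s and strides at the 0.2 s /
3.0 s / 0.15 m boundaries.

## Indoor/outdoor context from GPS

*Stay points.* A sliding window over time-sorted fixes grows while each new
fix lies within `stay_radius_m = 20` of the running window centroid;
anchoring on the centroid rather than the first fix makes detection robust
to receiver jitter. Dwell is credited over consecutive-fix intervals; an
interval longer than `gap_max_s = 60` counts only if its flanking fixes are
within `gap_radius_m = 10` of each other (phones suspend GPS when
stationary, so a stationary gap is evidence of staying put). A stay point
(the window centroid with arrival/departure times) is emitted when the
credited dwell strictly exceeds `stay_dwell_s = 120`. The 60 s gap
threshold is our operationalization — the rule it implements states the
10 m radius but no minimum gap duration.

*Stay regions.* Stay-point centroids are clustered by HDBSCAN
(`min_cluster_size = 2`) in a local equirectangular projection, then
consolidated by single linkage at `cluster_epsilon_m = 25`: points within
25 m (or sharing an HDBSCAN cluster) are unioned, and leftover noise points
become singleton regions. The epsilon consolidation is needed because the
density hierarchy over-fragments the very small stay-point sets a single
participant produces. Region occupancy is the union of member dwell
intervals.

*Land use.* A region centroid inside a "building" polygon gets
`p_indoor = 0.9`; inside urban/park/forest land use, `0.1`; outside every
polygon, `0.5`. Buildings take precedence; among outdoor polygons the
smallest containing one wins (a park inside the urban background is a
park). Polygon boundaries count as inside. The probability values encode
strength of evidence, not calibrated probabilities, and are configurable;
`0.5` always means "no location evidence".

*Bout labels.* Each bout receives the time-weighted mean indoor probability
over its interval: stay-region occupancy contributes the region's
probability, remaining time covered by moving GPS contributes the outdoor
probability, and uncovered time contributes 0.5. Each fix is treated as
evidence for ± half the nominal fix spacing (15 s) around it, so short
bouts with a single fix are still covered. If evidence covers less than
`min_bout_gps_coverage = 0.5` of the bout, the label is `unknown`
(excluded from context-stratified outcomes); otherwise indoor if p > 0.5,
outdoor if p < 0.5, and unknown at exactly 0.5. The three-way label (rather
than a binary split) mirrors the practice of excluding bouts invalid for
contextual analysis.

Distances use the haversine formula (R = 6,371,000 m); all planar work uses
an equirectangular projection about a reference latitude, which is
sub-meter accurate at city scale and exactly invertible.

## DMO aggregation

Daily summaries per context stratum (`all`, `indoor`, `outdoor`, plus
`unknown` so step counts are conserved): steps (2 × strides), walking
minutes, bout counts overall and per duration class, mean/max bout
duration, and per gait class the stride-weighted mean walking speed, stride
length, stride duration, and cadence. Cadence is derived from the gait
cycle duration as `120 / stride_duration_s` steps/min — a single source of
truth; walking speed is `length / duration`, equivalently
`length × cadence / 120`. Participant-level values are the median across
valid days (configurable to the mean); a valid day has at least one bout,
and participants with fewer than `min_days = 3` valid days are flagged
excluded, matching the "> 2 days of data" inclusion rule.

## Walking-speed modes

Per participant and duration class, stride speeds are pooled and fitted
with univariate Gaussian mixtures, K = 1..9, under two variance families
mirroring the classical univariate model family: `equal` (one pooled
variance, p = 2K parameters) and `varying` (per-component variances,
p = 3K − 1). The selected model minimises `BIC = −2 log L + p log n`; ties
within 1e-9 break toward smaller K, then the equal family (parsimony).
Infeasible fits (fewer than 2K distinct values) are excluded from the
table; if nothing is feasible an "insufficient data" error is raised rather
than a crash.

EM details: the E-step computes responsibilities from unshifted Gaussian
densities (speeds are O(1), so overflow is impossible; rows that underflow
fall back to max-shifted form), and the M-step uses weighted raw moments
collected in a single matrix product. The first start places component
means at equally spaced sample quantiles with sample-SD widths and equal
weights; the remaining `n_init = 10` starts jitter the means with seeds
derived from the configuration seed only — never from the data — so fits
are invariant to input permutation. Each start runs a short burn-in
(25 iterations, on a deterministic ≤ 1024-point subsample for large n);
the start with the best full-data log-likelihood is then polished to
convergence (relative log-likelihood change ≤ `rel_tol = 1e-8`, at most
`max_iter = 500` iterations). Variances are floored at `1e-4 ×` the sample
variance, with a degeneracy flag when the floor binds. Components are
reported sorted by mean. The log-likelihood trace of the winning start is
retained so the EM monotonicity guarantee can be asserted directly.

*Fixed-stride-count resampling.* To control for unequal data volume, each
day's time-ordered speed sequence (indexed 0..m−1) is linearly interpolated
at `target` equally spaced positions over [0, m−1] — up- or down-sampling as
needed, endpoints preserved — then days are pooled. Targets default to
2,500 / 5,000 / 7,500 / 10,000 strides per day. Resampling per day (rather
than per participant total) is our reading of an ambiguous procedure and is
recorded in output metadata. Note that interpolation between adjacent
strides from different modes creates intermediate speeds; at large
up-sampling factors this fills the valleys between modes and tends to
*increase* the selected K — the direction the resampling analysis is meant
to probe.

## Statistical layer

All continuous predictors are standardized before modeling. No
multiple-testing correction is applied — outputs carry an exploratory flag
and standardized effect sizes (coefficient / residual SD) so consistency of
trends can be judged alongside p-values.

*Within-cohort GLMs.* Gaussian-identity GLM of a participant-level DMO on
location (indoor/outdoor) + sex + age + height, fitted on the paired long
format (one row per participant per context). Participant-level medians
(not bout-level data) are the unit of analysis. Height is included as an
adjuster alongside age and sex.

*Interaction GLMs.* Adds cohort and cohort × location; the interaction
coefficient tests whether the environment effect differs between cohorts.

*Fisher's exact test.* 2×2 tables use full hypergeometric enumeration with
the two-sided rule "sum the probabilities of all tables no more probable
than the observed"; larger tables use seeded Monte Carlo over tables with
fixed margins (add-one estimator `p = (1 + #{prob ≤ obs}) / (draws + 1)`,
default 100,000 draws). The 2×2 branch is cross-checked in tests against an
exact rational-arithmetic enumeration and against an independent library
implementation.

*Proportional odds.* Cumulative-logit model
`P(Y ≤ j | x) = logistic(θ_j − xᵀβ)` fitted by maximum likelihood (BFGS,
gradient tolerance 1e-10; a stationary point with per-observation score
norm < 1e-6 is accepted even when the line search reports precision loss).
Backward elimination removes the candidate with the largest Wald p above
`0.05`, one at a time, never removing the age/sex adjusters, and refits
until all retained candidates are significant; the full trace is reported.
Wald p-values are used for elimination (the elimination rule's test statistic
is not specified by the procedure being implemented; Wald is the
conventional choice). Odds ratios are `exp(β)` with 95% CIs. Explanatory
power is Nagelkerke's
`R² = [1 − exp((2/n)(ℓ₀ − ℓ₁))] / [1 − exp((2/n) ℓ₀)]`, clamped to [0, 1],
with the null log-likelihood computed in closed form from the marginal
category counts.

## Synthetic cohort generator

The generator emulates the *structure* of a two-cohort free-living study —
PwP and older-adult controls — with known ground truth at every stage:

- **Speed mixtures.** Each participant gets a true mode count K\*
  (default 2–4), mode means on a grid centred at
  `base_speed_mean = 0.9` m/s (between-participant SD 0.05) with spacing
  `0.25` m/s and within-mode SD `0.05` m/s (≥ 4σ separation, so K\* is
  identifiable), and Dirichlet weights floored at ~0.13 so no mode is
  vanishingly rare. Stride speeds are drawn i.i.d. from the mixture and
  truncated to (0.05, 3.0) m/s by rejection, which preserves mode locations.
- **Bout structure.** Bouts per day are negative-binomial (mean 200);
  strides per bout are lognormal (median ≈ 9, floored at 3), giving a
  realistic preponderance of short bouts with a tail past 30 s. Strides
  within a bout are contiguous; between-bout gaps are exponential with a
  3.5 s floor, so segmentation must reconstruct the planted bouts exactly.
  A context *switch* (indoor↔outdoor) carries a 150 s gap floor — one does
  not finish a hallway walk and be mid-trip four seconds later — which also
  makes planted context recoverable by the 2-min stay rule.
- **Context and GPS.** Bouts are indoor with probability 0.8. Indoor bouts
  emit fixes (1 per 15 s) jittered 3 m around the participant's planted
  home; emission pads 90 s on each side of the bout (clipped against
  outdoor neighbours only, since near-home fixes during a neighbouring
  indoor bout are truthful). Outdoor bouts emit fixes along a 1.4 m/s
  constant-velocity path starting 250–500 m from home. 15% of bouts emit no
  fixes, emulating suspended sampling. The land-use map plants a 20 m
  building square at each home, a park polygon away from all homes, and an
  urban background.
- **Clinical covariates.** PwP covariates (LEDD, MDS-UPDRS II/III, FOG-Q,
  disease duration, LLFDI, mass, height, medication count) are drawn from
  distributions bracketing published cohort medians; K\* follows a
  proportional-odds model with `clinical_mode_logodds = 0.3` per SD of LEDD
  and of MDS-UPDRS III, so the ordinal analysis has a planted signal.
  Controls draw K\* at zero linear predictor and carry no PD-specific
  fields. Controls carry an indoor speed decrement of 0.08 m/s (PwP 0.0),
  planting the qualitative pattern that only controls adapt walking speed
  to environment.

Everything is seeded: streams are derived per (seed, purpose, participant),
so identical specs produce byte-identical CSV outputs and no stage's
randomness leaks into another's.

**What the generator does not emulate:** realistic activity scheduling
(bouts are laid out sequentially from 06:00), raw inertial signals, GPS
multipath/urban-canyon error (jitter is Gaussian), terrain and weather,
within-bout speed autocorrelation (stride speeds are i.i.d. given the
mixture), and medication-state fluctuations. Passing tests therefore
demonstrate that the pipeline recovers planted structure under clean,
well-specified conditions — they do not certify accuracy on real wearable
data, where stride detection error, GPS dropouts and unmodeled behaviour
dominate.

## Validation scales and numerical choices

Test and acceptance runs use deliberately modest problem sizes chosen to
exercise every code path with comfortable statistical margins: cohorts of
4–40 participants, 1–3 days, 25–150 bouts/day; 100 replicates for BIC
recovery at n = 5,000; 200 replicates for ordinal recovery at n = 500;
1,000 null cohorts for type-I calibration. The mode-recovery cohort sets
the indoor decrement to zero, since a nonzero decrement deliberately shifts
indoor mode locations and would make the planted K\* differ from the
effective number of modes in the pooled per-class distribution. The type-I
calibration simulates the GLM's own null (independent errors); the Fisher
test is conservative by construction on discrete support and is checked
for agreement with enumeration rather than for exact 5% size.

Known limitations: EM convergence at `rel_tol = 1e-8` is not always reached
within 500 iterations for heavily over-specified K (the fit is still
reported, flagged unconverged; its BIC is far from competitive); the
bout-level indoor probability is a time-weighted mean, one of several
defensible bout-level rules; and the stay-point scan is greedy (a window
that fails the dwell test advances one fix, which is O(n·w) worst case but
near-linear on real traces).
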