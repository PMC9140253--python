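# Methods

This note records the models, numerical choices and limitations behind
`startlehab`, in the package's own terms.

## 1. The concussive stimulus: jerk-limited motion profiles

The stroke is a point-to-point move specified by kinematic limits — start
and end positions (mm), velocity limit v_max (m/s), independent
acceleration and deceleration limits a_max, d_max (m/s²), and a shared jerk
limit j_max (m/s³) — realised as the classical seven-phase S-curve
(jerk-up / constant-acceleration / jerk-down, cruise, jerk-down /
constant-deceleration / jerk-up). Phase durations are solved in closed
form. For a ramp from rest to speed v under limits (a, j), the
acceleration phase is trapezoidal when v ≥ a²/j (jerk time a/j) and
triangular otherwise (jerk time √(v/j), peak acceleration √(vj) < a); the
ramp covers distance v·T/2 where T is the ramp time. The peak velocity
is v_max when the travel length L admits both ramps plus a cruise;
otherwise the cruise collapses first and the peak velocity is the root of
the monotone travel-length equation (solved by Brent's method), which in
turn triangularises the ramps for very short travels. This
cruise-then-velocity-then-acceleration collapse order is the standard
limited-jerk point-to-point convention and is deterministic.

Profiles are *sampled from the closed-form piecewise polynomials* of each
phase on a uniform dt grid (default dt = 1 ms, matching the motor
controller's input resolution), not integrated numerically, so the
derivative relations between position, velocity, acceleration and jerk
hold at machine precision at the phase level. A final sample is placed
exactly at the stroke end, pinned to rest. A sampling interval longer
than the shortest active phase is rejected with the phase named, since
such a grid cannot represent the phase structure. A zero-length travel
yields a degenerate single-sample profile at rest. Reverse travels are
generated on the magnitude and mirrored; the downward stroke of the
apparatus is represented as positive displacement.

**Default limit set** (`data/defaults.yaml`): 0 → 320 mm, v_max 5.1 m/s,
a_max 61 m/s², d_max 385 m/s², dt 1 ms. The published apparatus
description prints the peak velocity with acceleration units (m/s²); the
package treats it as m/s, the only dimensionally consistent reading.

**Jerk-limit calibration.** The vendor software takes a jerk limit that
the apparatus description does not print, while reporting a stroke
duration of ~121 ms. The package default j_max = 4.5 × 10⁴ m/s³ was fixed
once by a sweep over [10⁴, 10⁵] m/s³: it reproduces the duration within
10% (116.1 ms) while attaining all three kinematic limits. The feasible
window is informative: below ≈2.91 × 10⁴ m/s³ the braking ramp cannot
reach 385 m/s² before the stroke ends (the reported deceleration peak
would be unattainable), and at 10⁴ m/s³ the 320-mm travel is infeasible
altogether. The duration therefore reproduces the published value only up
to this calibrated default; it is stored in the versioned config, not in
code.

In the infinite-jerk limit the generator reduces to the trapezoidal
velocity profile with closed-form duration L/v + v/(2a) + v/(2d)
(111.2 ms for the default set), which serves as an independent oracle in
the tests.

## 2. Synthetic cohorts

No raw tracking exports are publicly deposited, so the analysis runs on
synthetic cohorts whose structure mirrors the study design: 2 groups
(control, concussed) × 24 fish × 3 sessions = 72 fish per group, each
tested at 6 times (baseline, 5 min, 40 min, 70 min, 5 h, 24 h), 20
stimulus-window distances per test.

Per trace, the distance at stimulus n is

    d(n) = max(0, s_f · [C + (A − C) e^{−(n−1)/τ}] + ε_n),
    ε_n ~ N(0, σ²)  i.i.d.,

where (A, C, τ) are the cell's (group × time) generative parameters and
s_f is a per-fish scale drawn once from a mean-one lognormal
(log-sd `fish_sd`) and reused at all six test times. The shared scale is
what carries within-subject correlation across the repeated measures — a
vigorous fish is vigorous in every session. Inter-stimulus-interval
movements are not modelled (they are excluded from the quantification).

**Calibration** (`data/defaults.yaml`, all values frozen): each cell's
(A, C) is a scaled copy of a base habituation shape — A:C = 4:1.2 with
τ = 3.5 stimuli for ordinary cells, and A = 2.8, C = 1.7, τ = 12 for the
acute concussed 5-min cell (weakly habituating: lower amplitude, higher
offset, much larger decay constant) — with the scale chosen per cell so
that the noiseless 20-stimulus sum equals the cell's group-mean TDT₂₀
anchor exactly. Five cell anchors and both group grand means (33.724 mm
control, 32.28 mm concussed) come from the published group-level summary;
the remaining cells interpolate them under the qualitative constraints of
the study narrative: the groups are identical at baseline (32.0 mm), the
control group grows steadily to 41.885 mm by 24 h (larval development),
and the concussed group recovers toward control at 40 min (30.5 mm), dips
at 70 min (27.547 mm), and sits markedly below control at 24 h
(31.491 mm, vs control 41.885 mm).

**Noise scales.** `fish_sd = 0.5` reproduces the published between-fish
standard errors (e.g. model 1.85 vs published 1.859 mm at the control
5-min cell, 2.63 vs 2.655 mm at 24 h, SE = sd/√72 on TDT₂₀). The
within-fish noise `sigma = 0.02 mm` is deliberately small: the published
SEs are between-fish quantities and constrain only `fish_sd`, while a
large σ would make the zero floor in the max(0, ·) generative rule active
for low-response fish, biasing means away from the calibrated anchors.
With the default table the floor is provably inert (the smallest curve
values sit > 5σ above zero across 10⁴ simulated traces), so every
calibrated anchor is also the exact expectation of the generator.

What this generator does *not* emulate: per-test state fluctuations
within a fish (arousal varying between sessions), non-Gaussian response
tails, occasional non-responders, and any dependence between consecutive
stimuli beyond the deterministic decay. One visible consequence: with
between-test variability carried solely by the shared fish scale, the
within-subject residual variance in the ANOVA is small and time/interaction
F statistics on simulated cohorts are far larger than would be seen on
real tracking data. Passing calibration tests therefore demonstrates
correctness of the analysis arithmetic and of the calibrated means/SEs,
not realism of every moment of real larval behaviour.

## 3. TDT₂₀ and the exponential SRH model

TDT₂₀ is the sum of the 20 per-stimulus distances of one test; group
values are arithmetic means over fish. Group habituation curves are
per-stimulus means (± SE) over fish.

The SRH model d(n) = C + (A − C) e^{−(n−1)/τ} is indexed so that the
fitted value at the first stimulus equals the amplitude A exactly; the
decay constant τ is then the number of stimuli after the first at which
the baseline-subtracted response reaches 1/e. Fitting is bounded
unweighted least squares (`scipy.optimize.least_squares`, trust-region
reflective, analytic Jacobian): A, C ∈ [0, 10 × max(curve)],
τ ∈ (0, 100], objective tolerance 10⁻¹⁰. The start point is
deterministic: A₀ = d(1), C₀ = mean of d(16…20), τ₀ from a log-linear
regression of max(d(n) − C₀, ε) on n. The τ cap of 100 stimuli — five
times the stimulus count — is the operational rendering of "infinitely
slow decay": beyond it the curve is observationally flat. A fit at the
cap, or a flat input curve (A ≈ C, τ unidentifiable), is returned with
`identified=False` rather than raised, with A = C = curve mean in the
exactly-flat case.

## 4. Fish-level bootstrap

The resampling unit is the fish (its whole 20-stimulus curve): stimuli
within a fish are dependent, so resampling stimuli would understate
uncertainty. Each of the N = 500 replicates draws n fish with
replacement, computes the resampled mean curve and fits the exponential
once — single-fish curves are too noisy for stable τ estimates, so
fitting per fish and averaging is deliberately avoided. Parameter means
and SEs (replicate SDs) summarise the population-level distribution;
capped-τ replicates are retained, counted (`n_capped`) and also
summarised separately over identified replicates.

Between-time deltas are paired at the replicate level: bootstrap runs for
the same group share their replicate index matrix (same seed and fish
count), so replicate b resamples the same fish at both times and the
delta SE is the SD of replicate-wise differences. This pairing choice
reflects the persistence of fish identity across test times in the
design; with unequal index sets the implementation falls back to
independent SE combination and flags the delta as unpaired.

## 5. Mixed-design ANOVA

The 2 × 6 design (group between, time within) is analysed by the balanced
split-plot decomposition, computed directly from sums of squares:

    SS_total = SS_group + SS_subjects(group) + SS_time
               + SS_group:time + SS_residual

with F_group = MS_group / MS_subjects(group) on (G−1, N−G) df and the two
within effects tested against MS_residual on ((k−1), (N−G)(k−1)) df.
Greenhouse–Geisser epsilon is estimated from the pooled within-group
covariance S of the six measures via the double-centred form
ε = tr(S̃)² / ((k−1)·tr(S̃²)), S̃ = CSC, clipped to [1/(k−1), 1] = [0.2, 1],
and applied to the within-effect dfs unconditionally (no sphericity-test
gating) — the published fractional dfs correspond to an ε-corrected
report. A numerically singular S̃ yields the lower bound with a warning
flag. Follow-ups are per-group one-way repeated-measures ANOVAs
(df (k−1), (n−1)(k−1), same ε treatment) and all 15 pairwise time
contrasts as paired t-tests with Bonferroni adjustment by default
(configurable; the published post-hoc method is unstated). Unbalanced
tables are rejected — completeness is the inclusion criterion, enforced
upstream — and zero-residual-variance inputs are rejected as degenerate.

The arithmetic is deliberately not delegated to a stats package so that
tiny designs can be checked against hand-computed sums of squares; the
test suite additionally cross-checks all three F statistics against an
independent implementation (pingouin) on a full-size cohort.

## 6. Pipeline and inclusion criteria

`run_pipeline` chains: ingest (tracking table) or simulate → completeness
filter (only fish with all six test times are analysed; an optional
per-fish `inspection_pass` flag represents the pre-tracking visual
inspection, which is not computable from tracking data) → per-cell TDT₂₀
and mean curves → bootstrap per group × time (one sub-seed per group, so
deltas are paired) → parameter deltas (baseline / 5 min / 24 h by
default) → mixed ANOVA, per-group RM ANOVAs, pairwise contrasts →
JSON/CSV report with provenance (seeds, config hash, package version),
plus optional figures (per-time habituation curves, TDT₂₀ bars, SRH
parameter bars). All seeding is explicit; a rerun with the same config
reproduces the report byte for byte. Stage failures carry the stage name
and the offending group × time cell.

## 7. Problem sizes in the stochastic test suites

Simulation-based checks use sizes chosen to keep the default test run
comfortably interactive while leaving ample statistical resolution: the
type-I-error suite runs 500 null cohorts at 12 fish/group (binomial 95%
band ±0.019 around α = 0.05); bootstrap coverage uses 200 cohorts of 24
fish at 200 replicates; the calibration-recovery check uses 20 seed
replicates of the full 72-fish design; the repeated-measures power check
uses 200 cohorts at 24 fish, where the calibrated developmental growth
effect is already detected in well over 80% of runs.

## 8. Known limitations

* The stroke duration depends on the unpublished vendor jerk setting; the
  calibrated default brackets it but cannot pin it down (any j_max in
  ≈[3, 10] × 10⁴ m/s³ satisfies both the duration band and limit
  attainment).
* The generator's simplifications listed in §2, chiefly the absence of
  within-fish between-test noise; inferential statistics on synthetic
  cohorts are correspondingly over-powered for within-subject effects.
* Greenhouse–Geisser is the only sphericity correction offered
  (Huynh–Feldt is noted, not implemented).
* Bootstrap intervals are plain percentile-scale mean ± SE summaries; no
  BCa or jackknife variants.
* The delta pairing across test times is a package design choice; an
  unpaired bootstrap would give conservative (larger) delta SEs.
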