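# Methods

## Scientific setting

In error-clamp reaching experiments the cursor moves along a fixed angular
path offset from the target by a clamp angle *e*, regardless of where the
hand actually goes. Participants are told to ignore the cursor and reach
straight to the target, so any drift of the hand away from the clamp
direction reflects implicit adaptation driven by the (constant) sensory
prediction error (SPE). Because the cursor's endpoint is fixed, the *task
outcome* — whether the cursor lands fully inside the target (hit),
partially overlaps it (straddle) or misses it entirely — can be
manipulated independently of the SPE simply by changing the target's
diameter. `clamplearn` implements the candidate models of how that binary
outcome modulates implicit adaptation, the experiment designs that
discriminate them, and the full analysis pipeline from raw trial tables to
model comparison.

## Geometry

With an 8 cm reach, the cursor and target centers sit on the same circle,
separated by the chord `2R sin(e/2)`. A 3.5° clamp gives a 4.9 mm
separation; 1.75° gives 2.4 mm. The outcome classification compares this
distance with the target and cursor radii: hit when
`d + r_cursor ≤ r_target`, miss when `d − r_cursor ≥ r_target`, straddle
otherwise. Boundary contact counts toward the embedded side so the
partition is closed and deterministic.

## Models

All models share a single-rate state-space core in hand-angle space with
state `x(1) = 0`:

- **Motor correction**: `x(n+1) = A·x(n) + U` on clamp trials. The clamp
  fixes the error magnitude, so the error-sensitivity function collapses to
  the single update parameter `U` (deg/trial); `A ∈ (0,1)` is retention.
  Non-clamp trials (no feedback, veridical baseline, zero-clamp washout)
  evolve by retention alone — the standard state-space treatment, needed to
  compute washout/retention metrics; fits use clamp-phase data only, so
  this is a convention, not an estimated feature.
- **Movement reinforcement**: the adaptation state is outcome-blind, but a
  model-free operant process reinforces executed directions on hit trials.
  A population of 36,000 directionally tuned units at 0.01° resolution
  carries non-negative weights; on every trial all weights decay by `A′`,
  and on a hit the unit at the executed direction (rounded to the nearest
  0.01°, ties away from zero) gains `s`. The population vector's direction
  `V_d` and length `V_l` (clipped to [0, 1]) blend into the output
  `y = (1 − V_l)·x + V_l·V_d`. When all weights are zero `V_d` is a 0/0;
  we define `y = x` there, which is the continuous limit. Because the
  vector is linear in the weights, its x/y components follow exact scalar
  recursions; the production simulator tracks only those two numbers, and
  a dense 36,000-unit implementation (`clamplearn.reference`) is kept and
  cross-checked against it in the tests.
- **Adaptation modulation**: task success gates adaptation itself —
  `x(n+1) = γ_A·A·x(n) + γ_u·U` on hit trials, plain on miss trials. Gains
  are fixed at 1 on miss trials by convention and estimated for hits; they
  are bounded in (0, 5] for fitting (unconstrained above/below 1, so
  success may amplify or attenuate either term).
- **Dual error**: two parallel implicit processes, an SPE-driven one
  updating on every clamp trial and a target-error-driven one updating
  only on miss/straddle trials (TE = 1 − hit, a step function under the
  clamp); the output is their sum.
- **Hybrids** `mr_am` / `mr_de`: the population-vector process layered on
  the modulated or dual-error adaptation state (6 parameters each).

The discriminating behavior is the miss→hit transfer: reinforcement can
only push the output *toward* previously rewarded (adapted) directions, so
it cannot produce a drop after the switch to a large target, whereas
gain modulation (γ_u < 1) drops by `U/(1−A) − γ_uU/(1−γ_AA)` and dual
error by the TE-process asymptote `U_te/(1−A_te)`. These closed forms are
asserted in the test suite and the acceptance run.

States are capped at ±10⁶ degrees inside the compiled recursions; this is
unreachable for in-bounds parameters and only prevents overflow when the
optimizer probes divergent corners (e.g. γ_A·A > 1).

## Preprocessing

Pipeline order: sign-flip CCW-clamped participants → outlier screen →
per-target baseline-bias subtraction → within-cycle aggregation. The
outlier screen flags reaches beyond ±90° or deviating more than 3 SD from
a centered five-trial moving average, per participant × target; windows
shrink at the series edges. The SD's sample is not uniquely determined by
the usual verbal description; we default to a leave-one-out SD of the
deviations (each trial judged against the variability of the *other*
trials), which keeps a single wild reach from inflating its own yardstick,
and expose the series-wide SD as `sd_scope="all"`. Baseline biases are the
per-target means over veridical-baseline cycles 2–10 (2–5 for the
transfer design). The early adaptation rate is the mean hand angle over
clamp cycles 3–7 divided by five cycles (a stabilized estimate of the
cycle-5 value from a zero start); a regression-slope variant over cycles
1–5 is available via `method="slope"`. Late learning is the mean of the
last 10 clamp cycles of a phase; the aftereffect is the first no-feedback
washout cycle; retention is quantified across the first non-veridical
washout block (no-feedback or zero-clamp, per design).

## Statistics

Group comparisons use a label-permutation test (difference of means for
two groups, one-way F for more), p = (count + 1)/(n_perm + 1). Although
such procedures are sometimes loosely described as resampling with
replacement, the operative operation is a shuffle of group assignment;
shuffling is the default and a bootstrap-style null is available as an
option. The null draws are generated from the sorted pooled values and the
sorted size multiset, which makes the p-value exactly invariant to group
labeling at a fixed seed; ties count toward the null within a 1e-9
relative epsilon (the conservative exact-test convention). Cohen's d
(pooled SD), d_z, and η² use the textbook formulas; zero-variance cases
surface as NaN/inf with an `undefined` flag.

## Fitting and model comparison

Models are fit to clamp-phase cycle means, for both groups of a transfer
experiment simultaneously with one shared parameter set. The loss is the
summed squared error between observed and simulated cycle means (the
simulated cycle mean averages the within-cycle trial outputs; for
reinforcement variants the loss compares the *motor output* y, since that
is the observable). Bounds: retentions in (0, 1), updates in (0, e),
gains in (0, 5], s in (0, 1). Optimization is bounded Powell (tolerance
1e−8) restarted from 10 initial points: one neutral point (gains 1,
s ≈ 0) so the nested-model basin is always explored, the rest uniform in
the bounds from the run's seed. In `compare_models`, hybrids additionally
warm-start from their fitted nested model, so a hybrid can never rank
below its own special case merely for want of a good basin. Goodness of
fit: `R² = 1 − SSE/SST` about the pooled observed mean and the Gaussian
least-squares `AIC = N ln(SSE/N) + 2k`; other AIC conventions shift all
models by a constant and leave the ordering unchanged. Ranking ties break
toward fewer parameters.

Parameter CIs use a participant-resampling bootstrap: resample
participants with replacement within each group, rebuild the
group-averaged cycle series, refit, and take percentile intervals.

## Synthetic data

The generator emulates per-trial source-data tables: hand angle = model
mean + per-target bias (drawn once per participant, SD 2°) + i.i.d.
Gaussian motor noise. The default noise SD is 3.5°, inside the 3.09–3.56°
range of reported baseline variabilities; the Exp-2 Hit emulation uses
3.09°. Clamp direction is counterbalanced and CCW participants are stored
sign-flipped so `flip_ccw` recovers the canonical frame. The default
generative truth is a Dual Error parameterization
(`A_spe=0.99, U_spe=0.07, A_te=0.95, U_te=0.285`) whose all-miss asymptote
is ≈12.7° with a 5.7° TE contribution — i.e. the reported ≈5.7° transfer
decrement and ≈45% asymptote reduction arise by construction of the
generative conditions, and the pipeline's job is to measure them back.
RT/MT columns are log-normal with medians near the reported ≈375/150 ms,
included only to exercise the kinematic summaries.

What the generator does *not* emulate: trial-to-trial noise
autocorrelation, within-session drift or fatigue, explicit/strategic
contributions, and any hand-angle dependence of the clamp outcome
(feedback is non-contingent by design). Passing tests therefore show the
pipeline and fitting machinery are correct under the stated statistical
structure, not that the models are correct for any particular human
dataset.

## Problem sizes

Simulation studies use sizes chosen to keep the whole suite quick while
leaving Monte-Carlo error well below the tolerances asserted: parameter
recovery uses 40 synthetic experiments in the tests and 100 in the
acceptance script (12 participants/group, 3.5° noise, 3 fit starts);
bootstrap coverage uses 6 experiments with 200 replicates (100 in tests)
and single-start refits; permutation calibration uses 300–400 null
datasets at 199 permutations. Target order within a cycle is a seeded
random permutation — the ordering is not specified by the designs and all
analyses aggregate within cycles.

## Known limitations

- The reinforcement process reinforces at most one unit per trial; basis
  -function smoothing across neighboring units would not change the
  population-vector predictions but is not implemented.
- Continuous (signed) target error for contingent feedback is out of
  scope; TE is strictly binary.
- Washout dynamics under all models are retention-only by convention;
  fits never include washout cycles.
- The AIC constant depends on the Gaussian least-squares convention;
  absolute AIC values are comparable only within a run.
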