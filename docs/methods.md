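# Methods

## Task model

The rGT session engine is a free-operant time-budget simulation. Each
trial consumes: a trial-initiation latency (default 4 s, the time a rat
takes to re-engage the food magazine), the 5 s inter-trial interval, a
choice latency (1 s), and then either a reward-collection latency (1 s)
on wins or the chosen option's time-out penalty (5–40 s) on losses.
Premature responses consume the ITI plus a 5 s time-out; omissions the
ITI plus the 10 s response window. A trial that begins before the
30-minute clock expires is completed even if it finishes after it. Under
these defaults a P2-exclusive policy completes roughly 160 trials per
session and mixed policies roughly 120–140, with risk-preferring
policies completing far fewer — the trial-count asymmetry that gives
P1/P2 their long-run advantage.

The canonical schedules are P1 (1 pellet, 0.9, 5 s @ 0.1), P2 (2, 0.8,
10 s @ 0.2), P3 (3, 0.5, 30 s @ 0.5), P4 (4, 0.4, 40 s @ 0.6). They are
plain data (`OptionSchedule`) so alternative schedules are a one-line
change. Cue delivery is metadata: the standard/reverse variants cue wins
only, the outcome variant cues everything, random-50% cues half of all
trials, and the loss variant cues losses only; cue salience scaling is
not part of the schedule structure.

## Learning models

All five models share the softmax rule over four latent Q-values in
pellet-equivalent units and the delta-rule win update toward the number
of pellets earned. The loss updates drive the chosen option's Q toward a
transformed cost: nothing (`basic`), a linear per-second cost (`scaled`,
slope `m` in pellets/s), a linear cost with a global offset
(`scaled_offset`), a power-law cost `b − Tʳ` (`nonlinear`), or the
linear cost with an extra win-side scaling `mRew` (`reward_scaled`, a
control for the asymmetric flexibility of the loss side). Q-values start
at zero on a subject's first trial and carry across session boundaries;
unchosen options are never updated. Only valid win/loss choices enter
the likelihood — premature and omitted trials carry no choice.

Numerical guards: softmax logits are max-subtracted (exact up to
|βQ| ≈ 700); model nesting identities (`scaled_offset(b=0) ≡ scaled`,
`nonlinear(b=0, r=1) ≡ scaled(m=1)`, `reward_scaled(mRew=1) ≡ scaled`)
hold to 1e-10 and are enforced by tests.

## Hierarchical inference

Within one task group, subject parameters live on an unconstrained
scale: learning rates map through the standard-normal CDF, β, m, r and
mRew through exp, and the offset b is unconstrained. Priors (the
analysis's own weakly-informative choices): group means Normal(0, 1)
(Normal(0, 2) for b), group SDs half-Normal(0, 1), subject deviations
Normal.

The sampler is an adaptive HMC written for this package: leapfrog
integration, dual-averaging step-size adaptation targeting 0.8
acceptance, Stan-style expanding warmup windows, and **dense**
mass-matrix estimation. The dense metric matters: with hundreds of
trials per subject the posterior has strong linear correlations between
group-level and subject-level coordinates that a diagonal metric leaves
as slow directions. Trajectory lengths are jittered uniformly over the
upper half of the leapfrog budget (default 48 steps); short trajectories
decorrelate poorly and full jitter is only needed to break resonance.

Centering is chosen per parameter (`parameterization="auto"`): the
subject-level β and learning rates are parameterized **centered**
(each subject's data pin them, so the noncentered form creates a
near-degenerate μ–z ridge), while the cost-transform parameters (m, b,
r, mRew) are **noncentered** (they are weakly identified per subject and
their group SD can collapse toward zero, the funnel regime). Both forms
express the same posterior and both are available explicitly; the
gradient of every variant is verified against finite differences.

Convergence follows the split-R-hat policy: if any parameter exceeds
1.01, warmup doubles and the fit re-runs, up to a cap (5000 at the
full-scale default), after which the fit is accepted with an explicit
warning. With 12-subject groups the group-SD of the offset b is the
slowest coordinate and can hover at R-hat ≈ 1.01–1.04 at the desk
preset (2 chains × 500 draws after 500 warmup); the recovery quantities
(group-mean learning rates, their HDI contrasts, WAIC) are insensitive
to this.

WAIC is computed from the pointwise posterior log-likelihood:
`elpd_i = log mean_s exp(ll_si) − var_s(ll_si)`, reported on the −2
scale with the pointwise standard error; model differences are paired
pointwise, as are their SEMs. The MLE path is L-BFGS-B with analytic
gradients from 10 Latin-hypercube starts inside documented box
constraints (η ∈ [1e-6, 1−1e-6], β ≤ 30, m ≤ 2, r ≤ 3, |b| ≤ 20).

## Synthetic cohorts

Cohorts emulate a multi-group rGT experiment: subject parameters are
drawn Normal(μ, σ) on the unconstrained scale (the same transforms
inference uses) and agents play the schedules through the session
engine. Default hypers are order-of-magnitude choices validated by
parameter recovery, not fitted values: β ≈ 1.5, η⁺ ≈ 0.12, offset
b ≈ 0.5, exponent r ≈ 0.35 (so a 40 s time-out costs ≈ 3.6 pellets
before the offset), with unconstrained SDs 0.2–0.5. Group differences
are injected through the punishment learning rate η⁻ (and optionally b),
the parameters that separate task variants: the loss-cued variant gets
the highest η⁻ (0.45) and the win-paired-cue variants the lowest
(0.12), so the variants' decision-score rank order emerges from loss
sensitivity alone. The canonical desk experiment is two groups × 12
subjects × 5 sessions (η⁻ 0.15 vs 0.45); the full-scale preset is six
variants × 28 subjects × 40 sessions.

What the synthetic data do **not** emulate: premature/omission rate
differences between cue variants, satiety or motivation drift within a
session, side biases, perseveration/stay biases, and any direct effect
of the cues on learning (cue identity is metadata only). Passing tests
therefore show that the pipeline recovers what the generative model puts
in — not that real rats obey these models.

## Analysis conventions

HDI uses the narrowest sorted-window interval; a group contrast is
credible when the 95% HDI of the difference of group means (on the
natural scale) excludes zero; contrasts with unequal sample counts
subsample the larger fit (seeded). Forward simulation uses subject-level
posterior means (medians available), sampled outcomes, and the
time-budget engine by default; simulated decision scores over sessions
36–40 are computed from mean per-trial choice probabilities
(variance-reduced) or realized choices. Regressions of parameter
estimates on final decision scores are ordinary least squares with
F = t² on (1, n−2) df, predictors on the natural scale.

Behavioral conventions: a decision score of exactly zero classifies as
optimal (the defining rule assigns only positive and negative scores, so
this is a measure-zero tie-break); the premature-rate denominator is all
initiated trials; the stable-baseline window is the latest k = 4
consecutive sessions without a significant session effect (one-way
ANOVA across sessions for cohort input, a linear-trend t-test for a
single subject), falling back to the last k sessions with a warning.
Tukey HSD p-values come from the studentized-range distribution;
differences are reported row-minus-column.

## Problem sizes

The test suite and the acceptance script run the desk preset: 12-subject
groups, 5 generating sessions (~600 valid trials per subject), 2 chains
× 500 draws after 500 warmup iterations, ten replicate seeds for the
recovery/model-selection checks, and 40-session forward simulations.
These sizes are the package's desk-scale defaults; the full-scale
configuration (4 chains × 1000 draws, warmup escalation to 5000, 28–32
subjects per group) is one `MCMCConfig` away.

## Known limitations

- The sampler is plain jittered HMC, not NUTS; pathological geometries
  are handled by warmup escalation rather than dynamic trajectories, and
  the group SD of weakly identified parameters mixes slowest.
- The stable-window rule simplifies the repeated-measures machinery
  (no sphericity corrections); it is overridable to a fixed window.
- The independent-cost model family (per-option cost weights) is out of
  scope by design: at 24–32 subjects per group those parameters are not
  well isolated.
- Session semantics are idealized (fixed latencies rather than empirical
  latency distributions); latencies are configurable but not fitted.
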