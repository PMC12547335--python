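# Methods

This note documents the models, the synthetic testbed, the numerical choices
and the limitations behind `carepath`.

## Problem setting

Medicaid care-management teams make monthly "next best step" decisions for
patients with concurrent medical, behavioral and social needs, choosing one of
nine mutually exclusive interventions (substance-use support, mental-health
support, chronic-condition support, food / housing / transportation / utility /
childcare assistance, or watchful waiting). The outcome of interest is a
composite acute-care event — any emergency-department visit or hospitalization
— over a 12-month follow-up. The package compares a status-quo,
experience-based behavior policy against an on-policy SARSA recommender via
counterfactual paired rollouts.

Because the motivating cohort is private, everything runs on a synthetic
cohort with a known ground-truth dynamic. This is a deliberate design: the
generator provides the oracle against which policy learning, transition-model
fitting, effect estimation and the doubly robust estimator can all be checked
for parameter recovery, which no real data set permits.

## State, actions, mask, reward

Patient state is a fixed 47-feature vector (see
`carepath/data/state_features.json`): demographics (standardized age, gender
and race/ethnicity indicators), six chronic-condition flags, four
social-determinant flags, auxiliary flags (child in household, positive
substance-use screen, durable medical equipment), trailing ED/hospitalization
windows at 1/3/6 months, baseline prior-6-month utilization flags, program
bookkeeping (cumulative events, months since last event, month index), the
calculated risk score, nine cumulative intervention-history counts, steps
since last active intervention, and three active-need-domain indicators
(medical / behavioral / social). Checkpoints store a hash of this layout and
refuse to score states produced under any other ordering.

Interventions map to need domains: chronic-condition support → medical;
mental-health and substance-use support → behavioral; the five assistance
actions → social; watchful waiting matches nothing. A patient's *primary risk
domain* is the argmax of a weighted need score (each flag counts 1; an active
need-domain indicator counts `NEED_WEIGHT = 6`, chosen larger than the maximum
per-domain flag count so an active need always dominates; ties break
medical > behavioral > social). This keeps the reward's matching bonus aligned
with the environment's matched-intervention effect — with a weaker weight the
learner can maximize the bonus while ignoring the actual need, a small
reward-hacking failure mode we observed during development.

The action mask is a hard constraint: rules shipped as editable YAML permit an
action only when a named state predicate holds (childcare assistance requires
a child in the household; substance-use support requires a recorded disorder
or a positive screen; each social assistance requires its flag, with utility
assistance also permitted for patients with durable medical equipment).
Watchful waiting is never maskable, so the permitted set is never empty.

The per-step reward is

```
r = w_event·1[event] + w_risk·(risk_before − risk_after)
  + w_prev·risk_before·1[no event] + w_match·1[action matches primary domain]
  + w_safe·1[action masked]
```

with defaults `w_event = w_safe = −1.0`, `w_risk = w_prev = 0.5`,
`w_match = 0.25`. The magnitudes are a design choice (only the signs and roles
of the components are externally specified); they satisfy
`|w_event| > w_prev + w_match`, so no stack of single-step bonuses can
outweigh causing an event. The prevention bonus scales continuously with
preintervention risk; banded risk levels can be emulated by discretizing the
risk feature upstream. All weights are config-exposed and the components are
individually auditable (`reward_components`).

## Ground-truth environment

Each month a patient's event probability is logistic:
`logit p = b0 + Σ βj·xj + β_need·1[any active need]`, with `b0 = −3.75`,
per-risk-factor increments β between 0.15 and 0.5 over the condition, social
and baseline-utilization flags, and `β_need = 0.7`. The baseline was
calibrated once so the behavior policy's 12-month composite event rate is
≈ 58–59%, matching the status-quo regime the package emulates; the increments
were fixed a priori at clinically plausible relative magnitudes.

Each patient carries at most one latent active need domain, sampled at
baseline in proportion to observed flag burden. An intervention matched to
the active domain multiplies that month's event odds by `ρ = 0.5` and resolves
the need with probability `q = 0.3`; resolution permanently removes `β_need`
from the hazard. Unmatched active interventions have odds multiplier 1
(configurable). Event type splits ED vs hospitalization 70/30 for window
bookkeeping. The *calculated risk score* is the probability of ≥1 event over
12 static months under watchful waiting — the stand-in for an external
risk-stratification model, and the generator-side ground truth for risk
tertiles (cut at the cohort 33.3/66.7 percentiles; tied risk values land in a
single tertile, so thirds are approximate in finite cohorts).

The status-quo behavior policy matches the most salient observed need with
probability 0.45 — choosing mental-health support for behavioral needs even
when substance use is the driver, mirroring reported practice patterns — and
otherwise draws from a biased distribution over permitted actions that
over-weights mental-health support and watchful waiting.

What the generator does *not* emulate: correlations between conditions and
social determinants (attributes are independent draws at the published
marginals), multiple simultaneous needs, time-varying confounding by
unobserved state, measurement error in flags, and enrollment churn. Passing
tests therefore demonstrate internal validity of the estimators under a known
truth, not transportability to any real cohort.

## SARSA agent

The Q-function is a 47→64→32→9 ReLU network with dropout 0.2, implemented in
a small seeded numpy module with manual backprop and Adam (the training loop
needs per-transition semi-gradient updates toward `r + γ·Q(s′, a′)` with the
*taken* next action, which off-the-shelf supervised APIs do not expose).
Defaults: learning rate 1e-3, γ = 0.95, epsilon schedule 0.3 → 0.01 with
decay 0.9 per epoch.

Two training regimes:

* **Offline** — per-transition updates over logged trajectories in patient
  order; on-policy with respect to the logging policy. In development, a
  greedy readout of this offline Q was *worse* than the behavior policy: with
  nine actions, rarely-logged interventions (childcare appears in ≈0.5% of
  behavior transitions) acquire optimistic extrapolated values that the argmax
  exploits — the classic offline-RL failure.
* **Online** (pipeline default) — each epoch regenerates the training
  trajectories by rolling the training cohort through the environment under
  the current epsilon-greedy policy, then applies the same updates. This is
  SARSA proper and reliably improves on the behavior policy.

Early stopping monitors either validation TD error or, in the pipeline, the
simulated event rate of the greedy policy on the validation cohort — the
direct analogue of tuning for reduction in acute-care events. For the
event-rate metric the best-epoch weights are selected on the *mean of two
fixed-seed rollouts*: the fixed seeds pair the comparison across epochs and
the averaging keeps selection from locking onto rollout noise, which with a
single noisy rollout occasionally froze a mediocre mid-training policy.
Patience 0 trains exactly one epoch. Two further stabilizers are pipeline
defaults: an exploration floor of 0.05 (rather than 0.01), and per-epoch
learning-rate decay of 0.93 — without annealing, late Adam updates at full
step size keep reshuffling the greedy argmax among near-tied actions.
Mini-batching (`batch_size=64` in the pipeline) is a shuffled-batch variant
of the same estimator, ~20× faster than strict per-transition updates at
indistinguishable policy quality. A grid-search helper (`grid_search_sarsa`)
tunes any `TrainConfig` field on the validation metric. Action selection is
masked everywhere; simulation raises on any masked emission, so a safety
violation cannot pass silently.

## Transition model

One-step dynamics for counterfactual rollouts: inputs are the 47 state
features plus a one-hot action; three ReLU hidden layers of 128, 64 and 32
units; heads for the event probability (sigmoid), event type (ED vs
hospitalization, fitted on event steps), the three next-step need indicators
(sigmoid), and linear heads for continuous mutable features (risk score,
trailing windows, months since event), with squared-error targets on fixed
scales. Immutable features pass through by construction.

Two numerical choices matter for multi-step fidelity:

* During rollouts, window/recency bookkeeping is driven by the *sampled*
  event and type rather than the expectation-valued linear heads — feeding
  fractional "0.35 ED visits" back into the network drifts off the data
  manifold and compounded into 3–7 pp rate errors over 12 months.
* The learning rate anneals (×0.93 per epoch over 40 epochs); without
  annealing, successive fits oscillate between under- and over-predicting
  the 12-month event rate.

The pipeline fits the model on pooled logged data: behavior trajectories plus
epsilon-greedy exploratory trajectories from the trained agent. Behavior-only
data lacks support over the recommender's state-action distribution and
produced visible covariate-shift bias in model-based rollouts. Because single
fits still showed occasional uniform ±3 pp bias in 12-month rollout rates
(fit-seed variance), the pipeline fits a 5-member seed ensemble and averages
the predicted probabilities. Under this design, model-based paired rollouts
reproduce environment-simulated event rates within two percentage points per
arm at n = 2,000.

Diagnostics follow convention: expected calibration error over 10 equal-width
bins; AUC as the tie-aware Mann–Whitney rank statistic (checked against
brute-force pairwise concordance in tests); Brier score; calibration slope by
maximum-likelihood logistic regression of outcomes on logit of clipped
predictions (clip 1e-6); Hosmer–Lemeshow over 10 equal-frequency groups with
χ² on g−2 degrees of freedom. With tens of thousands of transitions the HL
test detects trivial misfit, so its p-value is reported, not gated on.

## Counterfactual evaluation

Paired rollouts start both arms from the same initial states, share one
pre-drawn uniform noise array and one policy random stream (common random
numbers), so identical policies give ARR = 0 exactly and paired contrasts
have reduced variance. The per-patient outcome is any event within the
horizon.

Effect arithmetic: ARR (pp) = 100·(rate_sq − rate_sarsa); RRR (%) =
100·ARR/(100·rate_sq); NNT = 100/ARR when ARR > 0, else infinite; NNH uses
the harm direction symmetrically. Presentation rounds rates to whole percent
and ARR/RRR/NNT to one decimal. CIs are percentile bootstrap over
patient-level resamples (1,000 iterations by default); the NNT interval is
the transform of the ARR interval, so an ARR interval crossing zero maps to
an infinite NNT upper bound — NNT is not bootstrapped directly because it is
unstable near ARR = 0.

Risk-stratified effects re-apply the estimator within cohort risk tertiles;
empty strata are flagged, never dropped. One known phenomenon: over long
horizons the any-event outcome saturates for high-risk patients (both arms
approach certainty), which can invert the NNT gradient; at 6-month horizons
the generator shows the expected pattern of smallest NNT among high-risk
patients.

The doubly robust sensitivity analysis is augmented IPW with logistic
nuisance models by default (any sklearn-protocol classifier can be
substituted), propensities clipped to [0.01, 0.99], and a patient-level
bootstrap that refits the nuisances per resample. It recovers a known 10 pp
simulated ARR within 2 pp with either nuisance model deliberately
misspecified. Applied to the pipeline's paired rollouts — where each patient
appears in both arms and assignment is unconfounded by construction — the
AIPW estimate coincides with the naive rate difference, which is the expected
confirmatory behavior; its stress test is the confounded simulation, not the
paired design.

## Fairness

Disparities are assessed on outcomes: per policy arm, the maximum pairwise
absolute difference in group event rates, with ≤5% treated as acceptable.
Multi-group equalized-odds discrepancy is the maximum of the two-group
`max(|ΔTPR|, |ΔFPR|)` over all pairs — the most conservative natural
extension. Because the outcome-based headline needs no classifier, the
equalized-odds variant defines the "prediction" as the paired benefit
indicator (event averted under the recommender) against the status-quo event
label. Groups with fewer than 25 members are flagged as unstable; groups with
fewer than 50 are excluded from the pairwise maximum when at least two
adequate groups remain, since a group rate over a few dozen patients has a
standard error of several percentage points and would dominate the headline
by noise alone. Per-group rates are always reported; nothing is silently
pooled.

## Pipeline, seeds, and problem sizes

`run_pipeline` executes generate → split → simulate → train → fit-transition →
evaluate → fairness → report, writing artifacts and a digest manifest; intact
stages are skipped on re-run under the same config hash. The split is
70/20/10 with floor/round-half-up/remainder sizes (3175 → 2222/635/318) and
largest-remainder stratification on the baseline acute-care indicator. All
randomness derives from one global seed via
`sha256(seed:stage) mod 2^31`.

Training in the pipeline runs three independently seeded restarts and keeps
the one with the best validation event rate (the validation rollouts share
fixed seeds, so the comparison is paired): semi-gradient SARSA has
appreciable run-to-run variance, and an occasional run plateaus at the
behavior policy's level. For the paired evaluation, the held-out 10% split
is augmented with freshly generated patients — equally unseen by training —
up to 2,000, because a 318-patient contrast has a ~1.8 pp standard error on
the ARR, larger than the synthetic effect itself; fairness group rates are
computed on the same evaluation cohort.

Default experiment sizes were chosen so a complete run finishes in well under
a minute on one CPU: cohorts of 2,000–3,175 patients, 12 monthly decision
points, ≤40 training epochs with early stopping, 1,000 bootstrap iterations.
`scripts/acceptance.py` reruns the full pipeline at the published population
size (N = 3175) and additionally reproduces the effect-metric and fairness
arithmetic from published summary inputs.

## Known limitations

* The synthetic effect size is smaller than headline clinical reports: with a
  45%-matched behavior policy the ceiling for improvement (always-matched
  oracle) is ≈4–6 pp of 12-month event rate, so simulated ARRs sit in that
  range rather than double digits. Direction, inference machinery and
  stratified gradients — not magnitudes — are the tested claims.
* Single latent need per patient; domain-level (not intervention-level)
  matching within the social domain.
* The behavior policy is a stylized heuristic; real practice heterogeneity
  across team members is not modeled.
* The transition model treats a fixed feature list as mutable; alternative
  mutability partitions require re-specifying the heads.
* Tabular SARSA's convergence guarantee (exploring starts, GLIE, decaying
  steps) is exercised on small deterministic MDPs only.
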