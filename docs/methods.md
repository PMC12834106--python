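# Methods

This note documents the models implemented in `rulemem`, the assumptions
and numerical choices behind them, and what the synthetic cohorts do and do
not emulate.

## Task model

Eight stimuli enumerate all binary triples over three feature dimensions.
An RB (Type II) structure assigns the Reward category by the XOR of two
relevant dimensions (the third is irrelevant; a polarity bit selects which
XOR class is rewarded); a U (Type VI) structure uses three-dimensional
parity, so no single dimension or pair of dimensions predicts the category
(any classifier restricted to one or two dimensions labels at most 6 of 8
stimuli correctly, and exactly 4 in expectation).

Main task: the 16 cross-category pairs are each presented 10 times (160
trials, 5 runs of 32). Scheduling draws the next pair proportionally to its
remaining count among pairs different from the previous trial's (restart on
dead ends, capped at 10,000), which guarantees the no-consecutive-repeat
constraint. For each pair, 2 of its 10 repetitions are drawn without
replacement as misleading (feedback rewards the objectively wrong
stimulus), fixing valid feedback at exactly 128/160 = 80%. The side of the
Reward-category member is a fair coin per trial.

Pre-training: random cross-category pairs with deterministic feedback until
the responder makes 15 consecutive correct choices (cap 1,000 trials, with
a convergence flag), followed by a probabilistic familiarization phase
whose length is a parameter (default 40 trials; a fixed trial count
replaces the original wall-clock stopping rule, which is not reproducible).

## The learning agent

Features are coded x ∈ {−1, +1}. The agent carries seven fitted parameters
within the box bounds below, and a small set of fixed constants
(`ModelConfig`).

| parameter | bounds | role |
|---|---|---|
| γ | [−4, 4] | similarity/contrast precision; larger ⇒ wider gradients ⇒ weaker Simple-Rule updates |
| ω | [−5, 5] | contextual modulation strength |
| ρ^I | [0, 2] | salience of the current gain (reward coded +1, no-reward 0) |
| ρ^A | [0, 0.2] | salience of the accumulated gain |
| λ | [−5, 5] | configural memory strength (transformed scale) |
| λ^R | [−3, 3] | chosen-vs-unchosen encoding gain under reward |
| λ^NR | [−3, 3] | unchosen-vs-chosen encoding gain under no-reward |

**Feedback-processing strength.** With A_t the running sum of subjective
rewards and r_t ∈ {0, 1} the trial's subjective feedback,

    v_t = ρ^A·A_t − ρ^I·r_t·exp(−ρ^A·A_t).

Reward lowers v_t (by ρ^I, with an influence that decays as rewards
accumulate); accumulated reward raises it. v_t is mapped through a
saturating compression g = 3·tanh(v/3) into the trial-wise learning rates:
the Simple-Rule rate σ(−(γ + g)) (low v ⇒ narrow generalization ⇒ strong,
precise rule updates) and the modulator rate 0.25·σ(ω + g) (low v ⇒ weak
modulatory updates; the 0.25 ceiling keeps the tallies slow recency
accumulators rather than one-trial memories).

**Rule module.** Simple-Rule weights w_m (one per dimension) are recency
tallies of the training labels: w_m ← w_m + η_rule(y·x_m − w_m). Modulator
tallies u[m, c] track how the rule on dimension m co-varies with the
context feature on dimension c, and are *error-gated*: with ŷ the rule
module's own prediction for the training stimulus (clipped to [−1, 1],
evaluated before any within-trial update),

    u[m, c] ← u[m, c] + η_mod·(y − ŷ)·x_m·x_c.

They therefore accumulate while the modulated rule mispredicts and freeze
once it accounts for the feedback — this is what makes the RB solution
stable once discovered. Training examples: after Reward only the chosen
stimulus is processed (label +1); after NoReward the chosen (−1) is
processed first, then the unchosen (+1).

Attention weights are softmax-normalized with sharpness 5:
α ∝ exp(5·|w_m|) over dimensions (rule attention) and
β ∝ exp(5·Σ_m α_m |u[m, c]|) (modulator attention); both always sum to 1.
Rule evidence for a stimulus is

    R(s) = Σ_m α_m x_m (0.15·w_m + G·Σ_{c≠m} β_c u[m,c] x_c),

where G = 2σ(ω + 3·tanh(ρ^A A/3)) is a contextual-control gain that opens
as rewards accumulate. The small Simple-Rule weight (0.15) keeps transient
label-tracking in w from producing spuriously confident choices; the gain
produces the characteristic plateau (tallies accumulate silently while the
gate is shut) followed by an abrupt step when it opens.

**Memory module.** Each stimulus carries a reward-probability association
a(s) (init 0.5), updated by a delta rule toward the subjective outcome for
the chosen stimulus and toward its complement for the unchosen one (the
two stimuli are always from opposite categories). The trial-wise encoding
strengths are λ_t = λ ± λ^R (chosen/unchosen) under reward and λ ∓ λ^NR
under no-reward, mapped to rates by σ(λ_t − 3); the offset 3 puts λ = 0 at
a near-inert rate (≈0.05), aligning the regularization target "λ = 0" with
"memory off". The unchosen stimulus receives an additional constant
attenuation of 1.0 on this transformed scale, reflecting the robustly lower
attention it receives; this also removes a near-degeneracy in fitting
between "strengthen the chosen after reward" and "rework the unchosen"
accounts of the same learning curve. Memory evidence is 2a(s) − 1.

**Choice.** Evidence is combined additively, and
P(left) = σ(4·(E_L − E_R)); the rule-module-only probability (memory term
dropped) is recorded for the fitting objective. Choice sensitivity 4,
attention sharpness 5 and the other constants are fixed, not fitted.

**Error discounting.** A choice is *confident* if the chosen stimulus's
combined choice probability is ≥ 0.8 (matching the 80% accuracy criterion
used throughout; exposed as config). After three consecutive confident
correct choices the agent is *solved*, permanently: no-reward feedback is
re-evaluated as Reward (semi-self-supervised learning — rewards are
accepted as-is, errors re-evaluated), and the memory encoding strengths are
fixed to λ_t = −3 (chosen) and −5 (unchosen), i.e., nearly frozen. The
re-evaluation uses the solved state entering the trial, so the trial that
completes the streak still processes its objective feedback; because every
post-solution code path depends only on the subjective feedback, a
no-reward trial then produces a bitwise-identical state update to a reward
trial. Under self-supervision the error-gated tallies consolidate toward
the agent's own (now mostly correct) choices, which is what carries RB
accuracy from the ~85% imposed by probabilistic feedback to near ceiling.

**Derived trial-wise regressors.** Rule confidence p_t(A) is the mean of α
and β mass on the truly relevant dimensions ((Σ_rel α + Σ_rel β)/2, against
the generating structure's ground truth); memory confidence p_t(C) is
a(chosen) at choice time. The choice-phase regressor is p_t(A) in RB and
p_t(C) in U; the outcome-phase regressor is v_t in RB and λ_t (chosen
coding) in U. Regressors are z-scored (mean 0, SD 1, population SD) over
non-nuisance trials within participant; the first trial of each run
(trials 1, 33, 65, 97, 129) is flagged as nuisance. A 3-column
onset/duration/value export is provided for GLM software.

## Fitting

One parameter vector spans pre-training and main task; the agent state is
re-initialized at the phase boundary because the phases use different
stimulus sets. The objective is

    −LL_main(combined) + ratio·(−LL_pre(combined))
  + −LL_main(rule-only) + ratio·(−LL_pre(rule-only))
  + penalty_main + penalty_pre,

with ratio = n_main/n_pre (so 80 pre-training trials are scaled ×2),
probabilities clipped to [1e−6, 1−1e−6], and non-responses excluded. The
rule-only term forces the rule module to claim rule-like variance before
the memory module can. The penalty is acc_phase·(ρ^I + ρ^A + |λ^R| +
|λ^NR| + 2|λ|), with the phase's mean accuracy entering as a proportion:
this keeps the penalty a tie-breaker of a few nats against likelihood
differences of tens of nats, which is the only regime in which the
regularization behaves as intended (parameters become effective exactly
when they explain variance). A percentage-scale reading (×100) is exposed
via `accuracy_scale` for comparison but overwhelms the likelihood entirely.
γ and ω are exempt (γ is mechanistically self-regularizing: it only becomes
effective when behavior is rule-like).

Minimization is differential evolution (rand/1/bin, population 10×7,
mutation 0.8, recombination 0.9, no polishing) within the box bounds, 500
iterations by default; the recovery analyses use 150 iterations with two
independent starts, keeping the lower objective — the surface has
near-equivalent basins for some datasets and a second start guards against
the worse one.

## Changepoint trajectory model

Exactly as stated in the package docstrings: p̂ = 0.5 for t ≤ o_s and
1/(1+exp(−b_s(t−o_s))) after, Bernoulli likelihood; o_s ~ Categorical(θ),
θ ~ Dirichlet(1,…,1) over the 160 trial indices; b_s ~ N(β^M, β^SD)
truncated to [0, 3]; β^M ~ U(0, 3); β^SD ~ N(0.1, 1) truncated positive.
The slope prior's spread is parameterized as SD = β^SD (a
precision-style reading of the same prior is a sampler-dialect variant; the
recovery results are robust to either). The sampler is component-wise
MCMC: conjugate Dirichlet update for θ, exact enumeration of the 160-value
discrete full conditional for each o_s, and random-walk Metropolis for b_s
and the hyperparameters (truncation constants of the b-prior included in
the hyperparameter acceptance ratios). Defaults: 2,000 iterations, 500
burn-in, one chain (multiple chains with split-R̂ diagnostics available);
proposal SDs 0.15/0.1/0.1. Correctness was validated against brute-force
enumeration of the collapsed posterior on a 20-trial toy problem (total
variation < 0.1 at Monte-Carlo resolution).

Estimates: t_o is the posterior median of o_s (the central-tendency choice
for a discrete, often skewed marginal); b̂ is the posterior mean, reported
alongside log b̂ for group comparisons. t_s is the modal first trial at
which the predicted accuracy reaches 80% (closed form o + ⌈ln 4 / b⌉);
draws that reach 80% only within the final 16-trial block, or never, count
as non-learning, and a subject whose draws are mostly non-learning gets the
sentinel t_s = 161 and a non-learner flag — never-reachers and
last-block-only reachers are pooled, as in the histogram convention the
analyses use.

## Synthetic cohorts

Profiles draw parameters uniformly within sub-ranges of the fitting
bounds. Rule profile: γ ∈ [−2, −0.5], ω ∈ [−4, −2.5], ρ^I ∈ [0.6, 1.2] and
ρ^A ∈ [0.05, 0.12] (centred on the group means the estimation method is
expected to produce, ρ^I ≈ 0.87 and ρ^A ≈ 0.08), memory off (λ ≤ −4).
Memory profile: λ ∈ [−1.5, −0.3], λ^R ∈ [1.2, 1.8] > λ^NR ∈ [0.4, 0.9]
(centred on ≈1.45 and ≈0.66), rule learning neutral. Non-learners have all
learning parameters at inert values and behave as Bernoulli(0.5). The RB
irrelevant dimension and the reward polarity are randomized per subject.
A changepoint-generative profile bypasses the agent and emits Bernoulli
correctness from the changepoint curve for calibration studies. Cohort
pre-training is capped at 300 trials: memory agents that trigger error
discounting early in the deterministic phase freeze their memory at partial
knowledge and can otherwise take ~1,000 trials to produce a 15-streak.

What the generator emulates: plateau-then-step RB trajectories with
near-ceiling post-solution accuracy; gradual U learning; 80%-valid feedback
with exactly 2 misleading repetitions per pair; a non-learner fraction.
What it does not: response times, fixations, within-trial dynamics, session
effects, or between-participant parameter correlations — so passing tests
show the pipeline's statistical machinery is correct under the assumed
generative structure, not that real participants satisfy that structure.

## Numerical choices and degenerate inputs

Probabilities are clipped at 1e−6 in likelihoods and 1e−12 inside the
sampler; softmaxes subtract the maximum; attention argmax ties break toward
the lowest dimension index via the underlying argmax convention. Zero-variance
regressors raise with a diagnostic rather than emitting NaNs. Sequence
generation re-draws on scheduling dead ends and fails loudly after the
retry cap. The jitted fast path and the step-level reference implementation
share arithmetic exactly and are cross-checked in the tests.

## Known limitations

The exact functional forms of the rule-module equations are this package's
own constructions, designed to satisfy the documented behavioral contracts
(direction of every parameter's influence, the error-discounting semantics,
the fixed post-solution encoding strengths, the plateau/step vs. gradual
signatures); other forms satisfying the same contracts would differ in
quantitative detail. ρ^I is weakly identified from choices alone (its
influence decays with accumulated reward), so its recovery is assessed as a
sign. The λ^R/λ^NR asymmetry is identifiable but with a known mirrored
basin that the unchosen-encoding attenuation and the regularization
suppress in most, not all, datasets. Transition-width comparisons are
ordinal: the absolute widths depend on the changepoint model's smoothing of
the pre-solution creep in accuracy.
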