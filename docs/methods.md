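# Methods

## The task

Stimuli ("icons") have three dimensions (color, shape, texture) with three
features each. On every trial the learner selects features in zero to three
dimensions; the computer fills each unselected dimension uniformly at
random. A hidden rule assigns one rewarding feature to each of 1, 2 or 3
*relevant* dimensions; reward is Bernoulli with parameter

    p(reward | stimulus) = 0.2 + 0.6 · m / D,

where `D` is the rule's dimensionality and `m` the number of rewarding
features the stimulus carries. By construction a uniformly random agent
earns reward with probability exactly 0.4 in every game type, so chance
behavior is uninformative about `D`. Games come in six types (D ∈ {1,2,3} ×
hint known/unknown); the standard session is 18 games — three per type in
random order — of 30 trials each, with a fresh uniformly drawn rule per
game.

The choice set is all 64 configurations (including the empty one); the
hypothesis/rule space is the 63 non-empty partial feature assignments.
Wherever an expected reward is needed for an incomplete configuration, the
computer fill is marginalized uniformly and independently per unselected
dimension. Canonical integer orderings (configurations by base-4 code with
0 = "no selection"; rules by dimensionality, then lexicographically) make
all probability vectors comparable across runs and serializable.

## Models

All four models share the softmax choice comparison over the 64
configurations where applicable, and are scored by the exact log-likelihood
of the observed choice sequence, with learner state reset at every game
boundary (rules change between games; no carryover).

**Feature RL with decay.** Nine feature values `V(f_ij)` start at zero.
`ER(c)` is the sum of the chosen features' values, with the dimension mean
substituted for unselected dimensions; choice is softmax(β·ER). After each
outcome the three stimulus features are updated by a Rescorla–Wagner step
with learning rate η_s (participant-selected dimensions) or η_r
(computer-filled), against the prediction error r − ER(choice) — note the
error uses the choice's expectation while the update lands on the realized
stimulus's features, exactly as the update rule is defined. The six
features absent from the stimulus decay toward zero by factor d. The model
has no mechanism to use the hint. Decay and update happen together after
each outcome; there is no decay before the first outcome.

**Bayesian rule learning.** A belief over the hint-consistent rules (9/27/27
known, 63 unknown) starts uniform and is multiplied after each trial by the
reward likelihood of the *realized stimulus* (for a rewarded trial,
`p(reward|h, s)`; else its complement), then renormalized. This is
equivalent to conditioning on the choice for complete choices, and uses the
actually experienced outcome context for incomplete ones. Expected reward
per configuration marginalizes the belief; choice is softmax(β·ER). The
model is greedy (maximizes current-trial expected reward; no planning).

**Serial hypothesis testing (SHT).** One rule is tested at a time. The
prior over rules weights dimensionalities below / at / above the
instructed D by w_l / 1 / w_h (normalized); unknown games use the
arithmetic mean of the three known-game priors, cached per (w_l, w_h).
While testing h the agent emits h's exact configuration with probability
1 − λ and otherwise any of the 64 configurations uniformly (so the
hypothesis-consistent configuration receives 1 − λ + λ/64). A per-hypothesis
counter tracks rewards/trials since adoption — lapse trials included — and
the estimated reward rate is the Laplace estimate p̂ = (a+1)/(n+2). Between
trials the agent keeps the hypothesis with probability
σ(β_stay (p̂ − θ)); on a switch the counter resets and the next hypothesis
is drawn either from the prior renormalized without the current rule
(*random-switch*) or softmax(β_switch · ER(h)) over the prior's support
excluding the current rule (*value-based*, the hybrid model). ER(h) for
switching sums h's constituent feature values only (no dimension-mean
padding — deliberately different from the configuration expectation).
Values for the hybrid are learned by the same Rescorla–Wagner-with-decay
rule with a single learning rate η applied to all three stimulus features,
and decay d retained. Stay/switch is evaluated between trials only, never
before the first choice.

Variants: a *test gate* (before the first trial, at every switch point, and
on every trial while idle, the agent tests only with probability
σ(β_test(max_h ER(h) − θ_test)); while idle it emits the empty
configuration, with the same lapse mixture); a *reward-probability-target*
threshold (θ replaced by RP_target + δ, where RP_target is 0.8 when the
hypothesis covers at least the instructed dimensionality and the
interpolated table value otherwise; unknown games use fixed targets 0.6 /
0.733 / 0.8 for 1D/2D/3D hypotheses); and a *superset choice* policy
(choices that are supersets of h are emitted with weights e^{k(D(c)−D(h))},
non-supersets share the lapse mass λ uniformly).

Two documented quirks. First, the printed unknown-game target of 0.6 for 1D
hypotheses is not the arithmetic mean of the known-game targets
((0.8+0.5+0.4)/3 ≈ 0.567); the published constants are used verbatim.
Second, the random-switch model is the value-based model's exact special
case at η = 0, β_switch = 0 *only when the prior is uniform on its support*
(e.g. w_l = w_h = 1, or the strict w = 0 limit): the value-based switch
softmax carries no prior factor while the random switch renormalizes the
prior. The nesting checks are run in the uniform-on-support regime.

## Likelihood of the SHT family

The tested hypothesis is latent, so the likelihood marginalizes over
hypothesis trajectories. Because rewards are observed, the counter of a
hypothesis adopted before trial k is a deterministic function of k (n =
trials since adoption, a = observed rewards since adoption); the forward
filter therefore tracks the joint distribution of (hypothesis, adoption
trial) — at most 63 × T states — plus one scalar "not testing" mass under
the test gate. Per trial it scores the observed choice through the choice
policy, conditions, and applies the stay/switch kernel; the value
trajectory is precomputed from the observed stimuli and rewards (it never
depends on the latent state; values also update during idle trials, since
the learner still sees stimuli and outcomes). The filter is exact — no
pruning — and is verified against brute-force enumeration of all hypothesis
paths on short games for every variant. The switch kernel uses a
subtract-the-diagonal trick with an exact log-space fallback when a single
hypothesis holds nearly all softmax weight. Zero-likelihood observations
(possible only at λ = 0) yield −∞. The inner loops are compiled with numba
when available; the pure-numpy path is the reference implementation (and
serves the per-trial predictive output), and the suite asserts agreement
between the two.

## Fitting and model comparison

Maximum likelihood uses bounded L-BFGS-B (scipy) with numerical gradients,
ftol 1e−6, and multi-start: starting points uniform within bounds,
log-uniform for inverse temperatures, all derived from one master seed.
Default bounds: rates and probabilities (η, d, θ, λ, θ_test) in [0,1]
(λ's fitting floor is 0.001 to keep the likelihood finite), β-type
parameters in [0.01, 100] optimized on a log scale, hypothesis-space
weights w in [0, 10], δ in [−0.5, 0.5], k in [−5, 5]. Any parameter can be
pinned, which removes it from the search space.

Model comparison is leave-one-game-out cross-validation: each game is
scored with parameters fitted to the session's other games, and the summary
is the geometric average likelihood per trial, exp(Σ held-out log-lik / Σ
trials); chance is 1/64. Fold fits warm-start from the full-session MLE
(the held-out game never enters any objective, so this only stabilizes the
fold optimum). The contribution of each mechanism is the hybrid model's
held-out likelihood per trial minus the component model lacking it (minus
feature RL → the SHT contribution; minus random-switch SHT → the RL
contribution), reported per game type and overall; log-scale columns are
included because only log-likelihoods per trial recombine additively across
game types.

## Synthetic cohorts and what they do (not) show

The generator reproduces the experimental design exactly (18 games, 3 per
type, 30 trials, randomized order, fresh uniform rules) with choices from
any implemented model; all randomness flows from a single seed and cohorts
are bit-reproducible. Latent hypothesis trajectories are stored for
diagnostics but never consumed by fitting.

Reference agents (documented once, used for cohort simulation, model
recovery and the qualitative checks):

* feature RL: β = 8, η_s = 0.4, η_r = 0.2, d = 0.7 — mid-range values
  typical of behavioral fits;
* Bayesian: β = 10;
* SHT (both policies): w_l = w_h = 0, β_stay = 20, θ = 0.55, λ = 0.1; the
  hybrid adds η = 0.4, d = 0.95, β_switch = 5. θ sits between the payoff of
  a wrong hypothesis (≈0.4) and a correct one (0.8); β_stay = 20 retains a
  clearly rewarding hypothesis (p̂ ≈ 0.8) with probability ≈0.99 per trial.
  The strict instruction-following prior (w = 0) represents a learner who
  takes the hint at face value, and is the regime in which the hint shapes
  the hypothesis space throughout a game rather than only on its first
  trial (the value-based switch softmax carries no prior weights).

Parameter-recovery ranges: feature RL η_s ∈ [0.1, 0.6], η_r ∈ [0.05, 0.5],
d ∈ [0.3, 0.9], β log-uniform in [2, 20] (all four fitted); hybrid SHT
λ ∈ [0.05, 0.3], θ ∈ [0.4, 0.7], η ∈ [0.1, 0.6] varied and fitted with the
remaining parameters held at the reference values. Model recovery uses 20
agents per generating model on a reduced design of 6 games (one per type) ×
20 trials with the hypothesis-space weights pinned at their generating
values during fitting — they are weakly identified from short sessions and
irrelevant to the model-identity question. The qualitative-pattern cohort
uses the standard 18-game design; the contribution check uses 8 agents on a
12-game × 15-trial design. These problem sizes are the package's default
study conditions for its validation studies.

Passing these checks shows the pipeline is self-consistent — simulated
agents are recovered by the fitting machinery, and the generative hybrid
reproduces the qualitative orderings (late-game reward probability falls
with complexity; features selected in known games track the instructed
dimensionality; both mechanism contributions are non-negative on
hybrid-generated data). It does not show anything about human data: real
participants contribute reaction times, question responses, sequential
idiosyncrasies and heterogeneity that no synthetic cohort here emulates,
and published human-cohort quantities (e.g. absolute held-out likelihoods
per trial) are not reproducible from simulation alone.

## Numerical notes

Softmaxes are computed in log space with max subtraction; β is capped at
100 during fitting. Belief updates cannot degenerate (likelihoods lie in
[0.2, 0.8]). Ties in the softmax are resolved by the exact arithmetic —
equal expected rewards give exactly equal probabilities. The forward
filter's mass is renormalized every trial by construction (conditioning),
so drift cannot accumulate. File indices are 1-based for games and trials
(matching conventional trial numbering) and 0-based for dimensions and
features; the tidy CSV schema round-trips sessions exactly.

## Known limitations

The hybrid's switch rule cannot express prior-weighted value switching, so
intermediate instruction-following (0 < w ≪ 1) affects only the first
hypothesis of a game; hierarchical dimension-first hypothesis generation,
parallel hypothesis testing, and hypothesis-gated value learning are out of
scope. The approximately-optimal benchmark agent and all inferential
statistics on human data are likewise out of scope.
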