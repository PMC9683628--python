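# iconlearn

Computational models of how people solve multi-dimensional probabilistic
reward-learning problems, built around a free-configuration
("build your own icon") task: on each trial the learner assembles a
three-dimensional stimulus by choosing a feature in zero to three dimensions
(color, shape, texture; three features each), the computer fills the rest at
random, and a binary reward arrives with probability
`0.2 + 0.6·m/D` — `D` relevant dimensions, `m` rewarding features present.
Chance performance pays 0.4 in every game type, so only structured learning
reveals the rule. Sessions follow the standard design: 18 games (three of
each of 1D/2D/3D × known/unknown hint), 30 trials per game.

The package is for computational cognitive modelers who want to simulate,
fit and compare learning strategies on this class of task. It implements:

* **task core** — the 64-configuration choice set, 63-rule hypothesis
  space, reward law and stimulus realization, all by exact enumeration;
* **feature RL with decay** — Rescorla–Wagner learning of nine feature
  values `V(f_ij)` with separate learning rates for chosen (η_s) and
  computer-filled (η_r) features, decay `d` of absent features, and softmax
  choice `P(c) ∝ exp(β·ER(c))`, `ER(c) = Σ_i V(f_i,c_i)`;
* **Bayesian rule learning** — exact posterior over hint-consistent rules,
  `P(h|data) ∝ P(r|h,s)·P(h)`, greedy softmax on the marginal expected
  reward;
* **serial hypothesis testing (SHT)** — test one rule at a time, stay with
  probability `σ(β_stay(p̂ − θ))` where `p̂ = (rewards+1)/(trials+2)`, and
  switch either randomly from the prior (`P(h) ∝ w_l / 1 / w_h` by
  dimensionality relative to the hint) or by a value-based softmax
  `∝ exp(β_switch·ER(h))` — the hybrid model — plus published variants
  (test gate, reward-probability-target threshold, superset choices).
  Its likelihood is an exact forward filter over the latent
  (hypothesis, adoption-time) states;
* **fitting & comparison** — multi-start bounded MLE, leave-one-game-out
  cross-validation scored as geometric likelihood per trial (chance 1/64),
  mechanism-contribution metrics, model-comparison tables;
* **synthetic cohorts** — reproducible simulated "participants" from any
  model, parameter- and model-recovery studies, learning-curve analyses.

## Worked example

Simulate one hybrid (value-based SHT) agent on the standard design, refit
it, and cross-validate:

```python
from iconlearn.fitting import make_model, fit_mle, logo_cv
from iconlearn.synth import CohortSpec, MODEL_RECOVERY_PARAMS, simulate_cohort

session = simulate_cohort(
    CohortSpec("value_sht", 1, params=MODEL_RECOVERY_PARAMS["value_sht"], seed=7)
)[0]
model = make_model("value_sht", session, fixed={"w_l": 0.0, "w_h": 0.0})
fit = fit_mle(model, n_restarts=5, seed=0)
print(fit.summary())
cv = logo_cv(model, n_restarts=2, seed=0)
print(f"held-out likelihood per trial: {cv.likelihood_per_trial:.4f}")
```

```
Model:                value_sht
No. trials:           540
No. games:            18
Log-likelihood:       -1000.8305
Likelihood/trial:     0.1567
Converged:            True
Restarts:             5 (best: #3)
--------------------------------------------
parameter         estimate  bounds
beta_stay          20.6472  [0.01, 100]
theta               0.5547  [0, 1]
lapse               0.0845  [0.001, 1]
eta                 0.3784  [0, 1]
decay               0.9822  [0, 1]
beta_switch         3.9717  [0.01, 100]
w_l                 0.0000  (fixed)
w_h                 0.0000  (fixed)

held-out likelihood per trial: 0.1549
```

The agent was generated at β_stay = 20, θ = 0.55, λ = 0.1, η = 0.4,
d = 0.95, β_switch = 5: every free parameter is recovered close to its
generating value from a single 540-trial session, and the held-out
likelihood per trial (0.155) is an order of magnitude above the 1/64 ≈
0.0156 chance line.

The same machinery is available from the shell:

```
iconlearn simulate --config cohort.yaml --out sessions.csv
iconlearn compare  --sessions sessions.csv --models feature_rl,bayes,random_sht,value_sht
iconlearn curves   --sessions sessions.csv --plot
```

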