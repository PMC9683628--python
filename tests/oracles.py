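"""Independent reference implementations used only by the test suite.

Everything here is written as plain scalar Python over tuples, with no
imports from :mod:`iconlearn`, so that agreement between these oracles and
the package's vectorized implementations is a meaningful check.

Conventions (shared with the package only by construction):
  * a choice/configuration is a 3-tuple with entries in {None, 0, 1, 2};
  * a stimulus is a 3-tuple with entries in {0, 1, 2};
  * a rule/hypothesis is a non-empty choice-like 3-tuple;
  * configurations are ordered by the base-4 code d0*16+d1*4+d2 with
    digit 0 = None, digits 1..3 = features 0..2;
  * rules are ordered by (dimensionality, sorted (dim, feature) pairs).
"""

from itertools import product
from math import exp, log


def all_configurations():
    opts = (None, 0, 1, 2)
    return [c for c in product(opts, opts, opts)]


def all_rules():
    rules = [c for c in all_configurations() if any(f is not None for f in c)]
    rules.sort(
        key=lambda r: (
            sum(f is not None for f in r),
            tuple((d, f) for d, f in enumerate(r) if f is not None),
        )
    )
    return rules


def dimensionality(rule):
    return sum(f is not None for f in rule)


def reward_prob(rule, stimulus):
    d = dimensionality(rule)
    m = sum(a is not None and a == s for a, s in zip(rule, stimulus))
    return 0.2 + 0.6 * m / d


def reward_prob_choice(rule, choice):
    """Expected reward of a partial choice, marginalizing the uniform fill."""
    total, count = 0.0, 0
    for stim in product(range(3), range(3), range(3)):
        if all(c is None or c == s for c, s in zip(choice, stim)):
            total += reward_prob(rule, stim)
            count += 1
    return total / count


def softmax_logprob(utilities, beta, index):
    scores = [beta * u for u in utilities]
    m = max(scores)
    z = sum(exp(s - m) for s in scores)
    return scores[index] - m - log(z)


# ---------------------------------------------------------------------------
# Feature RL with decay
# ---------------------------------------------------------------------------


def rl_expected_reward(values, choice):
    er = 0.0
    for i, f in enumerate(choice):
        if f is None:
            er += sum(values[i]) / 3.0
        else:
            er += values[i][f]
    return er


def rl_trace_loglik(trials, beta, eta_s, eta_r, decay):
    """Step-by-step feature-RL likelihood of one game.

    ``trials`` is a list of (choice, stimulus, reward) tuples.  Values start
    at zero; after each outcome the three stimulus features are updated by
    the Rescorla-Wagner rule (learning rate eta_s on participant-selected
    dimensions, eta_r on computer-filled ones) and the six absent features
    are decayed toward zero.
    """
    configs = all_configurations()
    values = [[0.0, 0.0, 0.0] for _ in range(3)]
    total = 0.0
    for choice, stimulus, reward in trials:
        ers = [rl_expected_reward(values, c) for c in configs]
        total += softmax_logprob(ers, beta, configs.index(choice))
        pe = reward - rl_expected_reward(values, choice)
        new = [[0.0] * 3 for _ in range(3)]
        for i in range(3):
            for j in range(3):
                if j == stimulus[i]:
                    eta = eta_s if choice[i] is not None else eta_r
                    new[i][j] = values[i][j] + eta * pe
                else:
                    new[i][j] = decay * values[i][j]
        values = new
    return total


# ---------------------------------------------------------------------------
# Bayesian rule learning
# ---------------------------------------------------------------------------


def hint_rules(hint):
    if hint == "unknown":
        return all_rules()
    return [r for r in all_rules() if dimensionality(r) == hint]


def bayes_trace_loglik(trials, beta, hint):
    """Step-by-step Bayesian rule-learning likelihood of one game."""
    configs = all_configurations()
    rules = hint_rules(hint)
    belief = [1.0 / len(rules)] * len(rules)
    total = 0.0
    for choice, stimulus, reward in trials:
        ers = [
            sum(b * reward_prob_choice(h, c) for h, b in zip(rules, belief))
            for c in configs
        ]
        total += softmax_logprob(ers, beta, configs.index(choice))
        lik = [
            reward_prob(h, stimulus) if reward else 1.0 - reward_prob(h, stimulus)
            for h in rules
        ]
        post = [b * l for b, l in zip(belief, lik)]
        z = sum(post)
        belief = [p / z for p in post]
    return total


# ---------------------------------------------------------------------------
# Serial hypothesis testing: brute-force path enumeration
# ---------------------------------------------------------------------------

NOT_TESTING = "NT"


def sht_prior(hint, w_l, w_h):
    """Hint-weighted prior over all 63 rules (unknown games average the known priors)."""
    rules = all_rules()
    if hint == "unknown":
        known = [sht_prior(d, w_l, w_h) for d in (1, 2, 3)]
        return [sum(p[i] for p in known) / 3.0 for i in range(len(rules))]
    weights = []
    for r in rules:
        dh = dimensionality(r)
        weights.append(w_l if dh < hint else (1.0 if dh == hint else w_h))
    z = sum(weights)
    return [w / z for w in weights]


def sht_rp_target(hyp_dim, hint):
    if hint == "unknown":
        return {1: 0.6, 2: 0.733, 3: 0.8}[hyp_dim]
    if hyp_dim >= hint:
        return 0.8
    return 0.2 + 0.6 * hyp_dim / hint


def _stay_prob(a, n, theta, beta_stay):
    p_hat = (a + 1.0) / (n + 2.0)
    x = beta_stay * (p_hat - theta)
    if x >= 0:
        return 1.0 / (1.0 + exp(-x))
    e = exp(x)
    return e / (1.0 + e)


def _choice_prob(config, hyp, lapse, superset_choice, k):
    """P(config | hypothesis) under the lapse-mixture choice policy."""
    configs = all_configurations()
    if hyp == NOT_TESTING:
        target = (None, None, None)
        return lapse / 64.0 + (1.0 - lapse) * (config == target)
    if not superset_choice:
        return lapse / 64.0 + (1.0 - lapse) * (config == hyp)
    supersets = [
        c
        for c in configs
        if all(h is None or h == f for h, f in zip(hyp, c))
    ]
    if config in supersets:
        dh = dimensionality(hyp)
        z = sum(exp(k * (dimensionality(c) - dh)) for c in supersets)
        return (1.0 - lapse) * exp(k * (dimensionality(config) - dh)) / z
    return lapse / (64.0 - len(supersets))


def sht_path_loglik(
    trials,
    hint,
    *,
    w_l=1.0,
    w_h=1.0,
    beta_stay=5.0,
    theta=0.5,
    lapse=0.1,
    switch_policy="random",
    eta=0.0,
    decay=1.0,
    beta_switch=0.0,
    test_gate=False,
    beta_test=0.0,
    theta_test=0.0,
    rp_target=False,
    delta=0.0,
    superset_choice=False,
    k=0.0,
):
    """Exact SHT likelihood by enumerating every latent hypothesis path.

    Exponential in the number of trials: only usable for short games.  The
    latent state per trial is the tested hypothesis (or the not-testing
    state when the test gate is enabled); reward counters are reconstructed
    along each path from the observed rewards.
    """
    rules = all_rules()
    prior = sht_prior(hint, w_l, w_h)
    support = [i for i, p in enumerate(prior) if p > 0]
    T = len(trials)

    # deterministic value trajectory from the observed data (single eta)
    values_after = []
    values = [[0.0] * 3 for _ in range(3)]
    for choice, stimulus, reward in trials:
        pe = reward - rl_expected_reward(values, choice)
        new = [[0.0] * 3 for _ in range(3)]
        for i in range(3):
            for j in range(3):
                if j == stimulus[i]:
                    new[i][j] = values[i][j] + eta * pe
                else:
                    new[i][j] = decay * values[i][j]
        values = new
        values_after.append([row[:] for row in values])

    def hyp_value(values, rule_idx):
        r = rules[rule_idx]
        return sum(values[i][f] for i, f in enumerate(r) if f is not None)

    def p_test_at(values):
        if not test_gate:
            return 1.0
        best = max(hyp_value(values, i) for i in support)
        x = beta_test * (best - theta_test)
        if x >= 0:
            return 1.0 / (1.0 + exp(-x))
        e = exp(x)
        return e / (1.0 + e)

    def theta_for(hyp_idx):
        if not rp_target:
            return theta
        return sht_rp_target(dimensionality(rules[hyp_idx]), hint) + delta

    def switch_dist(prev_idx, values):
        """Distribution over the next hypothesis given a switch away from prev."""
        if switch_policy == "random":
            weights = [0.0 if i == prev_idx else prior[i] for i in range(len(rules))]
        else:
            scores = {i: beta_switch * hyp_value(values, i) for i in support}
            m = max(s for i, s in scores.items() if i != prev_idx)
            weights = [
                exp(scores[i] - m) if i in scores and i != prev_idx else 0.0
                for i in range(len(rules))
            ]
        z = sum(weights)
        return [w / z for w in weights]

    states = list(support) + ([NOT_TESTING] if test_gate else [])
    total = 0.0

    def recurse(t, state, adopted_at, weight):
        """Sum path weights over trials t..T-1; returns total probability."""
        nonlocal total
        if t == T:
            return weight
        choice, stimulus, reward = trials[t]
        hyp = NOT_TESTING if state == NOT_TESTING else rules[state]
        w = weight * _choice_prob(choice, hyp, lapse, superset_choice, k)
        if w == 0.0:
            return 0.0
        if t == T - 1:
            return w
        # transition between trial t and t+1, using values after trial t
        vals = values_after[t]
        out = 0.0
        if state == NOT_TESTING:
            p_t = p_test_at(vals)
            out += recurse(t + 1, NOT_TESTING, None, w * (1.0 - p_t))
            for i in support:
                out += recurse(t + 1, i, t + 1, w * p_t * prior[i])
            return out
        # reward counter for the current hypothesis, from observed rewards
        n = t - adopted_at + 1
        a = sum(r for _, _, r in trials[adopted_at : t + 1])
        p_stay = _stay_prob(a, n, theta_for(state), beta_stay)
        out += recurse(t + 1, state, adopted_at, w * p_stay)
        p_t = p_test_at(vals)
        if test_gate:
            out += recurse(t + 1, NOT_TESTING, None, w * (1.0 - p_stay) * (1.0 - p_t))
        dist = switch_dist(state, vals)
        for i in support:
            if i != state and dist[i] > 0:
                out += recurse(t + 1, i, t + 1, w * (1.0 - p_stay) * p_t * dist[i])
        return out

    for i in support:
        total += recurse(0, i, 0, p_test_at([[0.0] * 3] * 3) * prior[i])
    if test_gate:
        total += recurse(0, NOT_TESTING, None, 1.0 - p_test_at([[0.0] * 3] * 3))
    return log(total)
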