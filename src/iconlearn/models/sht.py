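"""Serial hypothesis testing (SHT) models: random-switch, value-based, variants.

The learner tests one candidate rule at a time.  While testing hypothesis
``h`` they mostly emit the configuration that selects exactly ``h``'s
features (with a lapse rate ``lapse`` of choosing uniformly among all 64
configurations), and track how often the hypothesis has been rewarded since
they adopted it.  Between trials they keep the hypothesis with probability

    Pr(stay) = logistic(beta_stay * (p_hat - theta)),
    p_hat    = (reward_count + 1) / (trial_count + 2),

and otherwise switch: either to a random other hypothesis drawn from the
prior (random-switch policy) or, in the hybrid value-based policy, softmax
in RL-learned hypothesis values (the sum of each rule's constituent feature
values, learned with a single learning rate and decay).

The prior over hypotheses encodes how the dimensionality hint is used: rules
below / at / above the instructed dimensionality get weights ``w_l`` / 1 /
``w_h`` before normalization; unknown games use the arithmetic mean of the
three known-game priors.

Variants: a test gate (the learner may not test any hypothesis when no
candidate looks valuable, emitting the empty configuration instead), a
reward-probability-target threshold (theta replaced by a game- and
hypothesis-dependent target plus an offset delta), and a superset choice
policy (choices may select more features than the hypothesis specifies).

Likelihood: the tested hypothesis is latent, so the model's likelihood
marginalizes over hypothesis paths with an exact forward filter.  Because
rewards are observed, a hypothesis's counters are a deterministic function
of its adoption trial; the filter therefore tracks the joint distribution of
(hypothesis, adoption trial), which is linear — not exponential — in game
length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional

import numpy as np
from scipy.special import expit

from .. import task
from ..task import (
    CONFIG_NDIMS,
    Configuration,
    GameSpec,
    Hint,
    N_CONFIGS,
    N_RULES,
    RULE_CONFIG,
    RULE_DIM,
    RULE_SUPERSETS,
    Rule,
    Trial,
)
from . import _kernels
from .base import BehavioralModel
from .values import RULE_FEATURE_MASK, update_values, value_trajectory

__all__ = [
    "SHTParams",
    "HypothesisCounter",
    "hypothesis_prior",
    "p_hat",
    "rp_target",
    "stay_probability",
    "switch_distribution",
    "test_probability",
    "choice_given_hypothesis",
    "forward_loglik",
    "simulate_game",
    "SerialHypothesisTestingModel",
]

# printed reward-probability targets for unknown games, by hypothesis dimensionality
UNKNOWN_RP_TARGETS = {1: 0.6, 2: 0.733, 3: 0.8}


@dataclass(frozen=True)
class SHTParams:
    """Parameters of the SHT family; variant fields are inert unless enabled."""

    w_l: float = 1.0
    w_h: float = 1.0
    beta_stay: float = 5.0
    theta: float = 0.5
    lapse: float = 0.1
    switch_policy: str = "random"  # "random" | "value"
    eta: float = 0.0
    decay: float = 1.0
    beta_switch: float = 0.0
    test_gate: bool = False
    beta_test: float = 0.0
    theta_test: float = 0.0
    rp_target: bool = False
    delta: float = 0.0
    superset_choice: bool = False
    k: float = 0.0

    def __post_init__(self):
        if self.switch_policy not in ("random", "value"):
            raise ValueError(f"unknown switch policy: {self.switch_policy!r}")
        for name in ("w_l", "w_h", "beta_stay", "beta_switch", "beta_test"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("theta", "lapse", "eta", "decay"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not -0.5 <= self.delta <= 0.5:
            raise ValueError("delta must lie in [-0.5, 0.5]")


@dataclass(frozen=True)
class HypothesisCounter:
    """Reward/trial counts accumulated since the current hypothesis was adopted."""

    rewards: int = 0
    trials: int = 0

    def __post_init__(self):
        if not 0 <= self.rewards <= self.trials:
            raise ValueError("need 0 <= rewards <= trials")


def p_hat(counter: HypothesisCounter) -> float:
    """Estimated reward probability under a uniform (Beta(1,1)) prior."""
    return (counter.rewards + 1.0) / (counter.trials + 2.0)


def hypothesis_prior(hint: Hint, w_l: float, w_h: float) -> np.ndarray:
    """Prior over all 63 rules given the dimensionality hint.

    Known games: weight ``w_l`` below, 1 at, ``w_h`` above the instructed
    dimensionality, normalized.  Unknown games: the arithmetic mean of the
    three known-game priors.
    """
    if hint == "unknown":
        return np.mean(
            [hypothesis_prior(d, w_l, w_h) for d in (1, 2, 3)], axis=0
        )
    if hint not in (1, 2, 3):
        raise ValueError(f"hint must be 1, 2, 3 or 'unknown', got {hint!r}")
    w = np.where(RULE_DIM < hint, w_l, np.where(RULE_DIM == hint, 1.0, w_h))
    total = w.sum()
    if total <= 0:
        raise ValueError("hypothesis prior has no mass")
    return w / total


def rp_target(hypothesis: Rule, game: GameSpec) -> float:
    """Target reward probability for a hypothesis, given the game's hint.

    Known games: 0.8 when the hypothesis covers at least the instructed
    dimensionality, else the task's interpolated reward probability for
    testing a lower-dimensional rule.  Unknown games use fixed targets of
    0.6, 0.733 and 0.8 for 1D, 2D and 3D hypotheses.
    """
    dh = hypothesis.dimensionality
    if not game.known:
        return UNKNOWN_RP_TARGETS[dh]
    if dh >= game.complexity:
        return 0.8
    return 0.2 + 0.6 * dh / game.complexity


def _theta_by_dim(params: SHTParams, hint: Hint) -> np.ndarray:
    """Switch threshold per hypothesis dimensionality (1, 2, 3)."""
    if not params.rp_target:
        return np.full(3, params.theta)
    if hint == "unknown":
        base = np.array([UNKNOWN_RP_TARGETS[d] for d in (1, 2, 3)])
    else:
        dims = np.arange(1, 4)
        base = np.where(dims >= hint, 0.8, 0.2 + 0.6 * dims / hint)
    return base + params.delta


def stay_probability(
    counter: HypothesisCounter,
    params: SHTParams,
    hypothesis: Optional[Rule] = None,
    game: Optional[GameSpec] = None,
) -> float:
    """Probability of keeping the current hypothesis for another trial."""
    theta = params.theta
    if params.rp_target:
        if hypothesis is None or game is None:
            raise ValueError("rp_target threshold needs the hypothesis and game")
        theta = rp_target(hypothesis, game) + params.delta
    return float(expit(params.beta_stay * (p_hat(counter) - theta)))


def test_probability(
    values: np.ndarray, params: SHTParams, support: np.ndarray
) -> float:
    """Probability of testing (rather than idling), from the best hypothesis value."""
    hyp_vals = RULE_FEATURE_MASK[support] @ np.asarray(values, dtype=float).ravel()
    return float(expit(params.beta_test * (hyp_vals.max() - params.theta_test)))


def choice_given_hypothesis(h: Rule, params: SHTParams) -> np.ndarray:
    """Choice distribution over all 64 configurations while testing ``h``."""
    return _choice_matrix(params)[h.index]


def _choice_matrix(params: SHTParams) -> np.ndarray:
    """P(configuration | hypothesis) for every rule; shape (63, 64)."""
    lam = params.lapse
    if not params.superset_choice:
        m = np.full((N_RULES, N_CONFIGS), lam / N_CONFIGS)
        m[np.arange(N_RULES), RULE_CONFIG] += 1.0 - lam
        return m
    logits = params.k * (CONFIG_NDIMS[None, :] - RULE_DIM[:, None]).astype(float)
    w = np.exp(logits) * RULE_SUPERSETS
    m = (1.0 - lam) * w / w.sum(axis=1, keepdims=True)
    n_sup = RULE_SUPERSETS.sum(axis=1, keepdims=True)
    m += (~RULE_SUPERSETS) * (lam / (N_CONFIGS - n_sup))
    return m


def _nt_choice_vector(params: SHTParams) -> np.ndarray:
    """Choice distribution while not testing: the empty configuration, with lapse."""
    v = np.full(N_CONFIGS, params.lapse / N_CONFIGS)
    v[task.EMPTY_CONFIG] += 1.0 - params.lapse
    return v


def switch_distribution(
    prev: Rule,
    params: SHTParams,
    values: Optional[np.ndarray] = None,
    game: Optional[GameSpec] = None,
) -> np.ndarray:
    """Distribution of the next hypothesis conditional on a switch away from ``prev``.

    Returns a length-63 vector with zero mass on ``prev``.  The random policy
    renormalizes the hint prior; the value policy softmaxes ``beta_switch``
    times the hypothesis values over the prior's support.
    """
    if game is None:
        raise ValueError("switch_distribution needs the game (for the hint prior)")
    prior = hypothesis_prior(game.hint, params.w_l, params.w_h)
    support = prior > 0
    if params.switch_policy == "random":
        out = prior.copy()
        out[prev.index] = 0.0
        total = out.sum()
        if total <= 0:
            raise ValueError("no candidate hypothesis to switch to")
        return out / total
    if values is None:
        values = np.zeros(9)
    scores = params.beta_switch * (
        RULE_FEATURE_MASK @ np.asarray(values, dtype=float).ravel()
    )
    scores[~support] = -np.inf
    scores[prev.index] = -np.inf
    if not np.isfinite(scores).any():
        raise ValueError("no candidate hypothesis to switch to")
    w = np.exp(scores - scores[np.isfinite(scores)].max())
    return w / w.sum()


def _apply_switch_kernel(
    out: np.ndarray,
    prior: np.ndarray,
    params: SHTParams,
    hyp_vals: Optional[np.ndarray],
) -> np.ndarray:
    """Redistribute switching mass ``out[h]`` over new hypotheses h' != h.

    Computes ``sum_h out[h] * K(h -> h')`` without materializing the 63x63
    kernel in the common case; falls back to explicit rows when a single
    hypothesis holds nearly all the softmax weight (where the subtraction
    trick loses precision).
    """
    if params.switch_policy == "random":
        w = prior
        total = w.sum()  # == 1
    else:
        scores = np.where(prior > 0, params.beta_switch * hyp_vals, -np.inf)
        w = np.exp(scores - scores[prior > 0].max())
        total = w.sum()
    denom = total - w
    risky = (out > 0) & (denom < 1e-12 * total)
    safe_out = np.where(risky, 0.0, out)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, safe_out / denom, 0.0)
    incoming = w * (ratio.sum() - ratio)
    for h in np.flatnonzero(risky):
        row = w.copy()
        row[h] = 0.0
        if params.switch_policy == "value":
            # recompute in log space excluding h to avoid total underflow
            scores = np.where(prior > 0, params.beta_switch * hyp_vals, -np.inf)
            scores[h] = -np.inf
            row = np.exp(scores - scores[np.isfinite(scores)].max())
        incoming += out[h] * row / row.sum()
    return incoming


def forward_loglik(
    game: tuple[GameSpec, list[Trial]] | GameSpec,
    params: SHTParams,
    trials_arrays=None,
    return_predictive: bool = False,
):
    """Exact marginal log-likelihood of one game's choice sequence.

    Forward-filters the joint distribution of (hypothesis, adoption trial)
    — counters are deterministic given the adoption trial because rewards
    are observed — plus a scalar not-testing mass under the test gate.
    Returns the total log-likelihood, and the per-trial predictive
    distributions over the 64 configurations when requested.
    """
    if trials_arrays is None:
        spec, trials = game
        choices, stims, rewards = task.game_arrays(trials)
    else:
        spec = game
        choices, stims, rewards = trials_arrays
    T = len(choices)
    prior = hypothesis_prior(spec.hint, params.w_l, params.w_h)
    support = np.flatnonzero(prior > 0)
    emit = _choice_matrix(params)  # (63, 64)
    emit_nt = _nt_choice_vector(params)
    cum_r = np.concatenate([[0], np.cumsum(rewards)])

    need_values = params.switch_policy == "value" or params.test_gate
    if need_values:
        vtraj = value_trajectory(
            choices, stims, rewards, params.eta, params.eta, params.decay
        )
        hyp_vals = vtraj @ RULE_FEATURE_MASK.T  # (T+1, 63)
    else:
        hyp_vals = None

    theta_dim = _theta_by_dim(params, spec.hint)  # (3,)
    theta_h = theta_dim[RULE_DIM - 1]  # (63,)
    uniform_theta = not params.rp_target

    if _kernels.HAVE_NUMBA and not return_predictive:
        hv = (
            np.ascontiguousarray(hyp_vals)
            if hyp_vals is not None
            else np.zeros((1, N_RULES))
        )
        return float(
            _kernels.sht_filter_kernel(
                choices,
                rewards,
                prior,
                emit,
                emit_nt,
                np.ascontiguousarray(theta_h, dtype=float),
                float(params.beta_stay),
                1 if params.switch_policy == "value" else 0,
                float(params.beta_switch),
                hv,
                1 if params.test_gate else 0,
                float(params.beta_test),
                float(params.theta_test),
            )
        )

    def p_test_at(t: int) -> float:
        if not params.test_gate:
            return 1.0
        best = hyp_vals[t, support].max()
        return float(expit(params.beta_test * (best - params.theta_test)))

    P = np.zeros((N_RULES, T))  # columns: adoption trial
    pt0 = p_test_at(0)
    P[:, 0] = prior * pt0
    nt = 1.0 - pt0 if params.test_gate else 0.0

    total_ll = 0.0
    preds = np.zeros((T, N_CONFIGS)) if return_predictive else None

    for t in range(T):
        if t > 0:
            ks = np.arange(t)
            n = t - ks  # trials experienced by a hypothesis adopted before trial k
            a = cum_r[t] - cum_r[ks]
            phat = (a + 1.0) / (n + 2.0)
            sub = P[:, :t]
            if uniform_theta:
                pstay = expit(params.beta_stay * (phat - params.theta))  # (t,)
                out = sub @ (1.0 - pstay)
                sub *= pstay
            else:
                pstay = expit(
                    params.beta_stay * (phat[None, :] - theta_h[:, None])
                )  # (63, t)
                out = (sub * (1.0 - pstay)).sum(axis=1)
                sub *= pstay
            switch_total = float(out.sum())
            pt = p_test_at(t)
            if switch_total > 0.0:
                hv = hyp_vals[t] if hyp_vals is not None else None
                P[:, t] = pt * _apply_switch_kernel(out, prior, params, hv)
            if params.test_gate:
                P[:, t] += pt * nt * prior
                nt = (1.0 - pt) * (switch_total + nt)

        marg = P[:, : t + 1].sum(axis=1)
        c = int(choices[t])
        like = float(marg @ emit[:, c]) + nt * emit_nt[c]
        if return_predictive:
            preds[t] = marg @ emit + nt * emit_nt
        if like <= 0.0:
            return (-np.inf, preds) if return_predictive else -np.inf
        total_ll += np.log(like)
        P[:, : t + 1] *= (emit[:, c] / like)[:, None]
        nt *= emit_nt[c] / like

    return (total_ll, preds) if return_predictive else total_ll


def simulate_game(
    spec: GameSpec, params: SHTParams, rng: np.random.Generator
) -> tuple[list[Trial], list[int]]:
    """Generate one game; returns trials and the latent hypothesis trajectory.

    The latent trajectory records the tested rule's canonical index per
    trial, or -1 on trials spent in the not-testing state.
    """
    prior = hypothesis_prior(spec.hint, params.w_l, params.w_h)
    support = np.flatnonzero(prior > 0)
    emit = _choice_matrix(params)
    rule_idx = spec.true_rule.index
    theta_dim = _theta_by_dim(params, spec.hint)
    v = np.zeros(9)

    def draw_test(vv) -> bool:
        if not params.test_gate:
            return True
        return bool(rng.random() < test_probability(vv, params, support))

    def adopt_from_prior() -> int:
        return int(rng.choice(N_RULES, p=prior))

    h = adopt_from_prior() if draw_test(v) else -1
    a = n = 0
    trials: list[Trial] = []
    latents: list[int] = []

    for t in range(spec.n_trials):
        if h < 0:
            c = int(rng.choice(N_CONFIGS, p=_nt_choice_vector(params)))
        else:
            c = int(rng.choice(N_CONFIGS, p=emit[h]))
        s = task.realize_stimulus_index(c, rng)
        r = task.draw_reward(rule_idx, s, rng)
        trials.append(
            Trial(Configuration.from_index(c), task.Stimulus.from_index(s), r)
        )
        latents.append(h)
        if h >= 0:
            n += 1
            a += r
        v = update_values(v, c, s, r, params.eta, params.eta, params.decay)

        if t < spec.n_trials - 1:
            if h < 0:
                if draw_test(v):
                    h = adopt_from_prior()
                    a = n = 0
            else:
                theta = theta_dim[RULE_DIM[h] - 1]
                pstay = float(
                    expit(params.beta_stay * ((a + 1.0) / (n + 2.0) - theta))
                )
                if rng.random() >= pstay:
                    if draw_test(v):
                        dist = switch_distribution(
                            Rule.from_index(h), params, values=v, game=spec
                        )
                        h = int(rng.choice(N_RULES, p=dist))
                    else:
                        h = -1
                    a = n = 0
    return trials, latents


class SerialHypothesisTestingModel(BehavioralModel):
    """Likelihood model for the SHT family.

    ``switch_policy='value'`` gives the hybrid value-based model; the
    ``test_gate``, ``rp_target`` and ``superset_choice`` flags enable the
    published variants.  Free parameters follow from the configuration.
    """

    BOUNDS = {
        "w_l": (0.0, 10.0),
        "w_h": (0.0, 10.0),
        "beta_stay": (0.01, 100.0),
        "theta": (0.0, 1.0),
        "lapse": (0.001, 1.0),
        "eta": (0.0, 1.0),
        "decay": (0.0, 1.0),
        "beta_switch": (0.01, 100.0),
        "beta_test": (0.01, 100.0),
        "theta_test": (0.0, 1.0),
        "delta": (-0.5, 0.5),
        "k": (-5.0, 5.0),
    }
    LOG_SCALE = frozenset({"beta_stay", "beta_switch", "beta_test"})
    DEFAULTS = {
        "w_l": 1.0,
        "w_h": 1.0,
        "beta_stay": 5.0,
        "theta": 0.5,
        "lapse": 0.1,
        "eta": 0.3,
        "decay": 0.9,
        "beta_switch": 3.0,
        "beta_test": 5.0,
        "theta_test": 0.3,
        "delta": 0.0,
        "k": 0.0,
    }

    def __init__(
        self,
        session,
        fixed=None,
        switch_policy: str = "random",
        test_gate: bool = False,
        rp_target: bool = False,
        superset_choice: bool = False,
    ):
        if switch_policy not in ("random", "value"):
            raise ValueError(f"unknown switch policy: {switch_policy!r}")
        self.switch_policy = switch_policy
        self.test_gate = test_gate
        self.rp_target = rp_target
        self.superset_choice = superset_choice
        names = ["w_l", "w_h", "beta_stay"]
        names.append("delta" if rp_target else "theta")
        names.append("lapse")
        if switch_policy == "value":
            names += ["eta", "decay", "beta_switch"]
        if test_gate:
            names += ["beta_test", "theta_test"]
        if superset_choice:
            names.append("k")
        self.PARAM_NAMES = tuple(names)
        self.name = (
            "value_sht" if switch_policy == "value" else "random_sht"
        )
        flags = [f for f, on in (
            ("test_gate", test_gate),
            ("rp_target", rp_target),
            ("superset", superset_choice),
        ) if on]
        if flags:
            self.name += "+" + "+".join(flags)
        super().__init__(session, fixed=fixed)

    def _params_obj(self, params: Mapping[str, float]) -> SHTParams:
        base = SHTParams(
            switch_policy=self.switch_policy,
            test_gate=self.test_gate,
            rp_target=self.rp_target,
            superset_choice=self.superset_choice,
        )
        fields = {
            k: v for k, v in params.items() if k in SHTParams.__dataclass_fields__
        }
        return replace(base, **fields)

    def game_loglike(self, game_index: int, params: Mapping[str, float]) -> float:
        spec, choices, stims, rewards = self._games[game_index]
        p = self._params_obj(params)
        return float(
            forward_loglik(spec, p, trials_arrays=(choices, stims, rewards))
        )

    def spawn(self, session):
        return type(self)(
            session,
            fixed=self.fixed,
            switch_policy=self.switch_policy,
            test_gate=self.test_gate,
            rp_target=self.rp_target,
            superset_choice=self.superset_choice,
        )
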