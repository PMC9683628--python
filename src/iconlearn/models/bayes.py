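"""Bayesian rule learning: exact posterior over the hint-consistent rules.

The learner starts from a uniform belief over every rule consistent with the
game's hint (9, 27 or 27 rules in known games; all 63 in unknown games) and
updates it by Bayes rule after each outcome, using the realized stimulus's
reward likelihood (0.2-0.8 per the task's interpolation table).  The
expected reward of each candidate configuration marginalizes the belief;
choice is softmax in that expected reward, mirroring the RL model.  The
model is greedy: it maximizes expected reward on the current trial, with no
planning over the remainder of the game.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .. import task
from ..task import Configuration, GameSpec, Hint, Rule, Stimulus, Trial
from .base import BehavioralModel
from .values import log_softmax


@dataclass
class Belief:
    """Posterior over a fixed support of rules."""

    support: np.ndarray  # rule indices into the canonical 63-rule ordering
    probs: np.ndarray

    def __post_init__(self):
        self.support = np.asarray(self.support, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.support.shape != self.probs.shape:
            raise ValueError("support and probs must align")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("belief must be a normalized probability vector")

    def rules(self) -> list[Rule]:
        return [Rule.from_index(int(i)) for i in self.support]


@dataclass(frozen=True)
class BayesParams:
    beta: float

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


def init_belief(hint: Hint) -> Belief:
    support = task.rule_indices_for_hint(hint)
    return Belief(support, np.full(len(support), 1.0 / len(support)))


def update_belief(belief: Belief, stimulus: Stimulus, reward: int) -> Belief:
    """Multiply by the reward likelihood of the realized stimulus; renormalize."""
    lik = task.P_REWARD[belief.support, stimulus.index]
    if not reward:
        lik = 1.0 - lik
    post = belief.probs * lik
    return Belief(belief.support, post / post.sum())


def expected_rewards(belief: Belief) -> np.ndarray:
    """Belief-weighted expected reward for all 64 configurations."""
    return belief.probs @ task.ER_RULE_CONFIG[belief.support]


class BayesianRuleLearningModel(BehavioralModel):
    """Likelihood model: Bayesian rule learning with a single softmax parameter."""

    PARAM_NAMES = ("beta",)
    BOUNDS = {"beta": (0.01, 100.0)}
    LOG_SCALE = frozenset({"beta"})
    DEFAULTS = {"beta": 10.0}
    name = "bayes"

    def game_loglike(self, game_index: int, params: Mapping[str, float]) -> float:
        spec, choices, stims, rewards = self._games[game_index]
        beta = params["beta"]
        support = task.rule_indices_for_hint(spec.hint)
        er_table = task.ER_RULE_CONFIG[support]  # (|support|, 64)
        p_table = task.P_REWARD[support]  # (|support|, 27)
        b = np.full(len(support), 1.0 / len(support))
        total = 0.0
        for c, s, r in zip(choices, stims, rewards):
            total += log_softmax(b @ er_table, beta)[c]
            lik = p_table[:, s] if r else 1.0 - p_table[:, s]
            b = b * lik
            b /= b.sum()
        return float(total)


def simulate_game(
    spec: GameSpec, params: BayesParams, rng: np.random.Generator
) -> list[Trial]:
    """Generate one game from the Bayesian rule learner against the true rule."""
    rule_idx = spec.true_rule.index
    support = task.rule_indices_for_hint(spec.hint)
    er_table = task.ER_RULE_CONFIG[support]
    p_table = task.P_REWARD[support]
    b = np.full(len(support), 1.0 / len(support))
    trials = []
    for _ in range(spec.n_trials):
        p = np.exp(log_softmax(b @ er_table, params.beta))
        c = int(rng.choice(task.N_CONFIGS, p=p))
        s = task.realize_stimulus_index(c, rng)
        r = task.draw_reward(rule_idx, s, rng)
        trials.append(
            Trial(Configuration.from_index(c), task.Stimulus.from_index(s), r)
        )
        lik = p_table[:, s] if r else 1.0 - p_table[:, s]
        b = b * lik
        b /= b.sum()
    return trials
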