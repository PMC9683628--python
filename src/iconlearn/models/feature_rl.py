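"""Feature reinforcement learning with decay.

The learner maintains a value for each of the nine features.  The expected
reward of a configuration is the sum of its selected features' values (the
dimension mean stands in for unselected dimensions); choices are softmax in
the expected rewards over all 64 configurations.  After each outcome the
three features of the realized stimulus are updated by a Rescorla-Wagner
rule — with separate learning rates for participant-selected
(``eta_selected``) and computer-filled (``eta_random``) dimensions — and the
six absent features decay toward zero by a factor ``decay``.  Values reset
to zero at every game start (rules change between games).

The model has no way to use the dimensionality hint, which is exactly what
makes it a pure value-learning benchmark for the hypothesis-testing models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .. import task
from ..task import Configuration, GameSpec, Trial
from .base import BehavioralModel
from .values import expected_rewards_all_configs, log_softmax, update_values


@dataclass(frozen=True)
class RLParams:
    beta: float
    eta_selected: float
    eta_random: float
    decay: float

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        for name in ("eta_selected", "eta_random", "decay"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "beta": self.beta,
            "eta_selected": self.eta_selected,
            "eta_random": self.eta_random,
            "decay": self.decay,
        }


def expected_reward(values: np.ndarray, choice: Configuration) -> float:
    """ER of a single configuration under the additive feature-value rule."""
    return float(task.CONFIG_FEATURE_WEIGHTS[choice.index] @ np.asarray(values).ravel())


def choice_probabilities(values: np.ndarray, beta: float) -> np.ndarray:
    """Softmax choice distribution over the canonical 64 configurations."""
    er = expected_rewards_all_configs(np.asarray(values, dtype=float).ravel())
    return np.exp(log_softmax(er, beta))


def update(values: np.ndarray, trial: Trial, params: RLParams) -> np.ndarray:
    """One learning step; returns the new 3x3 value array."""
    if not trial.stimulus.matches(trial.choice):
        raise ValueError("trial stimulus inconsistent with choice")
    new = update_values(
        np.asarray(values, dtype=float).ravel(),
        trial.choice.index,
        trial.stimulus.index,
        trial.reward,
        params.eta_selected,
        params.eta_random,
        params.decay,
    )
    return new.reshape(3, 3)


class FeatureRLModel(BehavioralModel):
    """Likelihood model: feature RL with decay (four free parameters)."""

    PARAM_NAMES = ("beta", "eta_selected", "eta_random", "decay")
    BOUNDS = {
        "beta": (0.01, 100.0),
        "eta_selected": (0.0, 1.0),
        "eta_random": (0.0, 1.0),
        "decay": (0.0, 1.0),
    }
    LOG_SCALE = frozenset({"beta"})
    DEFAULTS = {"beta": 5.0, "eta_selected": 0.3, "eta_random": 0.15, "decay": 0.8}
    name = "feature_rl"

    def game_loglike(self, game_index: int, params: Mapping[str, float]) -> float:
        from ._kernels import HAVE_NUMBA, rl_loglik_kernel

        _, choices, stims, rewards = self._games[game_index]
        beta = params["beta"]
        if HAVE_NUMBA:
            return float(
                rl_loglik_kernel(
                    choices, stims, rewards,
                    float(beta),
                    float(params["eta_selected"]),
                    float(params["eta_random"]),
                    float(params["decay"]),
                    task.CONFIG_FEATURE_WEIGHTS,
                    task.CONFIG_SEL,
                )
            )
        v = np.zeros(9)
        total = 0.0
        for c, s, r in zip(choices, stims, rewards):
            er = expected_rewards_all_configs(v)
            total += log_softmax(er, beta)[c]
            v = update_values(
                v, int(c), int(s), int(r),
                params["eta_selected"], params["eta_random"], params["decay"],
            )
        return float(total)


def simulate_game(
    spec: GameSpec, params: RLParams, rng: np.random.Generator
) -> list[Trial]:
    """Generate one game from the feature-RL policy against the true rule."""
    rule_idx = spec.true_rule.index
    v = np.zeros(9)
    trials = []
    for _ in range(spec.n_trials):
        p = np.exp(log_softmax(expected_rewards_all_configs(v), params.beta))
        c = int(rng.choice(task.N_CONFIGS, p=p))
        s = task.realize_stimulus_index(c, rng)
        r = task.draw_reward(rule_idx, s, rng)
        trials.append(
            Trial(Configuration.from_index(c), task.Stimulus.from_index(s), r)
        )
        v = update_values(
            v, c, s, r, params.eta_selected, params.eta_random, params.decay
        )
    return trials
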