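import numpy as np
import pytest

from iconlearn import task
from iconlearn.task import Configuration, GameSpec, Rule, Session, Stimulus, Trial


def make_random_game(
    rng: np.random.Generator,
    complexity: int = 1,
    known: bool = True,
    n_trials: int = 4,
    complete_choices: bool = False,
) -> tuple[GameSpec, list[Trial]]:
    """A game with uniformly random (arbitrary-policy) choices and task rewards."""
    pool = np.flatnonzero(task.RULE_DIM == complexity)
    rule = Rule.from_index(int(rng.choice(pool)))
    spec = GameSpec(complexity, known, rule, n_trials=n_trials)
    trials = []
    for _ in range(n_trials):
        c = (
            int(rng.choice(task.COMPLETE_CONFIGS))
            if complete_choices
            else int(rng.integers(task.N_CONFIGS))
        )
        s = task.realize_stimulus_index(c, rng)
        r = task.draw_reward(rule.index, s, rng)
        trials.append(
            Trial(Configuration.from_index(c), Stimulus.from_index(s), r)
        )
    return spec, trials


def make_random_session(
    rng: np.random.Generator, n_games: int = 2, n_trials: int = 5
) -> Session:
    games = []
    for i in range(n_games):
        complexity = 1 + i % 3
        games.append(
            make_random_game(rng, complexity, known=bool(i % 2), n_trials=n_trials)
        )
    return Session(games, session_id="random")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def as_tuples(trials):
    """Trials in the plain-tuple convention used by the oracle scripts."""
    return [(t.choice.selection, t.stimulus.features, t.reward) for t in trials]
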