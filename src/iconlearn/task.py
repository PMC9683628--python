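"""Combinatorial structure and reward law of the "build your own icon" task.

Stimuli live in three dimensions (color, shape, texture), each with three
features.  On every trial the learner selects features in zero to three
dimensions (a :class:`Configuration`); the computer fills the remaining
dimensions uniformly at random, producing a complete :class:`Stimulus`.
Reward is Bernoulli with a probability determined by how many of the hidden
rule's rewarding features appear in the stimulus: 0.2 with no rewarding
feature, 0.8 with all of them, linearly interpolated in between.  This
interpolation makes the chance reward rate exactly 0.4 in every game type,
so random behavior carries no information about rule dimensionality.

Everything downstream (learning models, likelihoods, simulators) works on
the canonical integer indexings defined here:

* 64 configurations: per-dimension digit in {0..3}, 0 = no selection,
  1..3 = feature 0..2; index = d0*16 + d1*4 + d2, so index 0 is the empty
  configuration.
* 27 stimuli: index = f0*9 + f1*3 + f2.
* 63 rules (non-empty partial assignments), ordered by dimensionality then
  lexicographically by assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional, Sequence, Union

import numpy as np

N_DIMS = 3
N_FEATURES = 3
N_CONFIGS = 4**N_DIMS  # 64
N_STIMULI = N_FEATURES**N_DIMS  # 27
N_RULES = N_CONFIGS - 1  # 63 non-empty partial assignments

DIMENSION_NAMES = ("color", "shape", "texture")

REWARD_P_MIN = 0.2
REWARD_P_MAX = 0.8

Hint = Union[int, str]  # 1 | 2 | 3 | "unknown"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Configuration:
    """A (possibly partial) feature selection: one optional feature per dimension."""

    selection: tuple[Optional[int], Optional[int], Optional[int]]

    def __post_init__(self) -> None:
        if len(self.selection) != N_DIMS:
            raise ValueError("configuration must cover exactly 3 dimensions")
        for f in self.selection:
            if f is not None and f not in range(N_FEATURES):
                raise ValueError(f"feature index out of range: {f!r}")

    @property
    def n_selected(self) -> int:
        return sum(f is not None for f in self.selection)

    @property
    def index(self) -> int:
        idx = 0
        for f in self.selection:
            idx = idx * 4 + (0 if f is None else f + 1)
        return idx

    @classmethod
    def from_index(cls, index: int) -> "Configuration":
        if not 0 <= index < N_CONFIGS:
            raise ValueError(f"configuration index out of range: {index}")
        digits = []
        for place in (16, 4, 1):
            d, index = divmod(index, place)
            digits.append(None if d == 0 else d - 1)
        return cls(tuple(digits))  # type: ignore[arg-type]

    @classmethod
    def empty(cls) -> "Configuration":
        return cls((None, None, None))


@dataclass(frozen=True)
class Stimulus:
    """A complete icon: one feature in every dimension."""

    features: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.features) != N_DIMS or any(
            f not in range(N_FEATURES) for f in self.features
        ):
            raise ValueError(f"invalid stimulus features: {self.features!r}")

    @property
    def index(self) -> int:
        f0, f1, f2 = self.features
        return f0 * 9 + f1 * 3 + f2

    @classmethod
    def from_index(cls, index: int) -> "Stimulus":
        if not 0 <= index < N_STIMULI:
            raise ValueError(f"stimulus index out of range: {index}")
        f0, rest = divmod(index, 9)
        f1, f2 = divmod(rest, 3)
        return cls((f0, f1, f2))

    def matches(self, config: Configuration) -> bool:
        """Does this stimulus agree with ``config`` on every selected dimension?"""
        return all(
            c is None or c == f for c, f in zip(config.selection, self.features)
        )


@dataclass(frozen=True)
class Rule:
    """A non-empty partial assignment of rewarding features.

    Rules double as the game's hidden ground truth and as the hypotheses
    learners entertain about it.
    """

    assignment: tuple[Optional[int], Optional[int], Optional[int]]

    def __post_init__(self) -> None:
        if all(f is None for f in self.assignment):
            raise ValueError("rule must assign at least one dimension")
        for f in self.assignment:
            if f is not None and f not in range(N_FEATURES):
                raise ValueError(f"feature index out of range: {f!r}")

    @property
    def dimensionality(self) -> int:
        return sum(f is not None for f in self.assignment)

    @property
    def config_index(self) -> int:
        """Index of the configuration that selects exactly this rule's features."""
        return Configuration(self.assignment).index

    @property
    def index(self) -> int:
        """Position in the canonical 63-rule ordering."""
        return int(_RULE_INDEX_BY_CONFIG[self.config_index])

    @classmethod
    def from_index(cls, index: int) -> "Rule":
        if not 0 <= index < N_RULES:
            raise ValueError(f"rule index out of range: {index}")
        cfg = Configuration.from_index(int(RULE_CONFIG[index]))
        return cls(cfg.selection)

    def matches(self, stimulus: Stimulus) -> int:
        """Number of assigned dimensions on which ``stimulus`` carries the rewarding feature."""
        return sum(
            a is not None and a == f
            for a, f in zip(self.assignment, stimulus.features)
        )


@dataclass(frozen=True)
class GameSpec:
    """One game: a hidden rule played for ``n_trials`` trials.

    ``known`` games reveal the rule's dimensionality (the "hint") to the
    learner before the game starts; the rule itself is never revealed.
    """

    complexity: int
    known: bool
    true_rule: Rule
    n_trials: int = 30

    def __post_init__(self) -> None:
        if self.complexity not in (1, 2, 3):
            raise ValueError(f"complexity must be 1, 2 or 3, got {self.complexity}")
        if self.true_rule.dimensionality != self.complexity:
            raise ValueError(
                "true rule dimensionality "
                f"{self.true_rule.dimensionality} != complexity {self.complexity}"
            )
        if self.n_trials < 1:
            raise ValueError("n_trials must be positive")

    @property
    def hint(self) -> Hint:
        """What the learner is told: the complexity in known games, else 'unknown'."""
        return self.complexity if self.known else "unknown"

    @property
    def game_type(self) -> str:
        return f"{self.complexity}D-{'known' if self.known else 'unknown'}"


@dataclass(frozen=True)
class Trial:
    choice: Configuration
    stimulus: Stimulus
    reward: int

    def __post_init__(self) -> None:
        if self.reward not in (0, 1):
            raise ValueError(f"reward must be 0 or 1, got {self.reward!r}")
        if not self.stimulus.matches(self.choice):
            raise ValueError(
                "stimulus disagrees with choice on a selected dimension: "
                f"{self.choice.selection} vs {self.stimulus.features}"
            )


@dataclass
class Session:
    """An ordered list of games with their trials — the unit of fitting and CV."""

    games: list[tuple[GameSpec, list[Trial]]]
    session_id: str = "agent"
    #: optional per-game latent hypothesis trajectories (diagnostics only;
    #: never consumed by fitting) and free-form metadata
    latents: Optional[list[Optional[list[int]]]] = field(
        default=None, repr=False, compare=False
    )
    meta: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_games(self) -> int:
        return len(self.games)

    @property
    def n_trials(self) -> int:
        return sum(len(trials) for _, trials in self.games)

    def drop_game(self, i: int) -> "Session":
        games = [g for j, g in enumerate(self.games) if j != i]
        return Session(games, session_id=self.session_id)

    def subset(self, indices: Iterable[int]) -> "Session":
        return Session([self.games[i] for i in indices], session_id=self.session_id)


# ---------------------------------------------------------------------------
# Canonical tables (computed once at import)
# ---------------------------------------------------------------------------


def _build_tables():
    # configuration selections: -1 marks an unselected dimension
    config_sel = np.empty((N_CONFIGS, N_DIMS), dtype=np.int8)
    for idx in range(N_CONFIGS):
        d0, rest = divmod(idx, 16)
        d1, d2 = divmod(rest, 4)
        config_sel[idx] = [d - 1 for d in (d0, d1, d2)]
    config_ndims = (config_sel >= 0).sum(axis=1).astype(np.int8)

    stim_feat = np.array(
        list(product(range(N_FEATURES), repeat=N_DIMS)), dtype=np.int8
    )

    # rules: non-empty configurations sorted by (dimensionality, assignment)
    rule_cfgs = [i for i in range(1, N_CONFIGS)]
    def rule_key(cfg: int):
        sel = config_sel[cfg]
        return (
            int((sel >= 0).sum()),
            tuple((int(d), int(f)) for d, f in enumerate(sel) if f >= 0),
        )
    rule_cfgs.sort(key=rule_key)
    rule_config = np.array(rule_cfgs, dtype=np.int16)
    rule_assign = config_sel[rule_config]
    rule_dim = config_ndims[rule_config].astype(np.int8)
    rule_index_by_config = np.full(N_CONFIGS, -1, dtype=np.int16)
    rule_index_by_config[rule_config] = np.arange(N_RULES)

    # reward probability table P(r=1 | rule, stimulus)
    match = (
        (rule_assign[:, None, :] == stim_feat[None, :, :])
        & (rule_assign[:, None, :] >= 0)
    ).sum(axis=2)
    p_reward = REWARD_P_MIN + (REWARD_P_MAX - REWARD_P_MIN) * match / rule_dim[:, None]

    # stimulus-fill distribution per configuration: P(stimulus | choice) under
    # uniform-independent computer fill of unselected dimensions
    sel_match = (config_sel[:, None, :] == stim_feat[None, :, :]) | (
        config_sel[:, None, :] < 0
    )
    consistent = sel_match.all(axis=2)  # (64, 27)
    fill = consistent / consistent.sum(axis=1, keepdims=True)

    # expected reward of each configuration under each rule
    er_rule_config = p_reward @ fill.T  # (63, 64)

    # feature-weight matrix for additive value models: ER(c) = W[c] @ V.ravel()
    w = np.zeros((N_CONFIGS, N_DIMS * N_FEATURES))
    for c in range(N_CONFIGS):
        for d in range(N_DIMS):
            f = config_sel[c, d]
            if f >= 0:
                w[c, d * N_FEATURES + f] = 1.0
            else:
                w[c, d * N_FEATURES : (d + 1) * N_FEATURES] = 1.0 / N_FEATURES

    # superset structure: config c is a superset of rule h if it selects the
    # rule's feature on every dimension the rule assigns
    sup = (
        (rule_assign[:, None, :] < 0)
        | (rule_assign[:, None, :] == config_sel[None, :, :])
    ).all(axis=2)  # (63, 64)

    return (
        config_sel,
        config_ndims,
        stim_feat,
        rule_config,
        rule_assign,
        rule_dim,
        rule_index_by_config,
        p_reward,
        consistent,
        fill,
        er_rule_config,
        w,
        sup,
    )


(
    CONFIG_SEL,
    CONFIG_NDIMS,
    STIM_FEAT,
    RULE_CONFIG,
    RULE_ASSIGN,
    RULE_DIM,
    _RULE_INDEX_BY_CONFIG,
    P_REWARD,
    STIM_CONSISTENT,
    STIM_FILL,
    ER_RULE_CONFIG,
    CONFIG_FEATURE_WEIGHTS,
    RULE_SUPERSETS,
) = _build_tables()

COMPLETE_CONFIGS = np.flatnonzero(CONFIG_NDIMS == 3)
EMPTY_CONFIG = 0


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def reward_probability(rule: Rule, stimulus: Stimulus) -> float:
    """Bernoulli reward parameter for a stimulus under a rule.

    Linear interpolation between 0.2 (no rewarding feature present) and 0.8
    (all present): ``0.2 + 0.6 * matches / dimensionality``.
    """
    return float(P_REWARD[rule.index, stimulus.index])


def enumerate_rules(hint: Hint) -> list[Rule]:
    """All rules consistent with a hint, in canonical order.

    ``hint`` 1, 2, 3 selects rules of that dimensionality (9, 27 and 27
    rules); ``"unknown"`` returns all 63.
    """
    idx = rule_indices_for_hint(hint)
    return [Rule.from_index(int(i)) for i in idx]


def rule_indices_for_hint(hint: Hint) -> np.ndarray:
    if hint == "unknown":
        return np.arange(N_RULES)
    if hint in (1, 2, 3):
        return np.flatnonzero(RULE_DIM == hint)
    raise ValueError(f"hint must be 1, 2, 3 or 'unknown', got {hint!r}")


def enumerate_configurations() -> list[Configuration]:
    """All 64 configurations in canonical order; index 0 is the empty one."""
    return [Configuration.from_index(i) for i in range(N_CONFIGS)]


def expected_reward_under_rule(rule: Rule, choice: Configuration) -> float:
    """Expected reward of a (possibly partial) choice under a rule.

    Unselected dimensions are marginalized over the computer's uniform fill.
    """
    return float(ER_RULE_CONFIG[rule.index, choice.index])


def chance_reward_probability(complexity: int) -> float:
    """Expected reward of a uniformly random complete stimulus, by enumeration.

    Equal to 0.4 for every complexity — the task's chance-rate guarantee.
    """
    if complexity not in (1, 2, 3):
        raise ValueError(f"complexity must be 1, 2 or 3, got {complexity}")
    rule_idx = int(np.flatnonzero(RULE_DIM == complexity)[0])
    return float(P_REWARD[rule_idx].mean())


def realize_stimulus(
    choice: Configuration, rng: np.random.Generator
) -> Stimulus:
    """Complete a choice into a stimulus, filling unselected dimensions uniformly."""
    feats = tuple(
        int(f) if f is not None else int(rng.integers(N_FEATURES))
        for f in choice.selection
    )
    return Stimulus(feats)  # type: ignore[arg-type]


def realize_stimulus_index(choice_idx: int, rng: np.random.Generator) -> int:
    """Array-level counterpart of :func:`realize_stimulus`."""
    sel = CONFIG_SEL[choice_idx]
    feats = np.where(sel >= 0, sel, rng.integers(N_FEATURES, size=N_DIMS))
    return int(feats[0] * 9 + feats[1] * 3 + feats[2])


def draw_reward(rule_idx: int, stim_idx: int, rng: np.random.Generator) -> int:
    return int(rng.random() < P_REWARD[rule_idx, stim_idx])


def game_arrays(trials: Sequence[Trial]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Choice, stimulus and reward index arrays for a list of trials."""
    choices = np.array([t.choice.index for t in trials], dtype=np.int64)
    stims = np.array([t.stimulus.index for t in trials], dtype=np.int64)
    rewards = np.array([t.reward for t in trials], dtype=np.int64)
    return choices, stims, rewards


GAME_TYPES = tuple(
    f"{d}D-{k}" for d in (1, 2, 3) for k in ("known", "unknown")
)
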