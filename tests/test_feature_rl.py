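"""Feature RL with decay: expected reward, softmax choice, learning, simulation."""

import numpy as np
import pytest

from conftest import as_tuples, make_random_game
from oracles import rl_trace_loglik

from iconlearn import task
from iconlearn.models.feature_rl import (
    FeatureRLModel,
    RLParams,
    choice_probabilities,
    expected_reward,
    simulate_game,
    update,
)
from iconlearn.task import Configuration, GameSpec, Rule, Session, Stimulus, Trial


class TestExpectedReward:
    def test_zero_values_give_zero(self):
        assert expected_reward(np.zeros((3, 3)), Configuration((0, 1, None))) == 0.0

    def test_selected_sum_with_dimension_mean(self):
        v = np.array([[0.5, 0, 0], [0, 0.3, 0], [0.1, 0.2, 0.3]])
        choice = Configuration((0, 1, None))
        assert expected_reward(v, choice) == pytest.approx(0.5 + 0.3 + 0.2)

    def test_empty_choice_sums_dimension_means(self):
        v = np.arange(9, dtype=float).reshape(3, 3)
        assert expected_reward(v, Configuration.empty()) == pytest.approx(
            v.mean(axis=1).sum()
        )


class TestChoiceRule:
    def test_beta_zero_is_uniform(self, rng):
        p = choice_probabilities(rng.normal(size=(3, 3)), beta=0.0)
        assert np.allclose(p, 1 / 64)

    def test_normalization_and_symmetry(self, rng):
        v = rng.normal(size=(3, 3))
        p = choice_probabilities(v, beta=7.3)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        # configurations with equal expected reward get equal probability
        er = task.CONFIG_FEATURE_WEIGHTS @ v.ravel()
        i, j = 0, int(np.flatnonzero(np.isclose(er, er[0]))[-1])
        assert p[i] == pytest.approx(p[j])

    def test_greedy_on_true_values_attains_max_reward(self):
        rule = Rule((0, 1, 2))
        v = np.zeros((3, 3))
        for d, f in enumerate(rule.assignment):
            v[d, f] = 1.0
        p = choice_probabilities(v, beta=80.0)
        best = int(np.argmax(p))
        stim = Stimulus(Configuration.from_index(best).selection)
        assert task.reward_probability(rule, stim) == pytest.approx(0.8)


class TestUpdate:
    def test_positive_surprise_updates_stimulus_features(self):
        params = RLParams(beta=1, eta_selected=0.5, eta_random=0.3, decay=0.5)
        trial = Trial(Configuration((0, 1, 2)), Stimulus((0, 1, 2)), 1)
        v = update(np.zeros((3, 3)), trial, params)
        assert v[0, 0] == v[1, 1] == v[2, 2] == pytest.approx(0.5)
        assert np.count_nonzero(v) == 3

    def test_random_fill_uses_other_learning_rate(self):
        params = RLParams(beta=1, eta_selected=0.5, eta_random=0.25, decay=1.0)
        trial = Trial(Configuration((0, None, None)), Stimulus((0, 2, 1)), 1)
        v = update(np.zeros((3, 3)), trial, params)
        assert v[0, 0] == pytest.approx(0.5)
        assert v[1, 2] == v[2, 1] == pytest.approx(0.25)

    def test_absent_features_decay(self):
        params = RLParams(beta=1, eta_selected=0.0, eta_random=0.0, decay=0.5)
        v0 = np.zeros((3, 3))
        v0[0, 1] = 0.4  # not in the upcoming stimulus
        trial = Trial(Configuration((0, 0, 0)), Stimulus((0, 0, 0)), 1)
        v = update(v0, trial, params)
        assert v[0, 1] == pytest.approx(0.2)

    def test_zero_prediction_error_and_no_decay_is_identity(self):
        params = RLParams(beta=1, eta_selected=0.7, eta_random=0.7, decay=1.0)
        v0 = np.zeros((3, 3))
        v0[:, 0] = 1.0 / 3  # ER of the full (0,0,0) choice is 1
        trial = Trial(Configuration((0, 0, 0)), Stimulus((0, 0, 0)), 1)
        assert np.allclose(update(v0, trial, params), v0)


class TestSessionLoglik:
    def test_beta_zero_is_chance(self, rng):
        session = Session([make_random_game(rng, 2, True, n_trials=6)])
        m = FeatureRLModel(session)
        ll = m.loglike(
            dict(beta=0.01, eta_selected=0.0, eta_random=0.0, decay=1.0)
        )
        # eta = 0, d = 1: values never move, so behavior is uniform
        assert ll == pytest.approx(6 * np.log(1 / 64))

    def test_loglik_nonpositive(self, rng):
        session = Session([make_random_game(rng, 1, False, n_trials=8)])
        m = FeatureRLModel(session)
        assert m.loglike(dict(beta=4, eta_selected=0.4, eta_random=0.2, decay=0.8)) < 0

    def test_matches_handrolled_trace(self, rng):
        spec, trials = make_random_game(rng, 3, True, n_trials=5)
        m = FeatureRLModel(Session([(spec, trials)]))
        ours = m.loglike(dict(beta=3.2, eta_selected=0.45, eta_random=0.2, decay=0.7))
        ref = rl_trace_loglik(as_tuples(trials), 3.2, 0.45, 0.2, 0.7)
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_values_reset_between_games(self, rng):
        g1 = make_random_game(rng, 1, True, n_trials=5)
        g2 = make_random_game(rng, 1, True, n_trials=5)
        p = dict(beta=5, eta_selected=0.5, eta_random=0.3, decay=0.8)
        both = FeatureRLModel(Session([g1, g2])).loglike(p)
        separate = (
            FeatureRLModel(Session([g1])).loglike(p)
            + FeatureRLModel(Session([g2])).loglike(p)
        )
        assert both == pytest.approx(separate, abs=1e-10)


class TestSimulation:
    def test_fixed_seed_reproduces_trials(self):
        spec = GameSpec(2, True, Rule((1, 2, None)), n_trials=15)
        params = RLParams(beta=5, eta_selected=0.4, eta_random=0.2, decay=0.8)
        t1 = simulate_game(spec, params, np.random.default_rng(42))
        t2 = simulate_game(spec, params, np.random.default_rng(42))
        assert t1 == t2

    def test_indifferent_agent_earns_chance_reward(self):
        rng = np.random.default_rng(7)
        params = RLParams(beta=0, eta_selected=0.3, eta_random=0.2, decay=0.9)
        rewards = []
        for _ in range(60):
            spec = GameSpec(2, False, Rule((0, 1, None)), n_trials=30)
            rewards += [t.reward for t in simulate_game(spec, params, rng)]
        n = len(rewards)
        se = np.sqrt(0.4 * 0.6 / n)
        assert abs(np.mean(rewards) - 0.4) < 3 * se
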