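"""Serial hypothesis testing: priors, policies, forward filter, simulation."""

import numpy as np
import pytest

from conftest import as_tuples, make_random_game, make_random_session
from oracles import sht_path_loglik

from iconlearn import task
from iconlearn.models import _kernels
from iconlearn.models.sht import (
    HypothesisCounter,
    SHTParams,
    SerialHypothesisTestingModel,
    choice_given_hypothesis,
    forward_loglik,
    hypothesis_prior,
    p_hat,
    rp_target,
    simulate_game,
    stay_probability,
    switch_distribution,
)
from iconlearn.models.sht import test_probability as gate_probability
from iconlearn.task import GameSpec, Rule, Session


class TestHypothesisPrior:
    def test_strict_instruction_following_limit(self):
        prior = hypothesis_prior(1, w_l=0.0, w_h=0.0)
        on = prior[task.RULE_DIM == 1]
        assert np.allclose(on, 1 / 9)
        assert prior[task.RULE_DIM != 1].sum() == 0.0

    def test_flat_weights_give_uniform_prior(self):
        assert np.allclose(hypothesis_prior(2, 1.0, 1.0), 1 / 63)

    def test_hand_normalization_known_2d(self):
        prior = hypothesis_prior(2, w_l=0.5, w_h=0.2)
        z = 9 * 0.5 + 27 * 1.0 + 27 * 0.2
        assert np.allclose(prior[task.RULE_DIM == 2], 1.0 / z)
        assert np.allclose(prior[task.RULE_DIM == 1], 0.5 / z)
        assert np.allclose(prior[task.RULE_DIM == 3], 0.2 / z)

    def test_unknown_games_average_the_known_priors(self):
        w_l, w_h = 0.4, 0.7
        known = np.mean(
            [hypothesis_prior(d, w_l, w_h) for d in (1, 2, 3)], axis=0
        )
        assert np.allclose(hypothesis_prior("unknown", w_l, w_h), known)
        assert hypothesis_prior("unknown", w_l, w_h).sum() == pytest.approx(1.0)


class TestStayPolicy:
    def test_reward_estimate_examples(self):
        assert p_hat(HypothesisCounter(0, 0)) == pytest.approx(0.5)
        assert p_hat(HypothesisCounter(3, 4)) == pytest.approx(4 / 6)
        assert p_hat(HypothesisCounter(0, 8)) == pytest.approx(0.1)

    def test_sigmoid_midpoint_and_limits(self):
        params = SHTParams(beta_stay=10.0, theta=0.5)
        assert stay_probability(HypothesisCounter(1, 2), params) == pytest.approx(0.5)
        hot = SHTParams(beta_stay=1e4, theta=0.5)
        assert stay_probability(HypothesisCounter(8, 8), hot) == pytest.approx(1.0)
        assert stay_probability(HypothesisCounter(0, 8), hot) == pytest.approx(0.0)
        flat = SHTParams(beta_stay=0.0, theta=0.9)
        assert stay_probability(HypothesisCounter(5, 5), flat) == pytest.approx(0.5)

    def test_monotone_in_reward_count(self):
        params = SHTParams(beta_stay=6.0, theta=0.55)
        probs = [
            stay_probability(HypothesisCounter(a, 10), params) for a in range(11)
        ]
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_rp_target_values(self):
        game3 = GameSpec(3, True, Rule((0, 1, 2)))
        assert rp_target(Rule((0, None, None)), game3) == pytest.approx(0.4)
        unknown = GameSpec(2, False, Rule((0, 1, None)))
        assert rp_target(Rule((0, 1, None)), unknown) == pytest.approx(0.733)
        for game in (game3, unknown):
            assert rp_target(Rule((0, 1, 2)), game) == pytest.approx(0.8)

    def test_rp_target_threshold_enters_stay_rule(self):
        game3 = GameSpec(3, True, Rule((0, 1, 2)))
        params = SHTParams(beta_stay=5.0, rp_target=True, delta=0.1)
        # p_hat = 0.5, theta = 0.4 + 0.1: sigmoid midpoint
        assert stay_probability(
            HypothesisCounter(0, 0), params, Rule((0, None, None)), game3
        ) == pytest.approx(0.5)


class TestSwitchAndTestPolicies:
    def test_value_policy_with_flat_values_is_uniform(self):
        game = GameSpec(1, False, Rule((0, None, None)))
        params = SHTParams(switch_policy="value", beta_switch=4.0)
        prev = Rule((1, None, None))
        dist = switch_distribution(prev, params, np.zeros(9), game)
        assert dist[prev.index] == 0.0
        assert np.allclose(dist[dist > 0], 1 / 62)

    def test_beta_switch_zero_is_uniform(self, rng):
        game = GameSpec(2, False, Rule((0, 1, None)))
        params = SHTParams(switch_policy="value", beta_switch=0.0)
        dist = switch_distribution(
            Rule((0, 1, None)), params, rng.normal(size=9), game
        )
        assert np.allclose(dist[dist > 0], 1 / 62)

    def test_random_policy_renormalizes_uniform_prior(self):
        game = GameSpec(3, False, Rule((0, 1, 2)))
        params = SHTParams(w_l=1.0, w_h=1.0)
        dist = switch_distribution(Rule((2, 2, 2)), params, game=game)
        assert np.allclose(dist[dist > 0], 1 / 62)
        assert dist.sum() == pytest.approx(1.0)

    def test_value_policy_prefers_valuable_hypotheses(self):
        game = GameSpec(1, False, Rule((0, None, None)))
        v = np.zeros(9)
        v[0] = 1.0  # feature 0 of dimension 0
        params = SHTParams(switch_policy="value", beta_switch=3.0)
        dist = switch_distribution(Rule((None, 1, None)), params, v, game)
        good, bad = Rule((0, None, None)), Rule((1, None, None))
        assert dist[good.index] > dist[bad.index]

    def test_test_probability_midpoint_and_limits(self):
        support = np.arange(63)
        v = np.zeros(9)
        mid = SHTParams(test_gate=True, beta_test=8.0, theta_test=0.0)
        assert gate_probability(v, mid, support) == pytest.approx(0.5)
        flat = SHTParams(test_gate=True, beta_test=0.0, theta_test=0.9)
        assert gate_probability(v, flat, support) == pytest.approx(0.5)
        shy = SHTParams(test_gate=True, beta_test=1e4, theta_test=0.9)
        assert gate_probability(v, shy, support) == pytest.approx(0.0)


class TestChoicePolicy:
    def test_no_lapse_is_point_mass_on_hypothesis_configuration(self):
        h = Rule((2, None, 1))
        p = choice_given_hypothesis(h, SHTParams(lapse=0.0))
        assert p[h.config_index] == pytest.approx(1.0)
        assert p.sum() == pytest.approx(1.0)

    def test_lapse_mixture_normalizes(self, rng):
        for lam in (0.1, 0.5, 1.0):
            p = choice_given_hypothesis(Rule((0, 1, 2)), SHTParams(lapse=lam))
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert p.min() == pytest.approx(lam / 64)

    def test_superset_policy_uniform_at_k_zero(self):
        h = Rule((1, None, None))
        p = choice_given_hypothesis(
            h, SHTParams(lapse=0.0, superset_choice=True, k=0.0)
        )
        sup = task.RULE_SUPERSETS[h.index]
        assert sup.sum() == 16
        assert np.allclose(p[sup], 1 / 16)
        assert np.allclose(p[~sup], 0.0)

    def test_superset_lapse_lands_outside_supersets(self):
        h = Rule((1, 0, None))
        lam = 0.2
        p = choice_given_hypothesis(
            h, SHTParams(lapse=lam, superset_choice=True, k=1.0)
        )
        sup = task.RULE_SUPERSETS[h.index]
        assert p[~sup].sum() == pytest.approx(lam)
        assert p.sum() == pytest.approx(1.0)


class TestForwardFilter:
    def test_full_lapse_is_chance(self, rng):
        spec, trials = make_random_game(rng, 2, True, n_trials=9)
        ll = forward_loglik((spec, trials), SHTParams(lapse=1.0))
        assert ll == pytest.approx(9 * np.log(1 / 64))

    def test_single_trial_closed_form(self, rng):
        spec, trials = make_random_game(rng, 1, True, n_trials=1)
        params = SHTParams(w_l=0.3, w_h=0.2, lapse=0.25)
        prior = hypothesis_prior(spec.hint, 0.3, 0.2)
        c = trials[0].choice.index
        lam = 0.25
        manual = np.log(
            sum(
                prior[h]
                * (lam / 64 + (1 - lam) * (task.RULE_CONFIG[h] == c))
                for h in range(63)
            )
        )
        assert forward_loglik((spec, trials), params) == pytest.approx(manual)

    @pytest.mark.parametrize("variant", ["base", "value", "gate", "rp", "super"])
    def test_matches_path_enumeration(self, variant, rng):
        kw = dict(
            w_l=0.0, w_h=0.0, beta_stay=6.0, theta=0.45, lapse=0.12
        )
        if variant == "value":
            kw.update(switch_policy="value", eta=0.4, decay=0.85, beta_switch=3.0)
        elif variant == "gate":
            kw.update(
                switch_policy="value", eta=0.3, decay=0.9, beta_switch=2.0,
                test_gate=True, beta_test=4.0, theta_test=0.3,
            )
        elif variant == "rp":
            kw.pop("theta")
            kw.update(rp_target=True, delta=-0.1)
        elif variant == "super":
            kw.update(superset_choice=True, k=0.8)
        for _ in range(3):
            spec, trials = make_random_game(rng, 1, True, n_trials=4)
            ours = forward_loglik((spec, trials), SHTParams(**kw))
            ref = sht_path_loglik(as_tuples(trials), spec.hint, **kw)
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_numba_and_numpy_paths_agree(self, rng):
        if not _kernels.HAVE_NUMBA:
            # single-path build: nothing to compare
            return
        spec, trials = make_random_game(rng, 2, False, n_trials=12)
        params = SHTParams(
            w_l=0.5, w_h=0.8, beta_stay=9.0, theta=0.6, lapse=0.08,
            switch_policy="value", eta=0.35, decay=0.9, beta_switch=6.0,
            test_gate=True, beta_test=3.0, theta_test=0.2,
        )
        fast = forward_loglik((spec, trials), params)
        slow, preds = forward_loglik((spec, trials), params, return_predictive=True)
        assert fast == pytest.approx(slow, abs=1e-10)
        assert np.allclose(preds.sum(axis=1), 1.0, atol=1e-10)

    def test_random_switch_is_special_case_of_value_switch(self, rng):
        session = make_random_session(rng, n_games=4, n_trials=10)
        base = dict(w_l=1.0, w_h=1.0, beta_stay=7.0, theta=0.5, lapse=0.15)
        for spec, trials in session.games:
            a = forward_loglik((spec, trials), SHTParams(**base))
            b = forward_loglik(
                (spec, trials),
                SHTParams(
                    **base, switch_policy="value", eta=0.0, decay=0.4,
                    beta_switch=0.0,
                ),
            )
            assert a == pytest.approx(b, abs=1e-10)

    def test_zero_probability_choice_reported_as_neg_inf(self):
        # lapse-free agent cannot produce a choice matching no hypothesis
        rng = np.random.default_rng(0)
        spec, trials = make_random_game(rng, 1, True, n_trials=1)
        bad = trials[0].choice.index == task.RULE_CONFIG[task.RULE_DIM == 1]
        if not bad.any():
            ll = forward_loglik(
                (spec, trials), SHTParams(w_l=0.0, w_h=0.0, lapse=0.0)
            )
            assert ll == -np.inf

    def test_extreme_beta_switch_remains_finite(self, rng):
        spec, trials = make_random_game(rng, 1, False, n_trials=20)
        params = SHTParams(
            beta_stay=50.0, theta=0.9, lapse=0.05, switch_policy="value",
            eta=1.0, decay=1.0, beta_switch=100.0,
        )
        assert np.isfinite(forward_loglik((spec, trials), params))


class TestSimulation:
    def test_never_switching_agent_repeats_its_choice(self):
        spec = GameSpec(2, True, Rule((0, 1, None)), n_trials=12)
        params = SHTParams(beta_stay=1e6, theta=0.0, lapse=0.0)
        trials, latents = simulate_game(spec, params, np.random.default_rng(5))
        assert len(set(latents)) == 1
        assert len({t.choice.index for t in trials}) == 1

    def test_always_switching_agent_changes_hypothesis_every_trial(self):
        spec = GameSpec(1, False, Rule((2, None, None)), n_trials=20)
        params = SHTParams(beta_stay=1e6, theta=1.0, lapse=0.0)
        _, latents = simulate_game(spec, params, np.random.default_rng(6))
        assert all(a != b for a, b in zip(latents, latents[1:]))

    def test_seed_reproducibility(self):
        spec = GameSpec(3, False, Rule((0, 1, 2)), n_trials=15)
        params = SHTParams(
            switch_policy="value", eta=0.4, decay=0.9, beta_switch=5.0,
            beta_stay=15.0, theta=0.55, lapse=0.1,
        )
        a = simulate_game(spec, params, np.random.default_rng(11))
        b = simulate_game(spec, params, np.random.default_rng(11))
        assert a == b

    def test_test_gate_agent_starts_with_empty_configurations(self):
        spec = GameSpec(1, True, Rule((0, None, None)), n_trials=10)
        params = SHTParams(
            switch_policy="value", eta=0.3, decay=0.9, beta_switch=3.0,
            lapse=0.0, test_gate=True, beta_test=1e6, theta_test=2.0,
        )
        # no hypothesis value can reach theta_test: the agent never tests
        trials, latents = simulate_game(spec, params, np.random.default_rng(2))
        assert all(h == -1 for h in latents)
        assert all(t.choice.n_selected == 0 for t in trials)


class TestModelInterface:
    def test_free_parameters_follow_configuration(self, rng):
        session = make_random_session(rng)
        m = SerialHypothesisTestingModel(session, switch_policy="random")
        assert m.PARAM_NAMES == ("w_l", "w_h", "beta_stay", "theta", "lapse")
        m = SerialHypothesisTestingModel(
            session, switch_policy="value", rp_target=True, superset_choice=True
        )
        assert "delta" in m.PARAM_NAMES and "theta" not in m.PARAM_NAMES
        assert {"eta", "decay", "beta_switch", "k"} <= set(m.PARAM_NAMES)

    def test_fixed_parameters_are_pinned(self, rng):
        session = make_random_session(rng)
        m = SerialHypothesisTestingModel(
            session, fixed={"w_l": 0.0, "w_h": 0.0}
        )
        assert "w_l" not in m.free_names
        ll = m.loglike(dict(beta_stay=5.0, theta=0.5, lapse=0.2))
        assert np.isfinite(ll)
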