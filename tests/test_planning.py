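import numpy as np
import pytest
from hypothesis import given, strategies as st

from gridforage import (
    ACTIONS,
    GridGeometry,
    build_geocache_model,
    enumerate_policies,
    expected_free_energy,
    novelty_term,
    policy_posterior,
    predicted_outcomes,
    score_policy_set,
    select_action,
    update_precision,
)
from gridforage.planning import PrecisionState, action_marginal


class TestEnumeratePolicies:
    def test_five_actions_depth_four_gives_625(self):
        assert len(enumerate_policies(ACTIONS, 4)) == 625

    def test_two_actions_depth_one(self):
        assert enumerate_policies(("up", "down"), 1) == [("up",), ("down",)]

    def test_lexicographic_contract_depth_two(self):
        ps = enumerate_policies(ACTIONS, 2)
        assert len(ps) == 25
        assert ps[0] == ("up", "up")
        assert ps[-1] == ("stay", "stay")

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            enumerate_policies(ACTIONS, 0)


class TestPredictedOutcomes:
    def test_delta_belief_at_target_certain_reward(self):
        model = build_geocache_model(GridGeometry(10, 10), 42)
        s = np.zeros(100)
        s[42] = 1.0
        o = predicted_outcomes(model, s)
        assert np.allclose(o["what"], [1.0, 0.0])

    def test_uniform_belief_over_100_states(self):
        model = build_geocache_model(GridGeometry(10, 10), 42)
        o = predicted_outcomes(model, np.full(100, 0.01))
        assert np.allclose(o["what"], [0.01, 0.99])

    def test_symmetric_dirichlet_mean_is_half(self):
        model = build_geocache_model(
            GridGeometry(10, 10), 42, dirichlet_prior_scale=0.01
        )
        rng = np.random.default_rng(0)
        s = rng.dirichlet(np.ones(100))
        assert np.allclose(predicted_outcomes(model, s)["what"], [0.5, 0.5])


class TestExpectedFreeEnergy:
    def test_risk_of_staying_at_reward_is_kl_from_preference(self):
        # isolate the what modality: its risk is KL(o ‖ softmax(C[what]))
        from gridforage.generative_model import (
            GenerativeModel, InitialAndHabitPriors, LikelihoodModel,
            PreferenceModel, TransitionModel,
        )
        base = build_geocache_model(GridGeometry(10, 10), 42)
        model = GenerativeModel(
            geometry=base.geometry,
            likelihood=LikelihoodModel(A={"what": base.likelihood.A["what"]}),
            transitions=base.transitions,
            preferences=PreferenceModel(C={"what": base.preferences.C["what"]}),
            priors=base.priors,
        )
        s = np.zeros(100)
        s[42] = 1.0
        comp = expected_free_energy(model, s[None, :], ("stay",))
        # o = [1, 0]: KL([1,0] ‖ softmax([3,0])) = −ln 0.9526 ≈ 0.0486
        assert comp.risk[0] == pytest.approx(-np.log(1 / (1 + np.exp(-3.0))), abs=1e-6)
        assert comp.risk[0] == pytest.approx(0.0486, abs=1e-4)

    def test_identity_where_contributes_no_ambiguity(self):
        model = build_geocache_model(GridGeometry(3, 3), 4)
        s = np.zeros(9)
        s[2] = 1.0
        comp = expected_free_energy(model, s[None, :], ("stay",))
        assert comp.ambiguity[0] == pytest.approx(0.0, abs=1e-12)

    def test_novelty_equal_for_unvisited_and_vanishing_when_certain(self):
        model = build_geocache_model(
            GridGeometry(3, 3), 4, dirichlet_prior_scale=0.01
        )
        novs = []
        for j in [0, 1, 8]:
            s = np.zeros(9)
            s[j] = 1.0
            novs.append(expected_free_energy(model, s[None, :], ("stay",)).novelty[0])
        assert np.allclose(novs, novs[0])
        model.likelihood.a["what"] = np.full((2, 9), 1e6)
        s = np.zeros(9)
        s[0] = 1.0
        assert expected_free_energy(model, s[None, :], ("stay",)).novelty[0] < 1e-6

    def test_tree_scoring_matches_per_policy_scoring(self):
        model = build_geocache_model(
            GridGeometry(3, 3), 4, dirichlet_prior_scale=0.01, start_location=0
        )
        policies = enumerate_policies(ACTIONS, 2)
        s0 = np.zeros(9)
        s0[0] = 1.0
        comps, levels = score_policy_set(model, s0, policies, depth=2)
        assert len(levels) == 3
        for idx in [0, 7, 24]:
            Bbar = {u: model.transitions.mean(u) for u in ACTIONS}
            s = s0
            beliefs = []
            for u in policies[idx]:
                s = Bbar[u] @ s
                beliefs.append(s)
            single = expected_free_energy(model, np.array(beliefs), policies[idx])
            assert comps.G[idx] == pytest.approx(single.G[0], abs=1e-10)
            assert comps.novelty[idx] == pytest.approx(single.novelty[0], abs=1e-10)


class TestNoveltyTerm:
    def test_saturated_counts_give_no_novelty(self):
        a = np.full((2, 3), 1e6)
        assert novelty_term(a, [0.5, 0.5], [1, 0, 0]) < 1e-6

    def test_hand_evaluated_small_count_column(self):
        a = np.array([[0.01], [0.01]])
        assert novelty_term(a, [0.5, 0.5], [1.0]) == pytest.approx(25.0)

    def test_strictly_decreasing_in_observation_counts(self):
        a = np.array([[0.01], [0.01]])
        before = novelty_term(a, [0.5, 0.5], [1.0])
        a_after = a + np.array([[1.0], [0.0]])
        assert novelty_term(a_after, [0.5, 0.5], [1.0]) < before

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            novelty_term(np.array([[0.0], [1.0]]), [0.5, 0.5], [1.0])

    @given(st.integers(0, 200))
    def test_nonnegative_for_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.01, 5.0, size=(2, 4))
        o = rng.dirichlet(np.ones(2))
        s = rng.dirichlet(np.ones(4))
        assert novelty_term(a, o, s) >= 0


class TestPolicyPosterior:
    def test_uniform_when_everything_equal(self):
        E = np.full(4, 0.25)
        Q = policy_posterior(E, np.zeros(4), np.ones(4) * 3.0, gamma=1.0)
        assert np.allclose(Q, 0.25)

    def test_habit_limit(self):
        E = np.array([0.7, 0.2, 0.1])
        Q = policy_posterior(E, np.zeros(3), np.array([1.0, 5.0, 9.0]), gamma=1e-12)
        assert np.allclose(Q, E, atol=1e-9)

    def test_two_policy_softmax_arithmetic(self):
        Q = policy_posterior(
            np.array([0.5, 0.5]), np.zeros(2), np.array([0.0, 1.0]), gamma=1.0
        )
        e = np.e
        assert np.allclose(Q, [e / (1 + e), 1 / (1 + e)], atol=1e-12)
        assert Q[0] == pytest.approx(0.7311, abs=1e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            policy_posterior(np.ones(2) / 2, np.zeros(3), np.zeros(2), 1.0)

    @given(st.integers(0, 200))
    def test_normalised_and_shift_invariant(self, seed):
        rng = np.random.default_rng(seed)
        E = rng.dirichlet(np.ones(5))
        F = rng.normal(size=5)
        G = rng.normal(size=5)
        Q = policy_posterior(E, F, G, 1.3)
        assert np.isclose(Q.sum(), 1.0)
        Q_shift = policy_posterior(E, F + 4.2, G + rng.normal(), 1.3)
        assert np.allclose(Q, Q_shift, atol=1e-9)


class TestUpdatePrecision:
    def test_no_update_without_evidence(self):
        prec = PrecisionState(beta_prior=1.0, beta=1.0)
        E = np.full(3, 1 / 3)
        out = update_precision(prec, E, np.zeros(3), np.array([0.0, 1.0, 2.0]))
        assert out.beta == pytest.approx(1.0)
        assert np.allclose(out.gamma_trace, 1.0)

    def test_constant_G_is_gauge(self):
        prec = PrecisionState(beta_prior=1.0, beta=1.0)
        E = np.full(2, 0.5)
        out = update_precision(prec, E, np.array([0.0, 10.0]), np.full(2, 3.0))
        assert out.beta == pytest.approx(1.0)

    def test_fixed_point_matches_direct_iteration_oracle(self):
        E = np.full(2, 0.5)
        F = np.array([0.0, 10.0])
        G = np.array([0.0, 3.0])
        out = update_precision(
            PrecisionState(beta_prior=1.0, beta=1.0), E, F, G, n_iter=64
        )
        # independent fixed-point iteration
        beta = 1.0
        for _ in range(10_000):
            g = 1.0 / beta
            Q = np.exp(-F - g * G) * E
            Q /= Q.sum()
            Q0 = np.exp(-g * G) * E
            Q0 /= Q0.sum()
            beta = 1.0 + float((Q - Q0) @ G)
        assert out.beta == pytest.approx(beta, abs=1e-10)
        assert out.beta < 1.0  # confidence rises: γ > 1
        assert len(out.gamma_trace) == 64


class TestSelectAction:
    def test_single_policy_returns_its_action(self):
        assert select_action(np.array([1.0]), [("down", "up")], 0) == "down"
        assert select_action(np.array([1.0]), [("down", "up")], 1) == "up"

    def test_uniform_posterior_tie_breaks_to_up(self):
        policies = enumerate_policies(ACTIONS, 2)
        Q = np.full(len(policies), 1 / len(policies))
        marg = action_marginal(Q, policies, 0)
        assert np.allclose(marg, 0.2)
        assert select_action(Q, policies, 0) == "up"

    def test_marginalisation(self):
        policies = [("up", "stay"), ("down", "stay")]
        assert select_action(np.array([0.6, 0.4]), policies, 0) == "up"

    def test_empty_set_and_bad_index_raise(self):
        with pytest.raises(ValueError):
            select_action(np.array([]), [], 0)
        with pytest.raises(IndexError):
            select_action(np.array([1.0]), [("up",)], 3)

    def test_seeded_sampling_is_reproducible(self):
        policies = [("up", "stay"), ("down", "stay")]
        draws1 = [
            select_action(np.array([0.5, 0.5]), policies, 0,
                          rng=np.random.default_rng(7), sample=True)
            for _ in range(3)
        ]
        draws2 = [
            select_action(np.array([0.5, 0.5]), policies, 0,
                          rng=np.random.default_rng(7), sample=True)
            for _ in range(3)
        ]
        assert draws1 == draws2


def test_preference_gauge_invariance_end_to_end():
    """Shifting any C column by a constant changes no policy posterior."""
    geom = GridGeometry(3, 3)
    s0 = np.zeros(9)
    s0[0] = 1.0
    policies = enumerate_policies(ACTIONS, 2)
    Qs = []
    for shift in (0.0, 5.0):
        model = build_geocache_model(geom, 4, utilities=(3.0 + shift, 0.0 + shift))
        model.preferences.C["where"] = model.preferences.C["where"] - 2.0 * (shift > 0)
        comps, _ = score_policy_set(model, s0, policies, depth=2)
        Qs.append(policy_posterior(np.full(25, 1 / 25), np.zeros(25), comps.G, 1.0))
    assert np.allclose(Qs[0], Qs[1], atol=1e-10)
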