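import numpy as np
import pytest
from hypothesis import given, strategies as st

from gridforage import (
    BeliefState,
    BeliefTrace,
    GridGeometry,
    bayesian_model_average,
    belief_iteration,
    build_geocache_model,
    infer_states,
    policy_free_energy,
    state_prediction_error,
)
from gridforage._num import softmax
from gridforage.fixtures import exhaustive_smoother, make_fixture
from gridforage.generative_model import (
    GenerativeModel,
    InitialAndHabitPriors,
    LikelihoodModel,
    PreferenceModel,
    TransitionModel,
)


def _random_chain_model(seed, n=3, peaked=False):
    """Random 2–3 state model with two actions; fully stochastic tables."""
    rng = np.random.default_rng(seed)
    if peaked:
        from gridforage.fixtures import _peaked_permutation_table

        table = lambda: _peaked_permutation_table(n, rng)  # noqa: E731
    else:
        table = lambda: rng.dirichlet(np.ones(n), size=n).T  # noqa: E731
    return GenerativeModel(
        geometry=GridGeometry(1, n),
        likelihood=LikelihoodModel(A={"what": table()}),
        transitions=TransitionModel(B={"up": table(), "down": table()}),
        preferences=PreferenceModel(C={"what": np.zeros(n)}),
        priors=InitialAndHabitPriors(D=rng.dirichlet(np.ones(n))),
        policy_depth=1,
    ), rng


def _onehot(n, i):
    v = np.zeros(n)
    v[i] = 1.0
    return v


class TestPredictionError:
    def test_delta_fixed_point_with_identity_likelihood(self):
        model = build_geocache_model(GridGeometry(2, 2), 3)
        obs = [{"where": _onehot(4, 2), "what": _onehot(2, 1)}]
        beliefs, _ = infer_states(model, [()], obs, t_now=0, n_times=1)
        assert np.argmax(beliefs.s[0, 0]) == 2
        assert beliefs.s[0, 0, 2] > 1 - 1e-6

    def test_zero_error_at_uniform_symmetric_setup(self):
        # uniform B, uniform beliefs, no observation yet → ε is constant,
        # hence zero after mean-centring
        n = 3
        model, _ = _random_chain_model(0, n)
        model.transitions.B["up"] = np.full((n, n), 1 / n)
        beliefs = BeliefState.uniform(1, 3, n)
        err = state_prediction_error(
            model, ("up", "up"), beliefs, [{}, {}, {}], tau=1, t_now=-1
        )
        centred = err.epsilon - err.epsilon.mean()
        assert np.allclose(centred, 0.0, atol=1e-12)

    def test_tau_out_of_range_raises(self):
        model, _ = _random_chain_model(1)
        beliefs = BeliefState.uniform(1, 3, 3)
        with pytest.raises(IndexError):
            state_prediction_error(model, ("up", "up"), beliefs, [{}], 5, 0)


class TestBeliefIteration:
    def test_zero_error_is_stationary(self):
        beliefs = BeliefState.uniform(1, 2, 3)
        before = beliefs.s.copy()
        belief_iteration(beliefs, np.zeros(3), policy_index=0, tau=0)
        assert np.allclose(beliefs.s, before)

    def test_constant_error_is_gauge_invariant(self):
        beliefs = BeliefState.uniform(1, 2, 4)
        before = beliefs.s.copy()
        belief_iteration(beliefs, np.full(4, 7.3), policy_index=0, tau=1)
        assert np.allclose(beliefs.s, before)

    def test_step_size_validated(self):
        beliefs = BeliefState.uniform(1, 1, 2)
        with pytest.raises(ValueError):
            belief_iteration(beliefs, np.zeros(2), step_size=0.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_fixed_point_matches_exact_smoother(self, seed):
        fx = make_fixture(["tiny_hmm", "two_state_bandit", "mini_grid"][seed % 3], seed)
        beliefs, _ = infer_states(
            fx["model"], [fx["policy"]], fx["observations"], t_now=len(fx["policy"])
        )
        assert np.max(np.abs(beliefs.s[0] - fx["exact_marginals"])) < 1e-3

    @pytest.mark.parametrize("seed", range(10))
    def test_free_energy_tightly_bounds_log_evidence(self, seed):
        fx = make_fixture("tiny_hmm", seed)
        beliefs, _ = infer_states(
            fx["model"], [fx["policy"]], fx["observations"], t_now=len(fx["policy"])
        )
        F = policy_free_energy(
            fx["model"], fx["policy"], beliefs, fx["observations"], len(fx["policy"])
        )
        neg_log_ev = -np.log(fx["exact_evidence"])
        assert F >= neg_log_ev - 1e-9
        assert F - neg_log_ev < 1e-3

    def test_free_energy_descends_on_random_models(self):
        # 100 random fully stochastic models: damped coordinate descent may
        # never increase F (tolerance 1e-8 per step)
        for seed in range(100):
            model, rng = _random_chain_model(seed, n=2 + seed % 2)
            T = 3
            policy = tuple(("up", "down")[int(x)] for x in rng.integers(0, 2, T))
            obs = [
                {"what": _onehot(model.n_states, int(rng.integers(model.n_states)))}
                for _ in range(T + 1)
            ]
            beliefs = None
            trace = BeliefTrace()
            F_prev = None
            for k in range(16):
                beliefs, trace = infer_states(
                    model, [policy], obs, t_now=T, n_iter=1,
                    beliefs=beliefs, trace=trace, iteration_offset=k,
                )
                F = policy_free_energy(model, policy, beliefs, obs, T)
                if F_prev is not None:
                    assert F <= F_prev + 1e-8
                F_prev = F


class TestInferStates:
    def test_trace_length_is_iterations_times_time_points(self):
        model = build_geocache_model(GridGeometry(3, 3), 4, start_location=0)
        T = 4
        policy = ("right", "right", "down", "down")
        loc = 0
        obs = []
        for tau in range(T + 1):
            obs.append({"where": _onehot(9, loc), "what": _onehot(2, 0 if loc == 4 else 1)})
            if tau < T:
                loc = model.geometry.move(loc, policy[tau])
        beliefs, trace = None, BeliefTrace()
        for t_now in range(T + 1):
            beliefs, trace = infer_states(
                model, [policy], obs[: t_now + 1] + [{}] * (T - t_now), t_now,
                beliefs=beliefs, trace=trace,
                iteration_offset=t_now * model.iterations_per_step,
            )
        assert len(trace) == model.iterations_per_step * (T + 1)
        assert trace.iterations == sorted(trace.iterations)
        frame = trace.to_frame()
        assert set(frame.columns) == {"iteration", "policy", "tau", "state", "s", "v"}

    def test_single_state_model_beliefs_are_one(self):
        model = build_geocache_model(GridGeometry(1, 1), 0)
        obs = [{"where": np.ones(1), "what": _onehot(2, 0)}] * 3
        beliefs, trace = infer_states(model, [("stay", "stay")], obs, t_now=2)
        assert np.allclose(beliefs.s, 1.0)
        assert all(np.allclose(s, 1.0) for s in trace.s)

    def test_normalisation_at_every_iteration(self):
        fx = make_fixture("tiny_hmm", 3)
        _, trace = infer_states(
            fx["model"], [fx["policy"]], fx["observations"], t_now=4
        )
        for s in trace.s:
            assert np.allclose(s.sum(axis=-1), 1.0, atol=1e-10)

    @given(st.integers(0, 500))
    def test_gauge_invariance_of_depolarisation(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=5)
        assert np.allclose(softmax(v), softmax(v + rng.normal()))


class TestBayesianModelAverage:
    def test_single_policy_passthrough(self):
        beliefs = BeliefState.uniform(1, 3, 4)
        assert np.allclose(bayesian_model_average(beliefs, [1.0]), beliefs.s[0])

    def test_identical_beliefs_independent_of_weights(self):
        beliefs = BeliefState.uniform(2, 2, 3)
        out = bayesian_model_average(beliefs, [0.9, 0.1])
        assert np.allclose(out, beliefs.s[0])

    def test_delta_mixture(self):
        beliefs = BeliefState.uniform(2, 1, 2)
        beliefs.s[0, 0] = [1.0, 0.0]
        beliefs.s[1, 0] = [0.0, 1.0]
        out = bayesian_model_average(beliefs, [0.7, 0.3])
        assert np.allclose(out[0], [0.7, 0.3])

    def test_unnormalised_posterior_rejected(self):
        beliefs = BeliefState.uniform(2, 1, 2)
        with pytest.raises(ValueError):
            bayesian_model_average(beliefs, [0.7, 0.7])
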