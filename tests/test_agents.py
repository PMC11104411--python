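"""Cost-sensitive actor-critic: policy, updates, simulation, likelihood."""

import numpy as np
import pytest

from policycomp import synthetic_data as sd
from policycomp.agents import (
    AgentParams,
    action_probs,
    adaptive_beta_step,
    init_block_state,
    simulate,
    step,
    trial_loglik,
)
from policycomp.rate_distortion import (
    deterministic_value_table,
    optimal_reward_at,
    policy_stats,
    tradeoff_curve,
)
from conftest import make_long_task

LOG3 = np.log(3.0)


def _fixed(beta=3.0, ath=0.1, aV=0.2, aP=0.0, model="fixed"):
    return AgentParams(
        model=model, beta=beta, alpha_theta=ath, alpha_V=aV, alpha_P=aP
    )


def _final_policy(params, data):
    """Replay a subject's last block; returns the terminal policy matrix and
    the correct action per state row (inferred from rewarded trials)."""
    state, action, reward, block_ptr, n_states = data.to_arrays()
    P_a = None
    st = None
    lo = 0
    for b in range(len(n_states)):
        st = init_block_state(int(n_states[b]), 3, params, P_a=P_a)
        lo = block_ptr[b]
        for i in range(block_ptr[b], block_ptr[b + 1]):
            pi = action_probs(int(state[i]), st)
            step(int(state[i]), int(action[i]), float(reward[i]), params, st, pi=pi)
            if params.model in ("adaptive", "reduced_adaptive"):
                adaptive_beta_step(int(state[i]), int(action[i]), params, st, pi=pi)
        P_a = st.P_a
    n = st.theta.shape[0]
    correct = np.full(n, -1)
    for i in range(lo, len(state)):
        if reward[i] == 1:
            correct[state[i]] = action[i]
    pi_mat = np.vstack([action_probs(s, st) for s in range(n)])
    return pi_mat, correct


class TestActionProbs:
    def test_zero_theta_returns_marginal(self):
        st = init_block_state(2, 3, _fixed())
        st.P_a = np.array([0.5, 0.3, 0.2])
        assert np.allclose(action_probs(0, st), st.P_a)

    def test_zero_beta_ignores_theta(self):
        st = init_block_state(2, 3, _fixed(beta=0.0))
        st.theta[0] = [5.0, -1.0, 2.0]
        assert np.allclose(action_probs(0, st), 1 / 3)

    def test_softmax_closed_form(self):
        st = init_block_state(1, 3, _fixed(beta=2.0))
        st.theta[0] = [1.0, 0.0, 0.0]
        pi = action_probs(0, st)
        e2 = np.exp(2.0)
        expected = np.array([e2, 1.0, 1.0]) / (e2 + 2.0)
        assert pi == pytest.approx(expected, abs=1e-5)
        assert pi[0] == pytest.approx(0.78699, abs=1e-5)


class TestStep:
    def test_delta_at_chance(self):
        """beta=1, r=1, pi(a|s)=P(a): realized cost is zero, delta = 1."""
        st = init_block_state(1, 3, _fixed(beta=1.0))
        res = step(0, 0, 1.0, _fixed(beta=1.0), st)
        assert res.delta == pytest.approx(1.0, abs=1e-12)
        assert res.cost == pytest.approx(0.0, abs=1e-12)

    def test_zero_alpha_p_freezes_marginal(self):
        params = _fixed(aP=0.0)
        st = init_block_state(2, 3, params)
        before = st.P_a.copy()
        for _ in range(5):
            step(0, 1, 1.0, params, st)
        assert np.array_equal(st.P_a, before)

    def test_update_arithmetic(self):
        """Direct evaluation of the prediction error and actor update."""
        params = _fixed(beta=2.0, ath=0.1)
        st = init_block_state(1, 2, params)
        st.P_a = np.array([0.25, 0.75])
        st.theta[0] = [np.log(2.0) / 2.0, 0.0]  # so pi = [0.5, 0.5]... see below
        # construct state so that pi(a=0|s) = 0.5 with P(a=0) = 0.25:
        # logits = beta*theta + log P => need beta*theta0 - beta*theta1 =
        # log(0.5/0.5) - log(0.25/0.75) = log 3
        st.theta[0] = [np.log(3.0) / 2.0, 0.0]
        st.V_hat[0] = 0.1
        st.t = 4
        pi = action_probs(0, st)
        assert pi[0] == pytest.approx(0.5, abs=1e-12)
        theta_before = st.theta[0, 0]
        res = step(0, 0, 0.0, params, st, pi=pi)
        assert res.delta == pytest.approx(-np.log(2.0) - 0.1, abs=1e-12)
        d_theta = st.theta[0, 0] - theta_before
        assert d_theta == pytest.approx(0.025 * res.delta * 0.5 * 2.0, abs=1e-12)
        assert d_theta == pytest.approx(-0.0198288, abs=1e-6)

    def test_marginal_update_moves_toward_policy(self):
        params = _fixed(beta=2.0, aP=0.2)
        st = init_block_state(1, 3, params)
        st.theta[0] = [1.0, 0.0, 0.0]
        pi = action_probs(0, st)
        step(0, 0, 1.0, params, st, pi=pi)
        assert st.P_a[0] > 1 / 3
        assert st.P_a.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonbinary_reward_warns(self):
        st = init_block_state(1, 3, _fixed())
        with pytest.warns(UserWarning, match="reward"):
            step(0, 0, 0.5, _fixed(), st)


class TestAdaptiveBetaStep:
    def _adaptive(self, C=1.0, ab=0.1):
        return AgentParams(
            model="adaptive", C=C, beta0=1.0, alpha_beta=ab,
            alpha_theta=0.1, alpha_V=0.1, alpha_P=0.0,
        )

    def test_zero_when_complexity_on_target(self):
        params = self._adaptive(C=0.5)
        st = init_block_state(1, 3, params)
        st.theta[0] = [1.0, 0.0, 0.0]
        st.R = 0.5
        before = st.beta_t
        adaptive_beta_step(0, 0, params, st)
        assert st.beta_t == before

    def test_zero_when_theta_row_constant(self):
        params = self._adaptive(C=1.0)
        st = init_block_state(1, 3, params)
        st.theta[0] = [0.7, 0.7, 0.7]
        st.R = 0.2
        before = st.beta_t
        adaptive_beta_step(0, 0, params, st)
        assert st.beta_t == pytest.approx(before, abs=1e-15)

    def test_update_arithmetic(self):
        params = self._adaptive(C=1.0, ab=0.1)
        st = init_block_state(1, 3, params)
        st.theta[0] = [1.0, 0.0, 0.0]
        st.R = 0.5
        pi = np.array([0.5, 0.25, 0.25])
        before = st.beta_t
        adaptive_beta_step(0, 0, params, st, pi=pi)
        assert st.beta_t - before == pytest.approx(0.1 * 0.5 * 0.5, abs=1e-12)

    def test_rejected_for_fixed_model(self):
        st = init_block_state(1, 3, _fixed())
        with pytest.raises(ValueError, match="adaptive"):
            adaptive_beta_step(0, 0, _fixed(), st)


class TestSimulate:
    def test_frozen_uniform_agent_at_chance(self):
        params = _fixed(beta=0.0, ath=0.0, aV=0.0, aP=0.0)
        data = simulate(params, make_long_task(3, 400), seed=0)
        assert data.trials["reward"].mean() == pytest.approx(1 / 3, abs=0.05)

    def test_learner_masters_small_set_size(self):
        """High beta, moderate actor rate: terminal accuracy > 0.9 on set
        size 2 across seeds."""
        params = _fixed(beta=8.0, ath=0.2, aV=0.3)
        task = sd.generate_task(sd.TaskConfig(set_sizes=(2,)), seed=3)
        acc = []
        for seed in range(10):
            data = simulate(params, task, seed=seed)
            last = data.trials.tail(8)["reward"].mean()
            acc.append(last)
        assert np.mean(acc) > 0.9

    def test_seeded_determinism(self, one_subject):
        params, data = one_subject
        task = sd.generate_task(seed=1)
        again = simulate(params, task, seed=2)
        assert data.trials.equals(again.trials)

    def test_beta_ordering_of_complexity(self):
        """Final-policy complexity is non-decreasing in beta."""
        task = make_long_task(2, 1000)
        comps = []
        for beta in (0.5, 2.0, 4.0, 8.0):
            data = simulate(_fixed(beta=beta, ath=0.1), task, seed=11)
            pi, correct = _final_policy(_fixed(beta=beta, ath=0.1), data)
            vt = deterministic_value_table(2, 3, correct)
            comps.append(policy_stats(pi, vt)[0])
        assert all(b >= a - 1e-9 for a, b in zip(comps, comps[1:]))

    def test_no_cost_at_least_as_complex_as_fixed(self):
        """Removing the complexity penalty cannot reduce policy complexity."""
        task = make_long_task(2, 1000)
        comps = {}
        for model in ("fixed", "no_cost"):
            params = _fixed(beta=3.0, ath=0.1, model=model)
            data = simulate(params, task, seed=4)
            pi, correct = _final_policy(params, data)
            vt = deterministic_value_table(2, 3, correct)
            comps[model] = policy_stats(pi, vt)[0]
        assert comps["no_cost"] >= comps["fixed"] - 1e-6

    def test_long_horizon_near_optimal_frontier(self):
        """With the 1/t schedule and a long horizon the converged policy
        approaches the optimal reward-complexity curve."""
        task = make_long_task(2, 5000)
        params = _fixed(beta=8.0, ath=0.3, aV=0.3)
        data = simulate(params, task, seed=6)
        pi, correct = _final_policy(params, data)
        vt = deterministic_value_table(2, 3, correct)
        complexity, reward = policy_stats(pi, vt)
        curve = tradeoff_curve(vt)
        assert reward >= optimal_reward_at(curve, complexity) - 0.05
        # frontier dominance: the point never lies above the curve
        assert reward <= optimal_reward_at(curve, complexity) + 1e-6


class TestTrialLoglik:
    def test_uniform_model_exact(self, one_subject):
        _, data = one_subject
        T = len(data.trials)
        params = _fixed(beta=0.0, aP=0.0)
        assert trial_loglik(params, data) == pytest.approx(-T * LOG3, abs=1e-9)

    def test_single_trial(self):
        import pandas as pd

        row = pd.DataFrame(
            [{"subject_id": "s", "group": "g", "block": 0, "set_size": 2,
              "trial_in_block": 0, "stimulus_id": 0, "action": 1, "reward": 0}]
        )
        data = sd.SubjectData("s", "g", row)
        params = _fixed(beta=4.0)
        st = init_block_state(1, 3, params)
        expected = np.log(action_probs(0, st)[1])
        assert trial_loglik(params, data) == pytest.approx(expected, abs=1e-12)

    def test_generating_parameters_beat_perturbed_beta(self):
        """Average log-likelihood is highest near the generating beta."""
        gains_lo, gains_hi = [], []
        for seed in range(20):
            params = _fixed(beta=4.0, ath=0.15, aV=0.3)
            task = sd.generate_task(seed=seed)
            data = simulate(params, task, seed=100 + seed)
            ll = trial_loglik(params, data)
            lo = trial_loglik(_fixed(beta=2.0, ath=0.15, aV=0.3), data)
            hi = trial_loglik(_fixed(beta=6.0, ath=0.15, aV=0.3), data)
            gains_lo.append(ll - lo)
            gains_hi.append(ll - hi)
        assert np.mean(gains_lo) > 0
        assert np.mean(gains_hi) > 0

    @pytest.mark.parametrize("model", ["fixed", "no_cost", "adaptive", "reduced_adaptive"])
    def test_compiled_kernel_matches_python_reference(self, model, one_subject):
        _, data = one_subject
        if model in ("fixed", "no_cost"):
            params = AgentParams(model=model, beta=3.7, alpha_theta=0.23,
                                 alpha_V=0.41, alpha_P=0.031)
        else:
            params = AgentParams(model=model, C=0.4, beta0=4.2, alpha_beta=0.6,
                                 alpha_theta=0.18, alpha_V=0.35, alpha_P=0.02)
        a = trial_loglik(params, data, engine="python")
        b = trial_loglik(params, data, engine="compiled")
        assert b == pytest.approx(a, abs=1e-8)

    def test_unknown_engine_rejected(self, one_subject):
        _, data = one_subject
        with pytest.raises(ValueError, match="engine"):
            trial_loglik(_fixed(), data, engine="matlab")


class TestAgentParams:
    def test_vector_round_trip(self):
        p = AgentParams(model="adaptive", C=0.5, beta0=3.0, alpha_beta=0.2,
                        alpha_theta=0.1, alpha_V=0.4, alpha_P=0.01)
        q = AgentParams.from_vector("adaptive", p.to_vector())
        assert q.free_values() == p.free_values()

    def test_validation(self):
        with pytest.raises(ValueError, match="beta"):
            AgentParams(model="fixed")
        with pytest.raises(ValueError, match="C"):
            AgentParams(model="adaptive", beta0=1.0, alpha_beta=0.1)
        with pytest.raises(ValueError, match="alpha_theta"):
            AgentParams(model="fixed", beta=1.0, alpha_theta=1.5)
        reduced = AgentParams(model="reduced_adaptive", C=0.3, beta0=1.0,
                              alpha_beta=0.1, alpha_P=0.7)
        assert reduced.alpha_P == 0.0
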