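"""Cost-sensitive actor-critic process models.

The agent's policy is a softmax over actor weights with a perseveration term,

    pi(a|s) ∝ exp[ beta * theta_sa + log P(a) ],

mirroring the form of the optimal capacity-limited policy.  After observing
reward ``r`` for action ``a`` in state ``s``, the cost-sensitive prediction
error

    delta = beta*r - log[pi(a|s)/P(a)] - V_hat(s)

drives the updates

    theta_sa  += (alpha_theta / t) * delta * (1 - pi(a|s)) * beta
    V_hat(s)  += alpha_V * delta
    P(a')     += alpha_P * (pi(a'|s) - P(a'))     for every action a'

with ``t`` the within-block trial index (the 1/t decay makes the actor
slower than the critic and yields convergence to the optimal policy).

Model variants
--------------
``fixed``             beta is a free constant.
``adaptive``          beta is learned online to hold the running policy
                      complexity R (the last realized cost
                      log[pi(a|s)/P(a)]) at a capacity C:
                      delta_beta = alpha_beta*(C - R)*[theta_sa -
                      sum_a' theta_sa' pi(a'|s)].
``reduced_adaptive``  adaptive with alpha_P fixed at 0.
``no_cost``           ablation: delta = beta*r - V_hat(s), no complexity
                      penalty in the prediction error.

The same recursion serves as simulator (actions sampled from pi) and as a
prequential trial-wise likelihood (pi evaluated at observed choices).  A
numba-compiled kernel mirrors the Python recursion for fitting speed; the
Python path is the reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import BlockScheduler, SubjectData, TaskDesign

__all__ = [
    "MODELS",
    "MODEL_CODES",
    "FREE_PARAMS",
    "AgentParams",
    "AgentState",
    "StepResult",
    "init_block_state",
    "action_probs",
    "step",
    "adaptive_beta_step",
    "simulate",
    "trial_loglik",
]

MODELS = ("fixed", "adaptive", "reduced_adaptive", "no_cost")
MODEL_CODES = {"fixed": 0, "adaptive": 1, "reduced_adaptive": 2, "no_cost": 3}

#: free parameters per model, in fitting-vector order
FREE_PARAMS = {
    "fixed": ("beta", "alpha_theta", "alpha_V", "alpha_P"),
    "no_cost": ("beta", "alpha_theta", "alpha_V", "alpha_P"),
    "adaptive": ("C", "beta0", "alpha_beta", "alpha_theta", "alpha_V", "alpha_P"),
    "reduced_adaptive": ("C", "beta0", "alpha_beta", "alpha_theta", "alpha_V"),
}

_P_FLOOR = 1e-8  # marginal probabilities stay off zero so log P(a) is finite
_PI_FLOOR = 1e-300
#: numerical guard: the adaptive beta update has a positive feedback loop
#: (theta steps scale with beta^2), so beta_t is clipped well above any
#: behaviorally plausible value instead of being allowed to overflow
_BETA_MAX = 50.0


@dataclass
class AgentParams:
    """Parameters of one model variant.

    ``beta`` applies to fixed/no_cost; (``C``, ``beta0``, ``alpha_beta``) to
    the adaptive variants.  Learning rates lie in [0, 1].  With
    ``scale_lr_by_set_size`` the actor rate becomes alpha_theta/(N*t) where
    N is the block's set size.
    """

    model: str = "fixed"
    beta: float | None = None
    C: float | None = None
    beta0: float | None = None
    alpha_beta: float | None = None
    alpha_theta: float = 0.1
    alpha_V: float = 0.1
    alpha_P: float = 0.0
    scale_lr_by_set_size: bool = False

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.model in ("fixed", "no_cost"):
            if self.beta is None:
                raise ValueError(f"{self.model} model requires beta")
            if self.beta < 0:
                raise ValueError("beta must be non-negative")
        else:
            for name in ("C", "beta0", "alpha_beta"):
                if getattr(self, name) is None:
                    raise ValueError(f"{self.model} model requires {name}")
            if self.C < 0 or self.beta0 < 0:
                raise ValueError("C and beta0 must be non-negative")
            if self.model == "reduced_adaptive":
                self.alpha_P = 0.0
        for name in ("alpha_theta", "alpha_V", "alpha_P"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def free_values(self) -> dict:
        return {name: getattr(self, name) for name in FREE_PARAMS[self.model]}

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FREE_PARAMS[self.model]], dtype=float)

    @classmethod
    def from_vector(cls, model: str, x) -> "AgentParams":
        return cls(model=model, **dict(zip(FREE_PARAMS[model], map(float, x))))

    @property
    def initial_beta(self) -> float:
        return self.beta if self.model in ("fixed", "no_cost") else self.beta0


@dataclass
class AgentState:
    """Mutable learner state.

    theta and V_hat are per-block (fresh stimuli); P_a persists across
    blocks within a subject.  For the adaptive variants beta_t restarts at
    beta0 with each block, re-adapting to that block's set size.  ``t`` is
    the within-block trial index (1-based); ``R`` is the running
    policy-complexity estimate (last realized cost), reset to 0 at block
    start.
    """

    theta: np.ndarray
    V_hat: np.ndarray
    P_a: np.ndarray
    beta_t: float
    t: int = 1
    R: float = 0.0


@dataclass(frozen=True)
class StepResult:
    delta: float
    pi: np.ndarray
    cost: float


def init_block_state(
    n_states: int,
    n_actions: int,
    params: AgentParams,
    P_a: np.ndarray | None = None,
    beta: float | None = None,
) -> AgentState:
    """Block-start state: theta and V_hat zeroed, P_a carried over (uniform
    for the first block); beta_t starts at the model's initial beta unless
    given explicitly."""
    if P_a is None:
        P_a = np.full(n_actions, 1.0 / n_actions)
    if beta is None:
        beta = params.initial_beta
    return AgentState(
        theta=np.zeros((n_states, n_actions)),
        V_hat=np.zeros(n_states),
        P_a=np.asarray(P_a, dtype=float).copy(),
        beta_t=float(beta),
    )


def action_probs(state: int, st: AgentState) -> np.ndarray:
    """pi(a|state) ∝ exp[beta_t * theta_sa + log P(a)], normalized."""
    logits = st.beta_t * st.theta[state] + np.log(st.P_a)
    logits = logits - logits.max()
    pi = np.exp(logits)
    return pi / pi.sum()


def step(
    state: int,
    action: int,
    reward: float,
    params: AgentParams,
    st: AgentState,
    pi: np.ndarray | None = None,
) -> StepResult:
    """Apply one trial's updates in place; returns the prediction error,
    the pre-update policy row and the realized complexity cost."""
    if reward not in (0, 1):
        import warnings

        warnings.warn(f"reward {reward} outside {{0,1}}; accepted as-is")
    if pi is None:
        pi = action_probs(state, st)
    pa = max(float(pi[action]), _PI_FLOOR)
    cost = np.log(pa) - np.log(st.P_a[action])
    if params.model == "no_cost":
        delta = st.beta_t * reward - st.V_hat[state]
    else:
        delta = st.beta_t * reward - cost - st.V_hat[state]
    n_states = st.theta.shape[0]
    lr = params.alpha_theta / st.t
    if params.scale_lr_by_set_size:
        lr /= n_states
    st.theta[state, action] += lr * delta * (1.0 - pi[action]) * st.beta_t
    st.V_hat[state] += params.alpha_V * delta
    if params.alpha_P > 0:
        st.P_a += params.alpha_P * (pi - st.P_a)
        np.clip(st.P_a, _P_FLOOR, None, out=st.P_a)
        st.P_a /= st.P_a.sum()
    st.R = cost
    st.t += 1
    return StepResult(delta=float(delta), pi=pi, cost=float(cost))


def adaptive_beta_step(
    state: int,
    action: int,
    params: AgentParams,
    st: AgentState,
    pi: np.ndarray | None = None,
) -> float:
    """Gradient step moving beta so the running complexity R tracks C.

    Called after :func:`step`, with the same trial's pre-update policy row;
    beta is floored at 0 and capped at a large numerical guard.  Only valid
    for the adaptive variants.
    """
    if params.model not in ("adaptive", "reduced_adaptive"):
        raise ValueError(f"adaptive beta update invalid for model {params.model!r}")
    if pi is None:
        pi = action_probs(state, st)
    bracket = st.theta[state, action] - float(st.theta[state] @ pi)
    new_beta = st.beta_t + params.alpha_beta * (params.C - st.R) * bracket
    st.beta_t = min(max(0.0, new_beta), _BETA_MAX)
    return st.beta_t


def _is_adaptive(params: AgentParams) -> bool:
    return params.model in ("adaptive", "reduced_adaptive")


def simulate(
    params: AgentParams,
    task: TaskDesign,
    seed: int = 0,
    subject_id: str = "sim",
    group: str = "sim",
) -> SubjectData:
    """Run the agent through a task design, sampling actions from its policy.

    The block scheduler evaluates the performance criterion online, so block
    length depends on the agent's accuracy (as in the real design).
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    cfg = task.config
    rows = []
    P_a = None
    for b, block in enumerate(task.blocks):
        n = block.set_size
        st = init_block_state(n, cfg.n_actions, params, P_a=P_a)
        sched = BlockScheduler(n, cfg, rng)
        t_in_block = 0
        while True:
            s = sched.next_stimulus()
            if s is None:
                break
            pi = action_probs(s, st)
            a = int(rng.choice(cfg.n_actions, p=pi))
            r = 1.0 if a == int(block.correct_actions[s]) else 0.0
            step(s, a, r, params, st, pi=pi)
            if _is_adaptive(params):
                adaptive_beta_step(s, a, params, st, pi=pi)
            sched.record(s, r == 1.0)
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "block": b,
                    "set_size": n,
                    "trial_in_block": t_in_block,
                    "stimulus_id": int(block.stimulus_ids[s]),
                    "action": a,
                    "reward": int(r),
                }
            )
            t_in_block += 1
        P_a = st.P_a
    return SubjectData(subject_id=subject_id, group=group, trials=pd.DataFrame(rows))


def _loglik_python(params: AgentParams, data: SubjectData) -> float:
    state, action, reward, block_ptr, n_states = data.to_arrays()
    n_actions = 3
    total = 0.0
    P_a = None
    for b in range(len(n_states)):
        st = init_block_state(int(n_states[b]), n_actions, params, P_a=P_a)
        for i in range(block_ptr[b], block_ptr[b + 1]):
            s, a, r = int(state[i]), int(action[i]), float(reward[i])
            pi = action_probs(s, st)
            total += np.log(max(float(pi[a]), _PI_FLOOR))
            step(s, a, r, params, st, pi=pi)
            if _is_adaptive(params):
                adaptive_beta_step(s, a, params, st, pi=pi)
        P_a = st.P_a
    return float(total)


def trial_loglik(params: AgentParams, data: SubjectData, engine: str = "compiled") -> float:
    """Total prequential log-likelihood (nats) of a subject's choices.

    Internal state is updated on the observed (s, a, r) sequence; the
    likelihood of each trial is pi(a_t|s_t) under the state just before it.
    ``engine='compiled'`` uses the numba kernel, ``engine='python'`` the
    step-based reference path; the two agree to floating-point noise.
    """
    if engine == "python":
        ll = _loglik_python(params, data)
    elif engine == "compiled":
        from ._kernels import loglik_kernel

        state, action, reward, block_ptr, n_states = data.to_arrays()
        ll = float(
            loglik_kernel(
                MODEL_CODES[params.model],
                params.to_vector(),
                state,
                action,
                reward,
                block_ptr,
                n_states,
                3,
                params.scale_lr_by_set_size,
            )
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")
    if not np.isfinite(ll):
        raise FloatingPointError(
            f"non-finite log-likelihood for model {params.model}: parameter pathology"
        )
    return ll
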