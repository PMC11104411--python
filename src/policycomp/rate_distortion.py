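"""Optimal action policies under an information-rate constraint.

An agent visits discrete states ``s`` with prior ``P(s)`` and chooses among
discrete actions ``a`` with policy ``pi(a|s)``, earning expected reward
``Q(s, a)``.  The *policy complexity* is the mutual information

    I(S; A) = sum_s P(s) sum_a pi(a|s) log[ pi(a|s) / P(a) ]    (nats)

which measures how state-dependent the policy is: a policy that ignores the
state has complexity 0, a deterministic lookup table has the maximal
complexity permitted by the state and action entropies.  Maximizing average
reward ``V = sum_s P(s) sum_a pi(a|s) Q(s, a)`` subject to ``I(S;A) <= C``
yields, via the Lagrangian ``beta*V - I``, the self-consistent softmax
solution

    pi*(a|s) ∝ exp[ beta*Q(s, a) + log P*(a) ],
    P*(a)    = sum_s P(s) pi*(a|s),

which is found by alternating the two updates (a Blahut-Arimoto iteration).
Sweeping the inverse temperature ``beta`` traces the optimal
reward-complexity frontier; ``1/beta`` is the slope ``dV/dI`` of that curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import rel_entr

__all__ = [
    "ValueTable",
    "PolicyMatrix",
    "TradeoffCurve",
    "ConvergenceError",
    "deterministic_value_table",
    "default_beta_grid",
    "policy_stats",
    "blahut_arimoto",
    "tradeoff_curve",
    "beta_for_capacity",
    "optimal_reward_at",
]

#: probabilities are floored at this value inside logarithms only
_LOG_FLOOR = 1e-16


class ConvergenceError(RuntimeError):
    """Blahut-Arimoto failed to reach the requested tolerance."""


@dataclass(frozen=True)
class ValueTable:
    """Expected reward table ``Q(s, a)`` plus the state prior ``P(s)``."""

    Q: np.ndarray
    P_s: np.ndarray

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        P_s = np.asarray(self.P_s, dtype=float)
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "P_s", P_s)
        if Q.ndim != 2:
            raise ValueError("Q must be a (state, action) matrix")
        if P_s.shape != (Q.shape[0],):
            raise ValueError("P_s length must match the number of states")
        if not np.all(np.isfinite(Q)):
            raise ValueError("Q must be finite")
        if np.any(P_s < 0):
            raise ValueError("P_s entries must be non-negative")
        if abs(P_s.sum() - 1.0) > 1e-12:
            raise ValueError("P_s must sum to 1 (within 1e-12)")

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]

    @property
    def n_actions(self) -> int:
        return self.Q.shape[1]


@dataclass(frozen=True)
class PolicyMatrix:
    """A row-stochastic policy with its marginal, complexity and reward."""

    pi: np.ndarray
    marginal: np.ndarray
    complexity: float
    reward: float


@dataclass
class TradeoffCurve:
    """Optimal reward-complexity frontier traced over a beta grid.

    ``complexities`` (nats) and ``rewards`` are non-decreasing in ``beta``,
    and the piecewise-linear (complexity, reward) graph is concave.
    """

    betas: np.ndarray
    complexities: np.ndarray
    rewards: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.complexities = np.asarray(self.complexities, dtype=float)
        self.rewards = np.asarray(self.rewards, dtype=float)

    def validate(self, mono_tol: float = 1e-9, concave_tol: float = 1e-6) -> None:
        """Raise if monotonicity or concavity is violated beyond tolerance."""
        if np.any(np.diff(self.betas) < 0):
            raise ValueError("betas must be ascending")
        if np.any(np.diff(self.complexities) < -mono_tol):
            raise ValueError("complexities must be non-decreasing in beta")
        if np.any(np.diff(self.rewards) < -mono_tol):
            raise ValueError("rewards must be non-decreasing along the curve")
        # concavity: every interior point lies on or above the chord of its
        # neighbours (to within concave_tol in reward units)
        I, V = self.complexities, self.rewards
        span = I[2:] - I[:-2]
        ok = span > 1e-12
        w = np.where(ok, (I[1:-1] - I[:-2]) / np.where(ok, span, 1.0), 0.0)
        chord = V[:-2] + w * (V[2:] - V[:-2])
        if np.any(ok & (V[1:-1] < chord - concave_tol)):
            raise ValueError("curve is not concave within tolerance")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.betas,
                "complexity_nats": self.complexities,
                "reward": self.rewards,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TradeoffCurve":
        df = pd.read_csv(path)
        return cls(
            df["beta"].to_numpy(),
            df["complexity_nats"].to_numpy(),
            df["reward"].to_numpy(),
        )


def deterministic_value_table(
    n_states: int,
    n_actions: int = 3,
    correct_actions: np.ndarray | None = None,
) -> ValueTable:
    """One-hot reward table with a single rewarded action per state.

    This is the value structure of the set-size task: each stimulus (state)
    has exactly one correct action, rewarded deterministically.  The state
    prior is uniform.
    """
    if correct_actions is None:
        correct_actions = np.arange(n_states) % n_actions
    correct_actions = np.asarray(correct_actions, dtype=int)
    Q = np.zeros((n_states, n_actions))
    Q[np.arange(n_states), correct_actions] = 1.0
    return ValueTable(Q, np.full(n_states, 1.0 / n_states))


def default_beta_grid(
    n: int = 200, lo: float = 1e-3, hi: float = 50.0
) -> np.ndarray:
    """beta = 0 plus ``n`` geometrically spaced points in [lo, hi].

    The geometric spacing resolves the low-complexity knee of the frontier
    where empirical subjects concentrate.
    """
    return np.concatenate([[0.0], np.geomspace(lo, hi, n)])


def _check_policy(pi: np.ndarray, vt: ValueTable) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != vt.Q.shape:
        raise ValueError(
            f"policy shape {pi.shape} does not match value table {vt.Q.shape}"
        )
    if np.any(pi < 0):
        raise ValueError("policy contains negative probabilities")
    if np.any(np.abs(pi.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("policy rows must sum to 1")
    return pi


def policy_stats(pi: np.ndarray, vt: ValueTable) -> tuple[float, float]:
    """Policy complexity I(S;A) in nats and average reward of ``pi``.

    The action marginal is ``P(a) = sum_s P(s) pi(a|s)``; terms with
    ``pi(a|s) = 0`` contribute zero to the mutual information.
    """
    pi = _check_policy(pi, vt)
    P_s = vt.P_s
    marginal = P_s @ pi
    # rel_entr(p, q) = p*log(p/q) with rel_entr(0, q) = 0
    per_state = rel_entr(pi, np.broadcast_to(marginal, pi.shape)).sum(axis=1)
    complexity = float(P_s @ per_state)
    reward = float(P_s @ (pi * vt.Q).sum(axis=1))
    return complexity, reward


def blahut_arimoto(
    vt: ValueTable,
    beta: float,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    init_marginal: np.ndarray | None = None,
) -> PolicyMatrix:
    """Solve for the optimal policy at inverse temperature ``beta``.

    Alternates the softmax policy update with the state-averaged marginal
    update until the marginal changes by less than ``tol`` in max-norm.
    The marginal is initialized uniform (the beta = 0 fixed point) unless
    ``init_marginal`` is given (used to warm-start curve sweeps; the
    convergence of dominated-action mass is slow at small beta).
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n_a = vt.n_actions
    if init_marginal is None:
        marginal = np.full(n_a, 1.0 / n_a)
    else:
        marginal = np.asarray(init_marginal, dtype=float).copy()
    pi = np.broadcast_to(marginal, vt.Q.shape).copy()
    resid = np.inf
    for _ in range(max_iter):
        logits = beta * vt.Q + np.log(np.maximum(marginal, _LOG_FLOOR))
        logits = logits - logits.max(axis=1, keepdims=True)
        pi = np.exp(logits)
        pi /= pi.sum(axis=1, keepdims=True)
        new_marginal = vt.P_s @ pi
        resid = float(np.abs(new_marginal - marginal).max())
        marginal = new_marginal
        if resid < tol:
            break
    else:
        raise ConvergenceError(
            f"Blahut-Arimoto did not converge in {max_iter} iterations "
            f"(last marginal residual {resid:.3e}, beta={beta})"
        )
    complexity, reward = policy_stats(pi, vt)
    return PolicyMatrix(pi=pi, marginal=marginal, complexity=complexity, reward=reward)


def tradeoff_curve(
    vt: ValueTable,
    beta_grid: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> TradeoffCurve:
    """Trace the optimal frontier with one Blahut-Arimoto solve per beta."""
    if beta_grid is None:
        beta_grid = default_beta_grid()
    beta_grid = np.asarray(beta_grid, dtype=float)
    if np.any(np.diff(beta_grid) < 0):
        raise ValueError("beta_grid must be ascending")
    if np.any(beta_grid < 0):
        raise ValueError("beta_grid entries must be non-negative")
    complexities = np.empty(beta_grid.size)
    rewards = np.empty(beta_grid.size)
    marginal = None
    uniform = np.full(vt.n_actions, 1.0 / vt.n_actions)
    for i, b in enumerate(beta_grid):
        # warm start from the previous solution, remixed with uniform mass so
        # actions suppressed at low beta can re-enter the support at high beta
        init = None if marginal is None else 0.9 * marginal + 0.1 * uniform
        pol = blahut_arimoto(vt, b, tol=tol, max_iter=max_iter, init_marginal=init)
        marginal = pol.marginal
        complexities[i] = pol.complexity
        rewards[i] = pol.reward
    return TradeoffCurve(beta_grid, complexities, rewards)


def beta_for_capacity(curve: TradeoffCurve, C: float) -> float:
    """Inverse temperature at which the frontier's complexity equals ``C``.

    Linear interpolation in (complexity, beta).  At the frontier the local
    slope dV/dI equals 1/beta, so this is the beta an optimal channel with
    capacity ``C`` would adopt.
    """
    if C < 0:
        raise ValueError("capacity must be non-negative")
    cmax = float(curve.complexities.max())
    if C > cmax + 1e-12:
        raise ValueError(f"capacity {C} exceeds curve maximum {cmax}")
    if C >= curve.complexities[-1]:
        return float(curve.betas[-1])
    return float(np.interp(C, curve.complexities, curve.betas))


def optimal_reward_at(curve: TradeoffCurve, I: float | np.ndarray) -> float | np.ndarray:
    """Optimal expected reward at policy complexity ``I`` (nats).

    Piecewise-linear interpolation of the (complexity, reward) frontier;
    complexities above the curve maximum are clamped to the terminal reward.
    """
    I_arr = np.asarray(I, dtype=float)
    if np.any(I_arr < 0):
        raise ValueError("complexity must be non-negative")
    out = np.interp(I_arr, curve.complexities, curve.rewards)
    if I_arr.ndim == 0:
        return float(out)
    return out
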