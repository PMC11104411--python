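"""Numba-compiled trial-loop likelihood kernel.

Mirrors the step-based recursion in :mod:`policycomp.agents` exactly
(update order, floors, renormalization); tests assert agreement between the
two routes.  Model codes: 0 fixed, 1 adaptive, 2 reduced_adaptive,
3 no_cost.  Parameter vector layouts follow ``agents.FREE_PARAMS``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_P_FLOOR = 1e-8
_PI_FLOOR = 1e-300
_BETA_MAX = 50.0


@njit(cache=True)
def loglik_kernel(
    model: int,
    p: np.ndarray,
    state: np.ndarray,
    action: np.ndarray,
    reward: np.ndarray,
    block_ptr: np.ndarray,
    n_states: np.ndarray,
    n_actions: int,
    scale_by_n: bool,
) -> float:
    if model == 0 or model == 3:  # fixed / no_cost: [beta, a_theta, a_V, a_P]
        beta = p[0]
        C = 0.0
        a_beta = 0.0
        a_theta = p[1]
        a_V = p[2]
        a_P = p[3]
    elif model == 1:  # adaptive: [C, beta0, a_beta, a_theta, a_V, a_P]
        C = p[0]
        beta0 = p[1]
        a_beta = p[2]
        a_theta = p[3]
        a_V = p[4]
        a_P = p[5]
        beta = beta0
    else:  # reduced_adaptive: [C, beta0, a_beta, a_theta, a_V]
        C = p[0]
        beta0 = p[1]
        a_beta = p[2]
        a_theta = p[3]
        a_V = p[4]
        a_P = 0.0
        beta = beta0

    P_a = np.full(n_actions, 1.0 / n_actions)
    logits = np.empty(n_actions)
    pi = np.empty(n_actions)
    total = 0.0
    n_blocks = n_states.shape[0]
    for b in range(n_blocks):
        N = n_states[b]
        theta = np.zeros((N, n_actions))
        V = np.zeros(N)
        t = 1.0
        if model == 1 or model == 2:
            beta = beta0  # beta re-adapts to each block's set size
        for i in range(block_ptr[b], block_ptr[b + 1]):
            s = state[i]
            a = action[i]
            r = reward[i]
            # softmax of beta*theta[s] + log P_a
            m = -np.inf
            for j in range(n_actions):
                logits[j] = beta * theta[s, j] + np.log(P_a[j])
                if logits[j] > m:
                    m = logits[j]
            z = 0.0
            for j in range(n_actions):
                pi[j] = np.exp(logits[j] - m)
                z += pi[j]
            for j in range(n_actions):
                pi[j] /= z
            pa = pi[a]
            if pa < _PI_FLOOR:
                pa = _PI_FLOOR
            lp = np.log(pa)
            total += lp
            cost = lp - np.log(P_a[a])
            if model == 3:
                delta = beta * r - V[s]
            else:
                delta = beta * r - cost - V[s]
            lr = a_theta / t
            if scale_by_n:
                lr /= N
            theta[s, a] += lr * delta * (1.0 - pi[a]) * beta
            V[s] += a_V * delta
            if a_P > 0.0:
                z = 0.0
                for j in range(n_actions):
                    P_a[j] += a_P * (pi[j] - P_a[j])
                    if P_a[j] < _P_FLOOR:
                        P_a[j] = _P_FLOOR
                    z += P_a[j]
                for j in range(n_actions):
                    P_a[j] /= z
            R = cost
            if model == 1 or model == 2:
                dot = 0.0
                for j in range(n_actions):
                    dot += theta[s, j] * pi[j]
                beta += a_beta * (C - R) * (theta[s, a] - dot)
                if beta < 0.0:
                    beta = 0.0
                elif beta > _BETA_MAX:
                    beta = _BETA_MAX
            t += 1.0
    return total
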