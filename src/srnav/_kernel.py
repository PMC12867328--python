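"""Compiled inner loop of the perceive-act-learn cycle.

Numerically mirrors :func:`srnav.agent.agent_act_and_learn` (same update
order, same arithmetic, same two-uniforms-per-step draw discipline) but
runs as a single jit-compiled episode.  The legacy MT19937 generator used
by numba's ``np.random`` is the same algorithm as
``np.random.RandomState``, so seeded episodes are reproducible against
the pure-Python path; a replay-equivalence test keeps the two in lock
step.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

N_ACTIONS = 4


@njit(cache=True)
def run_episode_kernel(
    seed, start_u, cap,
    view_of_u, next_u, reward_cell,
    cavity_mask, wallnear_mask, barrier_mask, prev_masks,
    M_s_A, M_A, M_s_E, M_E,
    w_A, w_E, m_A, m_E, v_A, v_E, t_arr,
    alpha_A, alpha_E, gamma_A, gamma_E, gamma_Q,
    eta, b1, b2, eps_adam, epsilon, tau,
    use_allo, use_ego_sr, use_ego_onehot, use_adam, no_sqrt,
    record, u_seq, a_seq,
):
    np.random.seed(seed)
    nA = M_s_A.shape[0]
    nE = w_E.shape[0]
    K = prev_masks.shape[0]
    prev_counts = np.zeros(K, dtype=np.int64)
    q = np.zeros(N_ACTIONS)
    q2 = np.zeros(N_ACTIONS)
    u = start_u
    counted = 0
    hole = 0
    wall = 0
    curbar = 0
    primitive = 0
    done = False
    for it in range(cap):
        c = u // 4
        d = u % 4
        sE = view_of_u[u]
        # occupancy bookkeeping counts the pre-step cell of every primitive step
        if cavity_mask[c]:
            hole += 1
        if wallnear_mask[c]:
            wall += 1
        if barrier_mask[c]:
            curbar += 1
        for k in range(K):
            if prev_masks[k, c]:
                prev_counts[k] += 1
        # --- action values -------------------------------------------------
        for a in range(N_ACTIONS):
            acc = 0.0
            if use_allo:
                aA = (d + a) % 4
                for j in range(nA):
                    acc += M_A[aA, c, j] * w_A[j]
            if use_ego_sr:
                for j in range(nE):
                    acc += M_E[a, sE, j] * w_E[j]
            elif use_ego_onehot:
                acc += w_E[sE]
            q[a] = acc
        # --- epsilon-softmax selection (two uniforms per step) -------------
        r1 = np.random.random()
        r2 = np.random.random()
        if r1 < epsilon:
            a = min(int(r2 * N_ACTIONS), N_ACTIONS - 1)
        else:
            qmax = q[0]
            for i in range(1, N_ACTIONS):
                if q[i] > qmax:
                    qmax = q[i]
            zsum = 0.0
            for i in range(N_ACTIONS):
                q2[i] = math.exp((q[i] - qmax) / tau)
                zsum += q2[i]
            a = N_ACTIONS - 1
            cum = 0.0
            for i in range(N_ACTIONS):
                cum += q2[i] / zsum
                if r2 < cum:
                    a = i
                    break
        if record:
            u_seq[it] = u
            a_seq[it] = a
        # --- environment transition ---------------------------------------
        u2 = next_u[u, a]
        c2 = u2 // 4
        d2 = u2 % 4
        sE2 = view_of_u[u2]
        done = c2 == reward_cell
        r = 1.0 if done else 0.0
        if a == 0:  # go-forward selection, the counted metric
            counted += 1
        aA = (d + a) % 4
        # --- SR TD updates (state-state first, then state-action) ----------
        if use_allo:
            if done:
                f = 1.0 - alpha_A
                for j in range(nA):
                    M_s_A[c, j] *= f
            elif c2 == c:
                f = 1.0 - alpha_A * (1.0 - gamma_A)
                for j in range(nA):
                    M_s_A[c, j] *= f
            else:
                for j in range(nA):
                    M_s_A[c, j] += alpha_A * (gamma_A * M_s_A[c2, j] - M_s_A[c, j])
            M_s_A[c, c2] += alpha_A
            if done:
                f = 1.0 - alpha_A
                for j in range(nA):
                    M_A[aA, c, j] *= f
            else:
                for j in range(nA):
                    M_A[aA, c, j] += alpha_A * (gamma_A * M_s_A[c2, j] - M_A[aA, c, j])
            M_A[aA, c, c2] += alpha_A
        if use_ego_sr:
            if done:
                f = 1.0 - alpha_E
                for j in range(nE):
                    M_s_E[sE, j] *= f
            elif sE2 == sE:
                f = 1.0 - alpha_E * (1.0 - gamma_E)
                for j in range(nE):
                    M_s_E[sE, j] *= f
            else:
                for j in range(nE):
                    M_s_E[sE, j] += alpha_E * (gamma_E * M_s_E[sE2, j] - M_s_E[sE, j])
            M_s_E[sE, sE2] += alpha_E
            if done:
                f = 1.0 - alpha_E
                for j in range(nE):
                    M_E[a, sE, j] *= f
            else:
                for j in range(nE):
                    M_E[a, sE, j] += alpha_E * (gamma_E * M_s_E[sE2, j] - M_E[a, sE, j])
            M_E[a, sE, sE2] += alpha_E
        # --- Q-learning step on the freshly updated features ---------------
        q_sa = 0.0
        if use_allo:
            for j in range(nA):
                q_sa += M_A[aA, c, j] * w_A[j]
        if use_ego_sr:
            for j in range(nE):
                q_sa += M_E[a, sE, j] * w_E[j]
        elif use_ego_onehot:
            q_sa += w_E[sE]
        target = r
        if not done:
            for a2 in range(N_ACTIONS):
                acc = 0.0
                if use_allo:
                    aA2 = (d2 + a2) % 4
                    for j in range(nA):
                        acc += M_A[aA2, c2, j] * w_A[j]
                if use_ego_sr:
                    for j in range(nE):
                        acc += M_E[a2, sE2, j] * w_E[j]
                elif use_ego_onehot:
                    acc += w_E[sE2]
                q2[a2] = acc
            qmax2 = q2[0]
            for i in range(1, N_ACTIONS):
                if q2[i] > qmax2:
                    qmax2 = q2[i]
            target += gamma_Q * qmax2
        delta = target - q_sa
        t_arr[0] += 1
        t = t_arr[0]
        bc1 = 1.0 - b1 ** t
        bc2 = 1.0 - b2 ** t
        if use_allo:
            if use_adam:
                for j in range(nA):
                    g = delta * M_A[aA, c, j]
                    m_A[j] = m_A[j] * b1 + (1.0 - b1) * g
                    v_A[j] = v_A[j] * b2 + ((1.0 - b2) * g) * g
                    m_hat = m_A[j] / bc1
                    v_hat = v_A[j] / bc2
                    if no_sqrt:
                        if v_hat > 0.0:
                            w_A[j] += eta * (m_hat / v_hat)
                    else:
                        w_A[j] += eta * (m_hat / (math.sqrt(v_hat) + eps_adam))
            else:
                for j in range(nA):
                    w_A[j] += eta * (delta * M_A[aA, c, j])
        if use_ego_sr or use_ego_onehot:
            if use_adam:
                for j in range(nE):
                    if use_ego_sr:
                        g = delta * M_E[a, sE, j]
                    else:
                        g = delta if j == sE else 0.0
                    m_E[j] = m_E[j] * b1 + (1.0 - b1) * g
                    v_E[j] = v_E[j] * b2 + ((1.0 - b2) * g) * g
                    m_hat = m_E[j] / bc1
                    v_hat = v_E[j] / bc2
                    if no_sqrt:
                        if v_hat > 0.0:
                            w_E[j] += eta * (m_hat / v_hat)
                    else:
                        w_E[j] += eta * (m_hat / (math.sqrt(v_hat) + eps_adam))
            else:
                if use_ego_sr:
                    for j in range(nE):
                        w_E[j] += eta * (delta * M_E[a, sE, j])
                else:
                    w_E[sE] += eta * delta
        u = u2
        primitive = it + 1
        if done:
            break
    return primitive, counted, done, hole, wall, curbar, prev_counts, u
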