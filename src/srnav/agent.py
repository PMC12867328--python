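"""Linear Q-learning over concatenated two-frame SR features.

The action value of an egocentric action ``a`` in pose ``(s_A, s_E, d)``
is a single weight vector dotted with the concatenation of (i) the
allocentric state-action SR row for the compass direction that ``a``
realises at heading ``d`` and (ii) the egocentric state-action SR row for
``a`` itself.  Weights are learned by semi-gradient Q-learning with an
ADAM step (the two SR bases have very different magnitudes, which a
global learning rate handles poorly).

Lesion variants remove one block (and its learning), replace the
egocentric SR features by a raw one-hot of the view index, or replace
the ADAM step by plain SGD.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .grid import (GO_FORWARD, N_ACTIONS, AgentState, World, ego_view,
                   inverse_rotate_action, step)
from .sr import SRSet


class Lesion(str, Enum):
    FULL = "FULL"
    ALLO_ONLY = "ALLO_ONLY"
    EGO_ONLY = "EGO_ONLY"
    EGO_QLEARNER = "EGO_QLEARNER"
    NO_ADAM = "NO_ADAM"

    @property
    def uses_allo(self) -> bool:
        return self is not Lesion.EGO_ONLY

    @property
    def uses_ego_sr(self) -> bool:
        return self in (Lesion.FULL, Lesion.EGO_ONLY, Lesion.NO_ADAM)

    @property
    def uses_ego_onehot(self) -> bool:
        return self is Lesion.EGO_QLEARNER

    @property
    def uses_ego_block(self) -> bool:
        return self.uses_ego_sr or self.uses_ego_onehot

    @property
    def uses_adam(self) -> bool:
        return self is not Lesion.NO_ADAM


@dataclass
class PolicyParams:
    """Epsilon-softmax action selection."""

    epsilon: float = 0.05
    tau: float = 0.02

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass
class QModel:
    """Weight vector over the two feature blocks plus optimizer state."""

    w_A: np.ndarray
    w_E: np.ndarray
    m_A: np.ndarray
    m_E: np.ndarray
    v_A: np.ndarray
    v_E: np.ndarray
    t: int = 0
    eta: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    eps_adam: float = 1e-8
    gamma_Q: float = 0.95
    adam_no_sqrt: bool = False
    lesion: Lesion = Lesion.FULL

    @classmethod
    def zeros(cls, n_allo: int, n_ego: int, **kw) -> "QModel":
        return cls(w_A=np.zeros(n_allo), w_E=np.zeros(n_ego),
                   m_A=np.zeros(n_allo), m_E=np.zeros(n_ego),
                   v_A=np.zeros(n_allo), v_E=np.zeros(n_ego), **kw)

    def grow_ego(self, n_new: int) -> None:
        """Append zero-initialised coordinates for new egocentric states."""
        pad = n_new - self.w_E.shape[0]
        if pad > 0:
            self.w_E = np.concatenate([self.w_E, np.zeros(pad)])
            self.m_E = np.concatenate([self.m_E, np.zeros(pad)])
            self.v_E = np.concatenate([self.v_E, np.zeros(pad)])


def feature_vector(sr: SRSet, s_A: int, s_E: int, d: int, a: int,
                   lesion: Lesion = Lesion.FULL) -> np.ndarray:
    """Concatenated feature vector for egocentric action ``a``.

    The allocentric block is the state-action SR row of the compass action
    the egocentric action realises at heading ``d``; the egocentric block
    is the view-level state-action SR row (or a one-hot of the view for the
    EGO_QLEARNER variant).  Lesioned blocks are identically zero.
    """
    n_E = sr.n_ego
    f_A = np.zeros(sr.n_allo)
    f_E = np.zeros(n_E)
    if lesion.uses_allo:
        f_A[:] = sr.M_A[inverse_rotate_action(d, a), s_A]
    if lesion.uses_ego_sr:
        f_E[:] = sr.M_E[a, s_E]
    elif lesion.uses_ego_onehot:
        f_E[s_E] = 1.0
    return np.concatenate([f_A, f_E])


def q_values(model: QModel, sr: SRSet, s_A: int, s_E: int, d: int) -> np.ndarray:
    """Action values of all four egocentric actions at one pose."""
    lesion = model.lesion
    q = np.zeros(N_ACTIONS)
    if lesion.uses_allo:
        if model.w_A.shape[0] != sr.n_allo:
            raise ValueError("model/SR allocentric dimension mismatch")
        perm = [(d + a) % 4 for a in range(N_ACTIONS)]
        q += sr.M_A[perm, s_A] @ model.w_A
    if lesion.uses_ego_sr:
        if model.w_E.shape[0] != sr.n_ego:
            raise ValueError("model/SR egocentric dimension mismatch")
        q += sr.M_E[:, s_E] @ model.w_E
    elif lesion.uses_ego_onehot:
        q += model.w_E[s_E]
    return q


def softmax_probabilities(q: np.ndarray, tau: float) -> np.ndarray:
    z = np.exp((q - q.max()) / tau)
    return z / z.sum()


def select_action(q: np.ndarray, policy: PolicyParams, rng) -> int:
    """Epsilon-softmax draw.

    Always consumes exactly two uniform variates (explore test, then either
    the uniform action or the softmax category), so action sequences are
    reproducible across implementations sharing the generator state.
    """
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite action values")
    r1 = rng.random()
    r2 = rng.random()
    if r1 < policy.epsilon:
        return min(int(r2 * N_ACTIONS), N_ACTIONS - 1)
    p = softmax_probabilities(q, policy.tau)
    c = 0.0
    for a in range(N_ACTIONS):
        c += p[a]
        if r2 < c:
            return a
    return N_ACTIONS - 1


def _adam_step(w, m, v, g, t, eta, b1, b2, eps, no_sqrt):
    m *= b1
    m += (1 - b1) * g
    v *= b2
    v += (1 - b2) * g * g
    m_hat = m / (1 - b1 ** t)
    v_hat = v / (1 - b2 ** t)
    if no_sqrt:  # the dimensionally unstable literal variant, off by default
        with np.errstate(divide="ignore", invalid="ignore"):
            upd = np.where(v_hat > 0, m_hat / v_hat, 0.0)
    else:
        upd = m_hat / (np.sqrt(v_hat) + eps)
    w += eta * upd


def adam_q_update(model: QModel, sr: SRSet, s_A: int, s_E: int, d: int, a: int,
                  reward: float, s2_A: int, s2_E: int, d2: int,
                  terminal: bool) -> float:
    """One semi-gradient Q-learning step; returns the TD error.

    The gradient is the TD error times the feature vector; moments decay on
    every step for every coordinate.  The bootstrap term is dropped on
    terminal transitions.  Returns delta for diagnostics.
    """
    q_sa = q_values(model, sr, s_A, s_E, d)[a]
    target = reward
    if not terminal:
        target += model.gamma_Q * q_values(model, sr, s2_A, s2_E, d2).max()
    delta = target - q_sa
    lesion = model.lesion
    model.t += 1
    if lesion.uses_allo:
        g_A = delta * sr.M_A[inverse_rotate_action(d, a), s_A]
        if lesion.uses_adam:
            _adam_step(model.w_A, model.m_A, model.v_A, g_A, model.t,
                       model.eta, model.beta1, model.beta2, model.eps_adam,
                       model.adam_no_sqrt)
        else:
            model.w_A += model.eta * g_A
    if lesion.uses_ego_block:
        if lesion.uses_ego_sr:
            g_E = delta * sr.M_E[a, s_E]
        else:
            g_E = np.zeros_like(model.w_E)
            g_E[s_E] = delta
        if lesion.uses_adam:
            _adam_step(model.w_E, model.m_E, model.v_E, g_E, model.t,
                       model.eta, model.beta1, model.beta2, model.eps_adam,
                       model.adam_no_sqrt)
        else:
            model.w_E += model.eta * g_E
    return delta


@dataclass
class StepRecord:
    action: int
    reward: float
    done: bool
    counted: bool           # a go-forward selection (the performance metric)
    td_error: float
    state: AgentState
    next_state: AgentState


def agent_act_and_learn(model: QModel, sr: SRSet, world: World,
                        state: AgentState, policy: PolicyParams, rng,
                        horizon: int) -> tuple[AgentState, StepRecord]:
    """One full perceive-act-learn cycle (reference implementation).

    Selects an egocentric action from the composite Q-values, steps the
    world, TD-updates both frames' SRs (a turn is an allocentric
    self-transition under the compass action chosen at the pre-step
    heading), then applies the Q-learning step using the freshly updated
    SR features.  The experiment runner uses a numerically identical
    compiled kernel; this function is the readable, testable form.
    """
    iw = world.width - 2
    s_A = (state.y - 1) * iw + (state.x - 1)
    lesion = model.lesion
    need_ego = lesion.uses_ego_block
    s_E = sr.codebook.encode(ego_view(world, state, horizon)) if need_ego else 0
    if need_ego and lesion.uses_ego_sr and sr.n_ego < sr.codebook.n_views:
        from .sr import grow_ego_tables
        while sr.n_ego < sr.codebook.n_views:
            sr.M_s_E, sr.M_E = grow_ego_tables(sr.M_s_E, sr.M_E)
    if need_ego:
        model.grow_ego(sr.codebook.n_views)
    q = q_values(model, sr, s_A, s_E, state.d)
    a = select_action(q, policy, rng)
    nxt, reward, done = step(world, state, a)
    s2_A = (nxt.y - 1) * iw + (nxt.x - 1)
    s2_E = sr.codebook.encode(ego_view(world, nxt, horizon)) if need_ego else 0
    if need_ego and lesion.uses_ego_sr and sr.n_ego < sr.codebook.n_views:
        from .sr import grow_ego_tables
        while sr.n_ego < sr.codebook.n_views:
            sr.M_s_E, sr.M_E = grow_ego_tables(sr.M_s_E, sr.M_E)
    if need_ego:
        model.grow_ego(sr.codebook.n_views)
    a_allo = inverse_rotate_action(state.d, a)
    if lesion.uses_allo:
        sr.update_allocentric(s_A, a_allo, s2_A, terminal=done)
    if lesion.uses_ego_sr:
        sr.update_egocentric(s_E, a, s2_E, terminal=done)
    delta = adam_q_update(model, sr, s_A, s_E, state.d, a, reward,
                          s2_A, s2_E, nxt.d, done)
    rec = StepRecord(action=a, reward=reward, done=done,
                     counted=(a == GO_FORWARD), td_error=delta,
                     state=state, next_state=nxt)
    return nxt, rec
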