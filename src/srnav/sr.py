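"""Successor representations in two reference frames.

The allocentric SR lives on interior grid cells with compass actions; the
egocentric SR lives on distinct occluded views with turn/forward actions.
Distinct poses that produce the same view are *aliased* into one
egocentric state through a codebook of canonical view serialisations.

Both frames keep a state-state table ``M_s`` (expected discounted future
occupancy of each state, bootstrapped on the next state) and a
state-action table ``M`` conditioning on the first action.  Tables are
initialised at the fixed points of the TD rules under uniformly random
actions — the allocentric one on an empty world, the egocentric one on
the average view-transition structure of the task's worlds — and then
track the agent's own behaviour by online TD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .grid import (BARRIER, DIR_DX, DIR_DY, GO_FORWARD, N_ACTIONS,
                   OCCLUDED, OUTSIDE, EgoView, World, cells_between)

_BLOCKING_LABELS = (BARRIER, 2, 3, 4, 5)  # barrier + the four walls

_log = logging.getLogger("srnav")
_CAPACITY_WARNED = False  # emit the capacity note at most once per process


def reported_ego_capacity(horizon: int) -> int:
    """The closed-form pixel-count expression 2(H+1)(2H+1) - 1.

    Recorded as metadata only: the operative egocentric dimension is the
    number of distinct *categorical* views actually enumerated, which
    routinely exceeds this figure."""
    return 2 * (horizon + 1) * (2 * horizon + 1) - 1


# ---------------------------------------------------------------------------
# egocentric codebook


class EgoCodebook:
    """Injective map from egocentric views to dense integer indices.

    Encoding a previously seen view returns its existing index; a new view
    appends.  Keys are the canonical byte serialisation of the pixel array,
    so aliased poses (same view, different place) collapse to one state.
    """

    def __init__(self, horizon: int):
        self.horizon = horizon
        self._index: dict[bytes, int] = {}
        self._views: list[bytes] = []

    @property
    def reported_capacity(self) -> int:
        return reported_ego_capacity(self.horizon)

    def check_capacity(self) -> None:
        global _CAPACITY_WARNED
        if self.n_views > self.reported_capacity and not _CAPACITY_WARNED:
            _CAPACITY_WARNED = True
            _log.info(
                "enumerated %d distinct views at H=%d, above the reported "
                "closed-form capacity %d (metadata only; tables are sized "
                "by the enumerated count)", self.n_views, self.horizon,
                self.reported_capacity)

    @property
    def n_views(self) -> int:
        return len(self._views)

    def encode_key(self, key: bytes) -> int:
        idx = self._index.get(key)
        if idx is None:
            idx = len(self._views)
            self._index[key] = idx
            self._views.append(key)
        return idx

    def encode(self, view: EgoView) -> int:
        if view.horizon != self.horizon:
            raise ValueError("view horizon does not match codebook")
        return self.encode_key(view.key())

    def lookup(self, view: EgoView) -> int | None:
        """Index of a view if already known, else None (no growth)."""
        return self._index.get(view.key())

    def view_pixels(self, idx: int) -> np.ndarray:
        H = self.horizon
        return np.frombuffer(self._views[idx], dtype=np.int8).reshape(
            H + 1, 2 * H + 1)


# ---------------------------------------------------------------------------
# closed-form uniform-policy SRs


def uniform_policy_sr(T: np.ndarray, gamma: float,
                      T_actions: np.ndarray | None = None):
    """Fixed points of the TD rules under a row-stochastic one-step matrix.

    ``M_s = T (I - gamma T)^{-1}`` is the fixed point of the next-state
    occupancy update; with action-conditioned one-step matrices ``T_a`` the
    state-action fixed point is ``M_a = T_a (I + gamma M_s)``.
    """
    n = T.shape[0]
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("T must be row-stochastic")
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must be in (0, 1)")
    A = np.eye(n) - gamma * T
    # M_s = T A^{-1}  <=>  A^T M_s^T = T^T
    M_s = scipy.linalg.solve(A.T, T.T, assume_a="gen").T
    if T_actions is None:
        return M_s, None
    B = np.eye(n) + gamma * M_s
    M = np.stack([T_actions[a] @ B for a in range(T_actions.shape[0])])
    return M_s, M


def allocentric_transitions(width: int, height: int):
    """One-step matrices on the empty walled world under compass actions.

    Returns ``(T, T_a)`` over all interior cells; blocked moves (into a
    wall) self-loop.  ``T`` is the uniform mixture of the four ``T_a``.
    """
    iw, ih = width - 2, height - 2
    n = iw * ih
    T_a = np.zeros((4, n, n))
    for y in range(1, height - 1):
        for x in range(1, width - 1):
            s = (y - 1) * iw + (x - 1)
            for a in range(4):
                nx, ny = x + DIR_DX[a], y + DIR_DY[a]
                if 1 <= nx <= width - 2 and 1 <= ny <= height - 2:
                    s2 = (ny - 1) * iw + (nx - 1)
                else:
                    s2 = s
                T_a[a, s, s2] += 1.0
    return T_a.mean(axis=0), T_a


def init_allocentric_sr(width: int, height: int, gamma: float):
    """Uniform-policy SR tables for the allocentric frame (empty world)."""
    T, T_a = allocentric_transitions(width, height)
    return uniform_policy_sr(T, gamma, T_a)


# ---------------------------------------------------------------------------
# per-world state tables (views, dynamics, metric masks)


@dataclass
class WorldTables:
    """Precomputed per-world lookups for fast simulation.

    Pose ids are ``u = cell * 4 + d`` over interior cells (row-major) and
    headings; only traversable poses are valid.
    """

    world: World
    horizon: int
    n_cells: int
    view_of_u: np.ndarray      # (n_cells*4,) int32, -1 for invalid poses
    next_u: np.ndarray         # (n_cells*4, 4 actions) int32
    traversable: np.ndarray    # (n_cells,) bool
    reward_index: int
    cavity_mask: np.ndarray    # (n_cells,) bool — inside a U cavity
    wallnear_mask: np.ndarray  # (n_cells,) bool — first interior ring
    barrier_mask: np.ndarray   # (n_cells,) bool — cavity or next to a barrier
    free_poses: np.ndarray = field(default=None)  # valid u excluding reward cell

    def cell_index(self, x: int, y: int) -> int:
        return (y - 1) * (self.world.width - 2) + (x - 1)


def _view_rows(world: World, horizon: int):
    """Vectorised occluded views for every traversable cell and heading.

    Returns (cells, views) where ``views[d]`` is an (n_cells, n_pix) int8
    array of view rows for heading ``d``.  Line-of-sight is translation
    invariant, so the strictly-between cells of each window pixel are
    precomputed once as offsets.
    """
    H = horizon
    pad = np.full((world.height + 2 * H, world.width + 2 * H), OUTSIDE,
                  dtype=np.int8)
    pad[H:H + world.height, H:H + world.width] = world.cells
    blocking = np.isin(pad, _BLOCKING_LABELS)
    cells = world.traversable_cells()
    xs = np.array([c[0] for c in cells]) + H
    ys = np.array([c[1] for c in cells]) + H
    views = []
    for d in range(4):
        fdx, fdy = DIR_DX[d], DIR_DY[d]
        rd = (d + 1) % 4
        rdx, rdy = DIR_DX[rd], DIR_DY[rd]
        n_pix = (H + 1) * (2 * H + 1)
        out = np.empty((len(cells), n_pix), dtype=np.int8)
        p = 0
        for k in range(H + 1):
            for c in range(2 * H + 1):
                lat = c - H
                ox, oy = k * fdx + lat * rdx, k * fdy + lat * rdy
                label = pad[ys + oy, xs + ox]
                if (ox, oy) != (0, 0):
                    blocked = np.zeros(len(cells), dtype=bool)
                    for (ix, iy) in cells_between((0, 0), (ox, oy)):
                        blocked |= blocking[ys + iy, xs + ix]
                    occ = blocked & (label != OUTSIDE)
                    label = np.where(occ, OCCLUDED, label).astype(np.int8)
                out[:, p] = label
                p += 1
        views.append(out)
    return cells, views


def build_world_tables(world: World, horizon: int,
                       codebook: EgoCodebook) -> WorldTables:
    """Enumerate all poses of a world: encode views, tabulate dynamics."""
    iw, ih = world.width - 2, world.height - 2
    n_cells = iw * ih
    cells, views = _view_rows(world, horizon)
    cell_idx = {(x, y): (y - 1) * iw + (x - 1) for (x, y) in cells}
    view_of_u = np.full(n_cells * 4, -1, dtype=np.int32)
    # enumeration order: cells row-major, heading inner — codebook indices
    # are a pure function of (task worlds, horizon)
    for i, (x, y) in enumerate(cells):
        for d in range(4):
            view_of_u[cell_idx[(x, y)] * 4 + d] = codebook.encode_key(
                views[d][i].tobytes())
    next_u = np.full((n_cells * 4, N_ACTIONS), -1, dtype=np.int32)
    for (x, y) in cells:
        ci = cell_idx[(x, y)]
        for d in range(4):
            u = ci * 4 + d
            for a in range(N_ACTIONS):
                if a == GO_FORWARD:
                    nx, ny = x + DIR_DX[d], y + DIR_DY[d]
                    if not world.is_traversable(nx, ny):
                        nx, ny = x, y
                    next_u[u, a] = cell_idx[(nx, ny)] * 4 + d
                else:
                    next_u[u, a] = ci * 4 + (d + a) % 4
    trav = np.zeros(n_cells, dtype=bool)
    for (x, y) in cells:
        trav[cell_idx[(x, y)]] = True
    rx, ry = world.reward_cell
    reward_index = (ry - 1) * iw + (rx - 1)
    cavity = np.zeros(n_cells, dtype=bool)
    for (x, y) in world.cavity_cells:
        cavity[(y - 1) * iw + (x - 1)] = True
    wallnear = np.zeros(n_cells, dtype=bool)
    for (x, y) in cells:
        if x == 1 or y == 1 or x == world.width - 2 or y == world.height - 2:
            wallnear[cell_idx[(x, y)]] = True
    barrier = cavity.copy()
    bar_cells = {(x, y) for y in range(world.height) for x in range(world.width)
                 if world.cells[y, x] == BARRIER}
    for (x, y) in cells:
        if any((bx, by) in bar_cells
               for bx in (x - 1, x, x + 1) for by in (y - 1, y, y + 1)):
            barrier[cell_idx[(x, y)]] = True
    free = np.array([cell_idx[(x, y)] * 4 + d
                     for (x, y) in cells if (x, y) != world.reward_cell
                     for d in range(4)], dtype=np.int64)
    return WorldTables(world=world, horizon=horizon, n_cells=n_cells,
                       view_of_u=view_of_u, next_u=next_u, traversable=trav,
                       reward_index=reward_index, cavity_mask=cavity,
                       wallnear_mask=wallnear, barrier_mask=barrier,
                       free_poses=free)


def ego_transitions(tables: WorldTables, n_views: int):
    """One world's view-level transition matrices under uniform ego actions.

    An aliased view's row is the mean of its pose-wise rows (each pose
    weighted equally).  Returns ``(T, T_a, present)`` where ``present[i]``
    marks views instantiated in this world.
    """
    T_a = np.zeros((N_ACTIONS, n_views, n_views))
    counts = np.zeros(n_views)
    for u in range(tables.view_of_u.shape[0]):
        i = tables.view_of_u[u]
        if i < 0:
            continue
        counts[i] += 1.0
        for a in range(N_ACTIONS):
            j = tables.view_of_u[tables.next_u[u, a]]
            T_a[a, i, j] += 1.0
    present = counts > 0
    T_a[:, present, :] /= counts[present, None]
    return T_a.mean(axis=0), T_a, present


def average_ego_transitions(world_tables: list[WorldTables], n_views: int):
    """Presence-weighted average of per-world view transition matrices.

    A view absent from a world contributes nothing to that row's average
    (its row is averaged over the worlds that instantiate it).
    """
    T_sum = np.zeros((n_views, n_views))
    T_a_sum = np.zeros((N_ACTIONS, n_views, n_views))
    pres_count = np.zeros(n_views)
    for wt in world_tables:
        T, T_a, present = ego_transitions(wt, n_views)
        T_sum[present] += T[present]
        T_a_sum[:, present] += T_a[:, present]
        pres_count += present
    if np.any(pres_count == 0):
        raise ValueError("codebook contains views absent from every world")
    T_bar = T_sum / pres_count[:, None]
    T_a_bar = T_a_sum / pres_count[None, :, None]
    return T_bar, T_a_bar


def init_egocentric_sr(world_tables: list[WorldTables], gamma: float,
                       n_views: int):
    """Uniform-policy egocentric SR from the average task transition matrix."""
    if not world_tables:
        raise ValueError("egocentric initialisation needs at least one world")
    T_bar, T_a_bar = average_ego_transitions(world_tables, n_views)
    return uniform_policy_sr(T_bar, gamma, T_a_bar)


# ---------------------------------------------------------------------------
# online TD updates


def td_update_state_sr(M_s: np.ndarray, s: int, s_next: int, alpha: float,
                       gamma: float, terminal: bool = False) -> None:
    """In-place next-state-occupancy TD update of row ``s``.

    Target is ``onehot(s') + gamma * M_s[s']`` (no bootstrap past a
    terminal transition).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if terminal:
        M_s[s] *= (1.0 - alpha)
    elif s_next == s:
        M_s[s] *= (1.0 - alpha * (1.0 - gamma))
    else:
        M_s[s] += alpha * (gamma * M_s[s_next] - M_s[s])
    M_s[s, s_next] += alpha


def td_update_state_action_sr(M: np.ndarray, M_s: np.ndarray, s: int, a: int,
                              s_next: int, alpha: float, gamma: float,
                              terminal: bool = False) -> None:
    """In-place state-action SR update, bootstrapping off the state-state
    table (which is maintained concurrently)."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if terminal:
        M[a, s] *= (1.0 - alpha)
    else:
        M[a, s] += alpha * (gamma * M_s[s_next] - M[a, s])
    M[a, s, s_next] += alpha


def grow_ego_tables(M_s_E: np.ndarray, M_E: np.ndarray):
    """Extend egocentric SR tables by one new view.

    The new state's rows start at the table-wide mean row (padded with a
    zero column for the new coordinate); existing rows gain a zero column.
    """
    n = M_s_E.shape[0]
    M_s2 = np.zeros((n + 1, n + 1))
    M_s2[:n, :n] = M_s_E
    M_s2[n, :n] = M_s_E.mean(axis=0)
    M2 = np.zeros((N_ACTIONS, n + 1, n + 1))
    M2[:, :n, :n] = M_E
    M2[:, n, :n] = M_E.mean(axis=1)
    return M_s2, M2


@dataclass
class SRSet:
    """Both frames' SR tables plus their discounts and learning rates."""

    M_s_A: np.ndarray          # (N_A, N_A)
    M_A: np.ndarray            # (4, N_A, N_A), compass-action conditioned
    M_s_E: np.ndarray | None   # (N_E, N_E)
    M_E: np.ndarray | None     # (4, N_E, N_E), ego-action conditioned
    gamma_A: float
    gamma_E: float
    alpha_A: float
    alpha_E: float
    codebook: EgoCodebook | None = None

    @property
    def n_allo(self) -> int:
        return self.M_s_A.shape[0]

    @property
    def n_ego(self) -> int:
        return 0 if self.M_s_E is None else self.M_s_E.shape[0]

    def update_allocentric(self, s: int, a_allo: int, s_next: int,
                           terminal: bool = False) -> None:
        td_update_state_sr(self.M_s_A, s, s_next, self.alpha_A, self.gamma_A,
                           terminal)
        td_update_state_action_sr(self.M_A, self.M_s_A, s, a_allo, s_next,
                                  self.alpha_A, self.gamma_A, terminal)

    def update_egocentric(self, s: int, a_ego: int, s_next: int,
                          terminal: bool = False) -> None:
        td_update_state_sr(self.M_s_E, s, s_next, self.alpha_E, self.gamma_E,
                           terminal)
        td_update_state_action_sr(self.M_E, self.M_s_E, s, a_ego, s_next,
                                  self.alpha_E, self.gamma_E, terminal)
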