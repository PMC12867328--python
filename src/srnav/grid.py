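"""Occluded gridworld: cells, deterministic dynamics, egocentric views.

The world is a rectangular grid of labelled cells.  A one-cell boundary
ring carries a distinct wall label per side (so the agent can tell the
four walls apart from its view); the interior holds free space, barrier
cells, and a single rewarded cell.  The agent occupies an interior cell
with one of four compass headings and acts in the egocentric frame
(go-forward / turn).  Its observation is a heading-aligned window of
cell labels, truncated by line-of-sight occlusion: opaque cells (barriers
and walls) hide everything strictly behind them.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# cell labels
EMPTY = 0
BARRIER = 1
WALL_N = 2
WALL_E = 3
WALL_S = 4
WALL_W = 5
OUTSIDE = 6   # view-only: beyond the grid
OCCLUDED = 7  # view-only: hidden behind an opaque cell
REWARD = 8    # view-only, opt-in: rendered reward cell

_BLOCKING = frozenset({BARRIER, WALL_N, WALL_E, WALL_S, WALL_W})

_CHAR_OF_LABEL = {EMPTY: ".", BARRIER: "#", WALL_N: "N", WALL_E: "E",
                  WALL_S: "S", WALL_W: "W"}
_LABEL_OF_CHAR = {v: k for k, v in _CHAR_OF_LABEL.items()}

# ---------------------------------------------------------------------------
# compass directions, clockwise from north; y grows southward (row index)
NORTH, EAST, SOUTH, WEST = 0, 1, 2, 3
DIR_NAMES = ("N", "E", "S", "W")
DIR_DX = (0, 1, 0, -1)
DIR_DY = (-1, 0, 1, 0)

# egocentric actions
GO_FORWARD, TURN_CW_90, TURN_180, TURN_CCW_90 = 0, 1, 2, 3
EGO_ACTION_NAMES = ("GO_FORWARD", "TURN_CW_90", "TURN_180", "TURN_CCW_90")
ALLO_ACTION_NAMES = DIR_NAMES
N_ACTIONS = 4

# heading change of each turn action (GO_FORWARD keeps heading)
_TURN_OF_ACTION = (0, 1, 2, 3)


def rotate_action(d: int, a_allo: int) -> int:
    """Map an allocentric action onto the egocentric action that realises it.

    Facing ``d``, moving in direction ``d`` itself is ``GO_FORWARD``; a
    direction 90 deg clockwise of ``d`` requires ``TURN_CW_90``, and so on.
    A bijection for every fixed heading.
    """
    if not (0 <= d < 4 and 0 <= a_allo < 4):
        raise ValueError(f"invalid direction {d} or allocentric action {a_allo}")
    return (a_allo - d) % 4


def inverse_rotate_action(d: int, a_ego: int) -> int:
    """Inverse of :func:`rotate_action`: the direction an egocentric action points."""
    if not (0 <= d < 4 and 0 <= a_ego < 4):
        raise ValueError(f"invalid direction {d} or egocentric action {a_ego}")
    return (d + a_ego) % 4


# ---------------------------------------------------------------------------


@dataclass
class Barrier:
    """A placed U-shaped barrier: outer bounding box and opening side."""

    x: int            # top-left of the outer footprint
    y: int
    width: int        # outer size, cells
    height: int
    opening: int      # side the cavity opens towards (compass direction)

    def footprint(self) -> list[tuple[int, int]]:
        return [(self.x + i, self.y + j)
                for j in range(self.height) for i in range(self.width)]


@dataclass
class World:
    """A walled grid with barriers and one rewarded interior cell.

    ``cells[y, x]`` holds the label of the cell at column ``x``, row ``y``
    (0-based; row 0 is the north edge).  The boundary ring carries the wall
    label of its side; corner cells take the horizontal wall's label.
    """

    width: int
    height: int
    cells: np.ndarray
    reward_cell: tuple[int, int]
    barriers: list[Barrier] = field(default_factory=list)
    cavity_cells: set[tuple[int, int]] = field(default_factory=set)
    meta: dict = field(default_factory=dict)

    @classmethod
    def empty(cls, width: int = 20, height: int = 20,
              reward_cell: tuple[int, int] | None = None) -> "World":
        """A walled world with an empty interior."""
        if width < 3 or height < 3:
            raise ValueError("world needs at least a 1x1 interior")
        cells = np.full((height, width), EMPTY, dtype=np.int8)
        cells[:, 0] = WALL_W
        cells[:, width - 1] = WALL_E
        cells[0, :] = WALL_N          # corners take the horizontal wall label
        cells[height - 1, :] = WALL_S
        if reward_cell is None:
            reward_cell = (width - 2, 1)  # top-right interior corner
        w = cls(width, height, cells, reward_cell)
        if not w.is_traversable(*reward_cell):
            raise ValueError("reward cell must be an empty interior cell")
        return w

    # -- queries ------------------------------------------------------------
    def in_grid(self, x: int, y: int) -> bool:
        return 0 <= x < self.width and 0 <= y < self.height

    def is_traversable(self, x: int, y: int) -> bool:
        return self.in_grid(x, y) and self.cells[y, x] == EMPTY

    def interior_cells(self) -> list[tuple[int, int]]:
        return [(x, y) for y in range(1, self.height - 1)
                for x in range(1, self.width - 1)]

    def traversable_cells(self) -> list[tuple[int, int]]:
        return [(x, y) for (x, y) in self.interior_cells()
                if self.cells[y, x] == EMPTY]

    def interior_size(self) -> int:
        return (self.width - 2) * (self.height - 2)

    def barrier_pixel_count(self) -> int:
        """Number of barrier-labelled cells (the 'coloured pixel' proxy)."""
        return int(np.sum(self.cells == BARRIER))

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        rows = []
        for y in range(self.height):
            row = "".join(
                "R" if (x, y) == self.reward_cell
                else _CHAR_OF_LABEL[int(self.cells[y, x])]
                for x in range(self.width))
            rows.append(row)
        return {
            "width": self.width,
            "height": self.height,
            "grid": rows,
            "reward_cell": list(self.reward_cell),
            "barriers": [[b.x, b.y, b.width, b.height, b.opening]
                         for b in self.barriers],
            "cavity_cells": sorted(list(c) for c in self.cavity_cells),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "World":
        cells = np.empty((d["height"], d["width"]), dtype=np.int8)
        for y, row in enumerate(d["grid"]):
            for x, ch in enumerate(row):
                cells[y, x] = EMPTY if ch == "R" else _LABEL_OF_CHAR[ch]
        return cls(
            width=d["width"], height=d["height"], cells=cells,
            reward_cell=tuple(d["reward_cell"]),
            barriers=[Barrier(*b) for b in d["barriers"]],
            cavity_cells={tuple(c) for c in d["cavity_cells"]},
            meta=dict(d.get("meta", {})),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "World":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class AgentState:
    """Allocentric pose: interior cell plus compass heading."""

    x: int
    y: int
    d: int

    def __post_init__(self):
        if not 0 <= self.d < 4:
            raise ValueError(f"invalid heading {self.d}")


@dataclass(frozen=True)
class EgoView:
    """Heading-aligned observation window of (H+1) x (2H+1) cell labels.

    ``pixels[k, c]`` is the label ``k`` cells ahead and ``c - H`` cells to
    the agent's right; row 0 is the agent's own row and pixel (0, H) is the
    agent's cell (always EMPTY — the agent does not occlude itself).
    """

    pixels: np.ndarray  # shape (H+1, 2H+1), int8
    horizon: int

    def key(self) -> bytes:
        """Canonical hashable serialisation (codebook key)."""
        return self.pixels.tobytes()


# ---------------------------------------------------------------------------
# dynamics


def step(world: World, state: AgentState, a: int) -> tuple[AgentState, float, bool]:
    """One primitive egocentric action.

    Turns change only the heading.  GO_FORWARD advances one cell along the
    heading when the target is traversable and is otherwise a no-op (the
    step is still consumed).  Entering the rewarded cell yields reward 1
    and terminates the episode.
    """
    if not 0 <= a < N_ACTIONS:
        raise ValueError(f"invalid egocentric action {a}")
    if not world.is_traversable(state.x, state.y):
        raise ValueError(f"agent state {state} is not on a traversable cell")
    if a == GO_FORWARD:
        nx, ny = state.x + DIR_DX[state.d], state.y + DIR_DY[state.d]
        if not world.is_traversable(nx, ny):
            nx, ny = state.x, state.y
        nxt = AgentState(nx, ny, state.d)
    else:
        nxt = AgentState(state.x, state.y, (state.d + _TURN_OF_ACTION[a]) % 4)
    done = (nxt.x, nxt.y) == world.reward_cell
    return nxt, (1.0 if done else 0.0), done


# ---------------------------------------------------------------------------
# visibility


def cells_between(a: tuple[int, int], b: tuple[int, int]) -> list[tuple[int, int]]:
    """Cells strictly between two cell centres whose interior the open
    segment crosses (exact integer supercover; a cell grazed only at a
    corner is skipped)."""
    ax, ay = a
    bx, by = b
    dx, dy = bx - ax, by - ay
    if dx == 0 and dy == 0:
        return []
    sx = 1 if dx > 0 else -1
    sy = 1 if dy > 0 else -1
    adx, ady = abs(dx), abs(dy)
    cx, cy = ax, ay
    out: list[tuple[int, int]] = []
    while True:
        # time (scaled) to the next vertical / horizontal cell boundary:
        # centres sit at odd coordinates of the doubled lattice, boundaries
        # at even ones, so both numerators are exact integers.
        nx_num = abs(2 * (cx - ax) + sx) if adx else 0
        ny_num = abs(2 * (cy - ay) + sy) if ady else 0
        if adx and (not ady or nx_num * ady < ny_num * adx):
            cx += sx
        elif ady and (not adx or ny_num * adx < nx_num * ady):
            cy += sy
        else:  # exact corner crossing: step diagonally, side cells grazed only
            cx += sx
            cy += sy
        if (cx, cy) == (bx, by):
            return out
        out.append((cx, cy))


def line_of_sight(world: World, from_cell: tuple[int, int],
                  to_cell: tuple[int, int]) -> bool:
    """True iff sight from ``from_cell`` to ``to_cell`` is blocked by an
    opaque cell strictly between the two cell centres."""
    for (x, y) in cells_between(from_cell, to_cell):
        if world.in_grid(x, y) and int(world.cells[y, x]) in _BLOCKING:
            return True
    return False


def ego_view(world: World, state: AgentState, horizon: int,
             show_reward: bool = False) -> EgoView:
    """The agent's occluded egocentric observation window.

    By default the reward cell renders as EMPTY (invisible), forcing
    reward localisation through the allocentric pathway; ``show_reward``
    labels it REWARD instead when visible.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    H = horizon
    fdx, fdy = DIR_DX[state.d], DIR_DY[state.d]
    rd = (state.d + 1) % 4
    rdx, rdy = DIR_DX[rd], DIR_DY[rd]
    px = np.empty((H + 1, 2 * H + 1), dtype=np.int8)
    for k in range(H + 1):
        for c in range(2 * H + 1):
            lat = c - H
            wx = state.x + k * fdx + lat * rdx
            wy = state.y + k * fdy + lat * rdy
            if not world.in_grid(wx, wy):
                px[k, c] = OUTSIDE
            elif (wx, wy) != (state.x, state.y) and line_of_sight(
                    world, (state.x, state.y), (wx, wy)):
                px[k, c] = OCCLUDED
            elif show_reward and (wx, wy) == world.reward_cell:
                px[k, c] = REWARD
            else:
                px[k, c] = world.cells[wy, wx]
    return EgoView(pixels=px, horizon=H)


# ---------------------------------------------------------------------------
# connectivity


def reachable_set(world: World, start_cell: tuple[int, int]) -> set[tuple[int, int]]:
    """Breadth-first closure of 4-neighbour moves through traversable cells."""
    if not world.is_traversable(*start_cell):
        raise ValueError(f"start cell {start_cell} is not traversable")
    seen = {start_cell}
    q = deque([start_cell])
    while q:
        x, y = q.popleft()
        for d in range(4):
            nx, ny = x + DIR_DX[d], y + DIR_DY[d]
            if (nx, ny) not in seen and world.is_traversable(nx, ny):
                seen.add((nx, ny))
                q.append((nx, ny))
    return seen
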