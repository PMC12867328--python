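"""Generative models for navigation tasks.

A *task* is an ordered sequence of worlds (default five) that the agent
experiences one after another, with the reward alternating between the
top-right and bottom-right interior corners.  Four barrier paradigms
stamp U-shaped barriers of varying size/orientation into an empty walled
world; a fifth scatters single-cell obstacles until a target density is
reached while preserving full connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .grid import (BARRIER, EMPTY, NORTH, EAST, SOUTH, WEST, Barrier, World,
                   reachable_set)


class Paradigm(str, Enum):
    """Families of world generators.

    MAIN
        Fixed-size U barriers; in the first world all barriers share one
        orientation (opening away from the reward corner's side), in later
        worlds each barrier is oriented at random.
    ALIGNED_FIXED
        Fixed-size barriers, aligned to obstruct reward access in every world.
    ALIGNED_VARSIZE
        As ALIGNED_FIXED, with per-barrier outer sizes sampled from a range.
    RANDOM_ORIENT_VARSIZE
        Varied sizes and uniformly random per-barrier orientation.
    FULLY_RANDOM
        Unstructured single-cell obstacles at a target density, constrained
        to keep all free space connected and the reward reachable.
    """

    MAIN = "MAIN"
    ALIGNED_FIXED = "ALIGNED_FIXED"
    ALIGNED_VARSIZE = "ALIGNED_VARSIZE"
    RANDOM_ORIENT_VARSIZE = "RANDOM_ORIENT_VARSIZE"
    FULLY_RANDOM = "FULLY_RANDOM"


@dataclass
class GeneratorParams:
    paradigm: Paradigm = Paradigm.MAIN
    width: int = 20
    height: int = 20
    barrier_size: int = 4            # outer size of the U (square)
    barrier_size_range: tuple[int, int] = (3, 6)  # for *_VARSIZE paradigms
    attempts: int = 20               # independent placement attempts per world
    buffer: int = 1                  # clear ring required around a barrier
    density: float = 0.2             # obstacle fraction (FULLY_RANDOM only)
    n_worlds: int = 5
    first_reward_corner: str = "TR"  # "TR" or "BR"
    max_rejections: int = 1000       # FULLY_RANDOM stall guard

    def __post_init__(self):
        if isinstance(self.paradigm, str):
            self.paradigm = Paradigm(self.paradigm)
        if not 0.0 <= self.density < 1.0:
            raise ValueError("density must be in [0, 1)")
        if self.attempts < 0:
            raise ValueError("attempts must be >= 0")
        lo, hi = self.barrier_size_range
        if lo < 3 or hi < lo:
            raise ValueError("barrier sizes must be >= 3 and range ordered")


@dataclass
class Task:
    """A sequence of worlds run back-to-back without resetting the agent."""

    worlds: list[World]
    episodes_per_world: int = 1000
    params: GeneratorParams | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.worlds)


def reward_corner_cell(world_shape: tuple[int, int], corner: str) -> tuple[int, int]:
    """Interior corner cell for a named corner ('TR', 'BR', 'TL', 'BL')."""
    w, h = world_shape
    x = w - 2 if corner[1] == "R" else 1
    y = 1 if corner[0] == "T" else h - 2
    return (x, y)


def _obstructing_opening(reward_cell: tuple[int, int], world: World) -> int:
    """Opening that faces away from the reward corner's (vertical) side, so
    a barrier traps agents travelling towards the reward."""
    return SOUTH if reward_cell[1] <= world.height // 2 else NORTH


def _u_cells(x: int, y: int, w: int, h: int, opening: int):
    """(barrier cells, cavity cells) of a U with outer box (x, y, w, h)."""
    box = {(x + i, y + j) for j in range(h) for i in range(w)}
    if opening == NORTH:
        cavity = {(cx, cy) for (cx, cy) in box
                  if x < cx < x + w - 1 and cy < y + h - 1}
    elif opening == SOUTH:
        cavity = {(cx, cy) for (cx, cy) in box
                  if x < cx < x + w - 1 and cy > y}
    elif opening == WEST:
        cavity = {(cx, cy) for (cx, cy) in box
                  if y < cy < y + h - 1 and cx < x + w - 1}
    elif opening == EAST:
        cavity = {(cx, cy) for (cx, cy) in box
                  if y < cy < y + h - 1 and cx > x}
    else:
        raise ValueError(f"invalid opening {opening}")
    return box - cavity, cavity


def place_u_barrier(world: World, anchor: tuple[int, int], size: tuple[int, int],
                    opening: int, buffer: int = 1) -> bool:
    """Try to stamp a U-shaped barrier with its outer top-left at ``anchor``.

    The placement succeeds only if the outer footprint plus a ``buffer``-wide
    ring overlaps nothing: no wall, no other barrier's footprint, and not the
    reward cell.  On failure the world is unchanged.
    """
    x, y = anchor
    w, h = size
    if w < 3 or h < 2 or w > world.width - 2 or h > world.height - 2:
        raise ValueError(f"barrier size {size} does not fit the interior")
    # expanded box (footprint + buffer) must stay inside the interior
    if (x - buffer < 1 or y - buffer < 1
            or x + w - 1 + buffer > world.width - 2
            or y + h - 1 + buffer > world.height - 2):
        return False
    ex0, ey0 = x - buffer, y - buffer
    ex1, ey1 = x + w - 1 + buffer, y + h - 1 + buffer
    patch = world.cells[ey0:ey1 + 1, ex0:ex1 + 1]
    if np.any(patch != EMPTY):
        return False
    rx, ry = world.reward_cell
    if ex0 <= rx <= ex1 and ey0 <= ry <= ey1:
        return False
    # existing cavities are EMPTY but must not be overlapped either
    if world.cavity_cells and any(ex0 <= cx <= ex1 and ey0 <= cy <= ey1
                                  for (cx, cy) in world.cavity_cells):
        return False
    walls, cavity = _u_cells(x, y, w, h, opening)
    for (cx, cy) in walls:
        world.cells[cy, cx] = BARRIER
    world.barriers.append(Barrier(x, y, w, h, opening))
    world.cavity_cells |= cavity
    return True


def _sample_size(params: GeneratorParams, rng: np.random.Generator) -> int:
    if params.paradigm in (Paradigm.ALIGNED_VARSIZE, Paradigm.RANDOM_ORIENT_VARSIZE):
        lo, hi = params.barrier_size_range
        return int(rng.integers(lo, hi + 1))
    return params.barrier_size


def generate_barrier_world(params: GeneratorParams, reward_corner: str,
                           rng: np.random.Generator,
                           aligned_override: bool | None = None) -> World:
    """One barrier world: ``params.attempts`` independent placement tries.

    ``aligned_override`` forces shared (True) or random (False) orientation
    regardless of paradigm; used by :func:`generate_task` for the MAIN
    paradigm's first-world constraint.
    """
    world = World.empty(params.width, params.height,
                        reward_corner_cell((params.width, params.height),
                                           reward_corner))
    aligned = params.paradigm in (Paradigm.ALIGNED_FIXED, Paradigm.ALIGNED_VARSIZE)
    if aligned_override is not None:
        aligned = aligned_override
    shared_opening = _obstructing_opening(world.reward_cell, world)
    for _ in range(params.attempts):
        s = _sample_size(params, rng)
        # anchor anywhere the outer box fits in the interior; the buffer
        # check inside place_u_barrier rejects wall-adjacent placements
        xmax, ymax = world.width - 1 - s, world.height - 1 - s
        if xmax < 1 or ymax < 1:
            continue
        anchor = (int(rng.integers(1, xmax + 1)), int(rng.integers(1, ymax + 1)))
        opening = shared_opening if aligned else int(rng.integers(0, 4))
        place_u_barrier(world, anchor, (s, s), opening, params.buffer)
    _assert_connected(world)
    world.meta.update(paradigm=params.paradigm.value, reward_corner=reward_corner,
                      n_barriers=len(world.barriers))
    return world


def generate_random_world(params: GeneratorParams, reward_corner: str,
                          rng: np.random.Generator) -> World:
    """Unstructured world: single-cell obstacles scattered one at a time.

    Each candidate obstacle is kept only if, afterwards, breadth-first
    search from the corner opposite the reward still reaches every
    non-obstacle interior cell (so free space stays connected and the
    reward reachable).  Stops at the first state with obstacle density
    >= ``params.density``.
    """
    world = World.empty(params.width, params.height,
                        reward_corner_cell((params.width, params.height),
                                           reward_corner))
    rx, ry = world.reward_cell
    opposite = (world.width - 1 - rx, world.height - 1 - ry)
    interior_n = world.interior_size()
    n_obstacles = 0
    rejections = 0
    while n_obstacles / interior_n < params.density:
        free = [c for c in world.traversable_cells()
                if c != world.reward_cell and c != opposite]
        cand = free[int(rng.integers(len(free)))]
        world.cells[cand[1], cand[0]] = BARRIER
        if reachable_set(world, opposite) == set(world.traversable_cells()):
            n_obstacles += 1
            rejections = 0
        else:
            world.cells[cand[1], cand[0]] = EMPTY
            rejections += 1
            if rejections > params.max_rejections:
                raise RuntimeError(
                    f"random-world generation stalled after {rejections} "
                    f"consecutive rejections (density {n_obstacles / interior_n:.3f})")
    world.meta.update(paradigm=params.paradigm.value, reward_corner=reward_corner,
                      n_obstacles=n_obstacles)
    return world


def generate_task(params: GeneratorParams, rng: np.random.Generator,
                  episodes_per_world: int = 1000) -> Task:
    """Mint a full task: ``n_worlds`` worlds with alternating reward corners."""
    corners = ["TR", "BR"] if params.first_reward_corner == "TR" else ["BR", "TR"]
    worlds = []
    for i in range(params.n_worlds):
        corner = corners[i % 2]
        if params.paradigm is Paradigm.FULLY_RANDOM:
            w = generate_random_world(params, corner, rng)
        elif params.paradigm is Paradigm.MAIN:
            w = generate_barrier_world(params, corner, rng,
                                       aligned_override=(i == 0))
        else:
            w = generate_barrier_world(params, corner, rng)
        w.meta["world_index"] = i
        worlds.append(w)
    return Task(worlds=worlds, episodes_per_world=episodes_per_world, params=params)


def _assert_connected(world: World) -> None:
    """Safety check: free space connected and reward reachable (with a
    one-cell buffer U barriers cannot disconnect space, but cheap to verify)."""
    reach = reachable_set(world, world.reward_cell)
    if reach != set(world.traversable_cells()):
        raise AssertionError("generated world has disconnected free space")
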