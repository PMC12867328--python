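"""Gridworld dynamics, views, visibility and the action-frame bijection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnav.grid import (BARRIER, EAST, EMPTY, GO_FORWARD, NORTH, OCCLUDED,
                        OUTSIDE, SOUTH, TURN_180, TURN_CCW_90, TURN_CW_90,
                        WALL_N, WEST, AgentState, World, cells_between,
                        ego_view, inverse_rotate_action, line_of_sight,
                        reachable_set, rotate_action, step)


class TestActionRotation:
    def test_north_while_facing_east_is_ccw_turn(self):
        assert rotate_action(EAST, NORTH) == TURN_CCW_90

    def test_north_while_facing_north_is_go_forward(self):
        assert rotate_action(NORTH, NORTH) == GO_FORWARD

    @pytest.mark.parametrize("d", range(4))
    def test_bijection_round_trip(self, d):
        ego = [rotate_action(d, a) for a in range(4)]
        assert sorted(ego) == [0, 1, 2, 3]
        for a in range(4):
            assert inverse_rotate_action(d, rotate_action(d, a)) == a

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            rotate_action(4, 0)
        with pytest.raises(ValueError):
            inverse_rotate_action(0, -1)


class TestStep:
    def test_turns_change_only_heading(self, empty_world):
        s = AgentState(5, 5, NORTH)
        for a, d_new in [(TURN_CW_90, EAST), (TURN_180, SOUTH),
                         (TURN_CCW_90, WEST)]:
            nxt, r, done = step(empty_world, s, a)
            assert (nxt.x, nxt.y, nxt.d) == (5, 5, d_new)
            assert r == 0 and not done

    def test_blocked_forward_is_noop(self, empty_world):
        s = AgentState(5, 1, NORTH)  # wall directly ahead
        nxt, r, done = step(empty_world, s, GO_FORWARD)
        assert (nxt.x, nxt.y, nxt.d) == (5, 1, NORTH)
        assert r == 0 and not done

    def test_forward_moves_and_reward_terminates(self, empty_world):
        rx, ry = empty_world.reward_cell
        s = AgentState(rx, ry + 1, NORTH)
        nxt, r, done = step(empty_world, s, GO_FORWARD)
        assert (nxt.x, nxt.y) == (rx, ry)
        assert r == 1.0 and done

    def test_forward_never_changes_heading(self, small_world):
        for (x, y) in small_world.traversable_cells():
            for d in range(4):
                nxt, _, _ = step(small_world, AgentState(x, y, d), GO_FORWARD)
                assert nxt.d == d

    def test_invalid_action_raises(self, empty_world):
        with pytest.raises(ValueError):
            step(empty_world, AgentState(5, 5, 0), 4)

    def test_state_on_barrier_raises(self, small_world):
        with pytest.raises(ValueError):
            step(small_world, AgentState(3, 4, 0), 0)


def _sampling_los_oracle(world, a, b, n=4097):
    """Dense-sampling oracle: walk the open segment between cell centres and
    collect every cell whose interior a sample point falls in."""
    ax, ay = a[0] + 0.5, a[1] + 0.5
    bx, by = b[0] + 0.5, b[1] + 0.5
    hit = set()
    for i in range(1, n):
        t = (i + 0.381966) / (n + 1)  # avoid exact corner hits
        x, y = ax + t * (bx - ax), ay + t * (by - ay)
        if x != int(x) and y != int(y):
            hit.add((int(x), int(y)))
    hit -= {tuple(a), tuple(b)}
    return any(world.in_grid(x, y) and int(world.cells[y, x]) != EMPTY
               for (x, y) in hit)


class TestLineOfSight:
    def test_same_and_adjacent_cells_unblocked(self, small_world):
        assert not line_of_sight(small_world, (2, 2), (2, 2))
        assert not line_of_sight(small_world, (2, 2), (3, 2))
        assert not line_of_sight(small_world, (2, 2), (3, 3))

    def test_barrier_mid_ray_blocks(self, small_world):
        # barrier at (3, 4): the ray (1,4) -> (5,4) passes through it
        assert line_of_sight(small_world, (1, 4), (5, 4))
        assert line_of_sight(small_world, (5, 4), (1, 4))

    def test_matches_dense_sampling_oracle_exhaustively(self, small_world):
        cells = small_world.interior_cells()
        for a in cells[::3]:
            for b in cells[::2]:
                assert line_of_sight(small_world, a, b) == \
                    _sampling_los_oracle(small_world, a, b), (a, b)

    def test_corner_grazing_does_not_block(self):
        # the diagonal (2,1)->(4,3) passes exactly through the shared corner
        # of (3,1)/(2,2)/(3,2)/(2,1): only (3,2) is crossed through its
        # interior, the two side cells are merely grazed
        assert cells_between((2, 1), (4, 3)) == [(3, 2)]
        w = World.empty(8, 8, reward_cell=(6, 1))
        w.cells[1, 3] = BARRIER  # (3,1), grazed only
        assert not line_of_sight(w, (2, 1), (4, 3))
        w.cells[2, 3] = BARRIER  # (3,2), crossed
        assert line_of_sight(w, (2, 1), (4, 3))

    @given(st.integers(-6, 6), st.integers(-6, 6))
    @settings(max_examples=60, deadline=None)
    def test_cells_between_symmetric_and_excludes_endpoints(self, dx, dy):
        a, b = (10, 10), (10 + dx, 10 + dy)
        cells = cells_between(a, b)
        assert a not in cells and b not in cells
        assert set(cells) == set(cells_between(b, a))


class TestEgoView:
    def test_all_empty_at_centre(self, empty_world):
        v = ego_view(empty_world, AgentState(10, 10, NORTH), 2)
        assert v.pixels.shape == (3, 5)
        assert np.all(v.pixels == EMPTY)

    def test_far_row_is_wall_when_facing_boundary(self, empty_world):
        # two cells from the north boundary, facing it, H=2: the farthest
        # front row is exactly the wall
        v = ego_view(empty_world, AgentState(10, 2, NORTH), 2)
        assert np.all(v.pixels[1] == EMPTY)
        assert np.all(v.pixels[2] == WALL_N)
        # directly adjacent: near wall cells occlude the diagonal ones and
        # the row beyond the wall is outside the grid
        v = ego_view(empty_world, AgentState(10, 1, NORTH), 2)
        assert np.all(v.pixels[1, 1:4] == WALL_N)
        assert np.all(v.pixels[1, [0, 4]] == OCCLUDED)
        assert np.all(v.pixels[2] == OUTSIDE)

    def test_occlusion_behind_barrier(self, small_world):
        # facing north from (3, 6): barrier at (3, 4) is 2 ahead; the cell
        # behind it is outside horizon 2, so look with H=3
        v = ego_view(small_world, AgentState(3, 6, NORTH), 3)
        assert v.pixels[2, 3] == BARRIER
        assert v.pixels[3, 3] == OCCLUDED

    def test_agent_cell_is_empty(self, small_world):
        for (x, y) in small_world.traversable_cells():
            for d in range(4):
                v = ego_view(small_world, AgentState(x, y, d), 2)
                assert v.pixels[0, 2] == EMPTY

    def test_rotational_equivariance(self):
        # a barrier 2 cells ahead looks identical for any heading
        views = []
        offs = {NORTH: (0, -2), EAST: (2, 0), SOUTH: (0, 2), WEST: (-2, 0)}
        for d, (ox, oy) in offs.items():
            w = World.empty(12, 12, reward_cell=(10, 1))
            w.cells[6 + oy, 6 + ox] = BARRIER
            views.append(ego_view(w, AgentState(6, 6, d), 2).pixels)
        for v in views[1:]:
            assert np.array_equal(views[0], v)

    def test_occlusion_monotone_along_ray(self, small_world):
        # every straight-ahead ray: once occluded, farther stays occluded
        H = 4
        for (x, y) in small_world.traversable_cells():
            for d in range(4):
                col = ego_view(small_world, AgentState(x, y, d), H).pixels[:, H]
                seen_occ = False
                for k in range(H + 1):
                    if col[k] == OCCLUDED:
                        seen_occ = True
                    elif seen_occ and col[k] not in (OUTSIDE,):
                        # a visible in-grid cell after an occluded one on the
                        # same ray would violate monotonicity
                        raise AssertionError((x, y, d, col))


def _flood_fill(world, start):
    seen = set()

    def rec(c):
        if c in seen or not world.is_traversable(*c):
            return
        seen.add(c)
        for dx, dy in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            rec((c[0] + dx, c[1] + dy))

    rec(start)
    return seen


class TestReachableSet:
    def test_empty_interior_fully_reachable(self, empty_world):
        assert len(reachable_set(empty_world, (1, 1))) == 18 * 18

    def test_bisecting_wall_splits_components(self):
        w = World.empty(10, 10, reward_cell=(8, 1))
        w.cells[1:9, 4] = BARRIER
        left = reachable_set(w, (1, 1))
        assert all(x < 4 for (x, y) in left)
        assert len(left) == 3 * 8

    def test_matches_recursive_flood_fill_on_random_small_worlds(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            w = World.empty(8, 8, reward_cell=(6, 6))
            for _ in range(8):
                x, y = int(rng.integers(1, 7)), int(rng.integers(1, 7))
                if (x, y) not in ((1, 1), (6, 6)):
                    w.cells[y, x] = BARRIER
            starts = [c for c in w.traversable_cells()]
            s = starts[int(rng.integers(len(starts)))]
            assert reachable_set(w, s) == _flood_fill(w, s)

    def test_untraversable_start_raises(self, small_world):
        with pytest.raises(ValueError):
            reachable_set(small_world, (0, 0))


class TestSerialisation:
    def test_round_trip_exact(self, main_task):
        for w in main_task.worlds:
            w2 = World.from_json(w.to_json())
            assert np.array_equal(w.cells, w2.cells)
            assert w2.reward_cell == w.reward_cell
            assert w2.cavity_cells == w.cavity_cells
            assert w2.to_json() == w.to_json()

    def test_reward_marked_in_grid_chars(self, empty_world):
        d = empty_world.to_dict()
        rx, ry = empty_world.reward_cell
        assert d["grid"][ry][rx] == "R"
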