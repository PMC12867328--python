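"""Composite agent: features, Q-values, selection, ADAM, learning loop."""

from collections import deque

import numpy as np
import pytest

from srnav.agent import (Lesion, PolicyParams, QModel, _adam_step,
                         adam_q_update, agent_act_and_learn, feature_vector,
                         q_values, select_action, softmax_probabilities)
from srnav.config import AgentConfig
from srnav.grid import (DIR_DX, DIR_DY, EAST, GO_FORWARD, NORTH, TURN_CCW_90,
                        AgentState, World, step)
from srnav.runner import make_bundle, prepare_task, run_episode
from srnav.sr import SRSet
from srnav.worldgen import GeneratorParams, Task, generate_task


def _toy_sr(n_allo=6, n_ego=4, seed=0):
    rng = np.random.default_rng(seed)
    sr = SRSet(M_s_A=rng.random((n_allo, n_allo)),
               M_A=rng.random((4, n_allo, n_allo)),
               M_s_E=rng.random((n_ego, n_ego)),
               M_E=rng.random((4, n_ego, n_ego)),
               gamma_A=0.95, gamma_E=0.9, alpha_A=0.05, alpha_E=0.05)
    return sr


class TestFeatureVector:
    def test_zero_sr_gives_zero_vector(self):
        sr = _toy_sr()
        sr.M_A[:] = 0
        sr.M_E[:] = 0
        f = feature_vector(sr, 0, 0, 0, 0, Lesion.FULL)
        assert f.shape == (10,)
        assert np.all(f == 0)

    def test_allo_only_zeroes_ego_block(self):
        sr = _toy_sr()
        f = feature_vector(sr, 1, 2, 0, 1, Lesion.ALLO_ONLY)
        assert np.all(f[6:] == 0)
        assert np.any(f[:6] != 0)

    def test_facing_east_ccw_turn_reads_north_row(self):
        sr = _toy_sr()
        f = feature_vector(sr, 3, 1, EAST, TURN_CCW_90, Lesion.FULL)
        np.testing.assert_array_equal(f[:6], sr.M_A[NORTH, 3])

    def test_ego_qlearner_uses_onehot(self):
        sr = _toy_sr()
        f = feature_vector(sr, 0, 2, 0, 1, Lesion.EGO_QLEARNER)
        np.testing.assert_array_equal(f[6:], [0, 0, 1, 0])


class TestQValues:
    def test_zero_weights_zero_q(self):
        sr = _toy_sr()
        model = QModel.zeros(6, 4)
        assert np.all(q_values(model, sr, 0, 0, 0) == 0)

    def test_onehot_weight_reads_sr_entry(self):
        sr = _toy_sr()
        model = QModel.zeros(6, 4)
        j = 2
        model.w_A[j] = 1.0
        for d in range(4):
            q = q_values(model, sr, 1, 0, d)
            for a in range(4):
                assert q[a] == pytest.approx(sr.M_A[(d + a) % 4, 1, j])

    def test_matches_feature_dot_product(self):
        sr = _toy_sr(seed=3)
        rng = np.random.default_rng(4)
        model = QModel.zeros(6, 4)
        model.w_A[:] = rng.standard_normal(6)
        model.w_E[:] = rng.standard_normal(4)
        for lesion in Lesion:
            model.lesion = lesion
            q = q_values(model, sr, 2, 3, 1)
            for a in range(4):
                f = feature_vector(sr, 2, 3, 1, a, lesion)
                w = np.concatenate([model.w_A, model.w_E])
                assert q[a] == pytest.approx(f @ w, abs=1e-12)

    def test_dimension_mismatch_raises(self):
        sr = _toy_sr()
        model = QModel.zeros(5, 4)
        with pytest.raises(ValueError):
            q_values(model, sr, 0, 0, 0)


class TestSelectAction:
    def test_uniform_when_epsilon_one(self):
        rng = np.random.RandomState(0)
        pol = PolicyParams(epsilon=1.0, tau=0.1)
        q = np.array([5.0, 0.0, 0.0, 0.0])
        counts = np.bincount([select_action(q, pol, rng)
                              for _ in range(10000)], minlength=4)
        np.testing.assert_allclose(counts / 10000, 0.25, atol=0.02)

    def test_greedy_in_low_temperature_limit(self):
        rng = np.random.RandomState(1)
        pol = PolicyParams(epsilon=0.0, tau=1e-9)
        q = np.array([0.1, 0.3, 0.2, 0.0])
        assert all(select_action(q, pol, rng) == 1 for _ in range(100))

    def test_equal_q_gives_exact_quarter_probabilities(self):
        p = softmax_probabilities(np.zeros(4), 0.5)
        np.testing.assert_array_equal(p, 0.25)

    def test_nonfinite_q_rejected(self):
        with pytest.raises(ValueError):
            select_action(np.array([np.nan, 0, 0, 0]),
                          PolicyParams(), np.random.RandomState(0))


class TestAdam:
    def test_first_step_bias_correction(self):
        # single nonzero gradient coordinate: m-hat = g, v-hat = g^2, so the
        # step is eta * g / (|g| + eps)
        w = np.zeros(3)
        m = np.zeros(3)
        v = np.zeros(3)
        g = np.array([0.0, -0.4, 0.0])
        _adam_step(w, m, v, g, t=1, eta=0.1, b1=0.9, b2=0.999, eps=1e-8,
                   no_sqrt=False)
        assert w[1] == pytest.approx(0.1 * (-0.4) / (0.4 + 1e-8))
        assert w[0] == 0 and w[2] == 0

    def test_zero_gradient_keeps_weights_but_counts_step(self):
        sr = _toy_sr()
        model = QModel.zeros(6, 4)
        before = model.w_A.copy()
        # reward 0 and all-zero weights: TD error 0
        delta = adam_q_update(model, sr, 0, 0, 0, 1, 0.0, 1, 1, 1, False)
        assert delta == 0.0
        np.testing.assert_array_equal(model.w_A, before)
        assert model.t == 1

    def test_no_sqrt_variant_guards_zero_second_moment(self):
        w = np.zeros(2)
        _adam_step(w, np.zeros(2), np.zeros(2), np.zeros(2), t=1, eta=0.1,
                   b1=0.9, b2=0.999, eps=1e-8, no_sqrt=True)
        assert np.all(np.isfinite(w))

    def test_bitwise_determinism_of_learning(self):
        task = Task(worlds=[World.empty(10, 10)], episodes_per_world=3)
        cfg = AgentConfig()
        trajs = []
        for _ in range(2):
            prep = prepare_task(task, cfg)
            bundle = make_bundle(prep, cfg, Lesion.FULL)
            pol = PolicyParams(cfg.epsilon, cfg.tau)
            for ep in range(3):
                run_episode(bundle, 0, start_u=5 * 4, ep_seed=123 + ep,
                            policy=pol, cap=500)
            trajs.append((bundle.model.w_A.copy(), bundle.model.w_E.copy()))
        np.testing.assert_array_equal(trajs[0][0], trajs[1][0])
        np.testing.assert_array_equal(trajs[0][1], trajs[1][1])


def _pose_distances(world: World):
    """BFS over (cell, heading) poses under the 4 egocentric actions,
    measured in primitive steps to the reward cell."""
    iw = world.width - 2
    rx, ry = world.reward_cell
    goal = (ry - 1) * iw + (rx - 1)
    dist = {}
    q = deque()
    for d in range(4):
        dist[(goal, d)] = 0
        q.append((goal, d))
    # reverse search: predecessors under deterministic dynamics
    preds = {}
    for (x, y) in world.traversable_cells():
        c = (y - 1) * iw + (x - 1)
        for d in range(4):
            for a in range(4):
                if a == GO_FORWARD:
                    nx, ny = x + DIR_DX[d], y + DIR_DY[d]
                    if not world.is_traversable(nx, ny):
                        nx, ny = x, y
                    nxt = ((ny - 1) * iw + (nx - 1), d)
                else:
                    nxt = (c, (d + a) % 4)
                preds.setdefault(nxt, []).append((c, d))
    while q:
        node = q.popleft()
        for p in preds.get(node, []):
            if p not in dist:
                dist[p] = dist[node] + 1
                q.append(p)
    return dist


class TestGreedyRollout:
    def test_oracle_q_reaches_reward_in_manhattan_counted_steps(self):
        """With Q frozen at negative true pose distance, the greedy policy
        reaches the reward using exactly the Manhattan number of forward
        moves on an empty world."""
        world = World.empty(12, 12, reward_cell=(10, 1))
        dist = _pose_distances(world)
        iw = world.width - 2
        pol = PolicyParams(epsilon=0.0, tau=1e-9)
        rng = np.random.RandomState(0)
        for (sx, sy, sd) in [(1, 10, NORTH), (5, 5, EAST), (10, 10, 2)]:
            state = AgentState(sx, sy, sd)
            counted = 0
            for _ in range(500):
                qs = []
                for a in range(4):
                    nxt, _, _ = step(world, state, a)
                    c2 = (nxt.y - 1) * iw + (nxt.x - 1)
                    qs.append(-1.0 - dist.get((c2, nxt.d), 1e9))
                a = select_action(np.array(qs), pol, rng)
                state, r, done = step(world, state, a)
                counted += (a == GO_FORWARD)
                if done:
                    break
            assert done
            rx, ry = world.reward_cell
            assert counted == abs(sx - rx) + abs(sy - ry)


class TestKernelEquivalence:
    @pytest.mark.parametrize("lesion", list(Lesion))
    def test_kernel_replays_pure_path(self, lesion):
        """The compiled episode loop and the composable reference functions
        must produce the same trajectory and (near-bitwise) identical
        learned tables from a shared seed."""
        params = GeneratorParams(n_worlds=2)
        task = generate_task(params, np.random.default_rng(11),
                             episodes_per_world=2)
        cfg = AgentConfig()
        pol = PolicyParams(cfg.epsilon, cfg.tau)
        need_ego = lesion.uses_ego_sr
        results = {}
        for use_kernel in (True, False):
            prep = prepare_task(task, cfg, need_ego_sr=need_ego)
            bundle = make_bundle(prep, cfg, lesion)
            recs = []
            for wi in range(2):
                for ep in range(2):
                    start_u = int(prep.tables[wi].free_poses[30 + 7 * ep])
                    recs.append(run_episode(
                        bundle, wi, start_u=start_u, ep_seed=77 + ep,
                        policy=pol, cap=300, use_kernel=use_kernel,
                        record_trajectory=True))
            results[use_kernel] = (bundle, recs)
        bk, rk = results[True]
        bp, rp = results[False]
        for a, b in zip(rk, rp):
            np.testing.assert_array_equal(a.trajectory, b.trajectory)
            np.testing.assert_array_equal(a.actions, b.actions)
            assert a.counted_steps == b.counted_steps
            assert a.hole_steps == b.hole_steps
        np.testing.assert_allclose(bk.model.w_A, bp.model.w_A, atol=1e-12)
        np.testing.assert_allclose(bk.sr.M_s_A, bp.sr.M_s_A, atol=1e-12)
        if lesion.uses_ego_block:
            np.testing.assert_allclose(bk.model.w_E, bp.model.w_E, atol=1e-12)
        if lesion.uses_ego_sr:
            np.testing.assert_allclose(bk.sr.M_E, bp.sr.M_E, atol=1e-12)
        assert bk.model.t == bp.model.t


class TestActAndLearn:
    def test_turn_updates_allocentric_self_transition(self):
        world = World.empty(10, 10)
        task = Task(worlds=[world], episodes_per_world=1)
        cfg = AgentConfig(epsilon=1.0)  # force explored actions via seed
        prep = prepare_task(task, cfg)
        bundle = make_bundle(prep, cfg, Lesion.FULL)
        state = AgentState(4, 4, NORTH)
        iw = 8
        c = (state.y - 1) * iw + (state.x - 1)
        before = bundle.sr.M_s_A[c].copy()
        rng = np.random.RandomState(0)
        # find a seed whose first action is a turn
        nxt, rec = agent_act_and_learn(bundle.model, bundle.sr, world, state,
                                       PolicyParams(1.0, 0.01), rng, 2)
        while rec.action == GO_FORWARD:
            state = nxt
            c = (state.y - 1) * iw + (state.x - 1)
            before = bundle.sr.M_s_A[c].copy()
            nxt, rec = agent_act_and_learn(bundle.model, bundle.sr, world,
                                           state, PolicyParams(1.0, 0.01),
                                           rng, 2)
        # turn: allocentric self-transition, row moved toward onehot(c)
        after = bundle.sr.M_s_A[c]
        expect = before + 0.05 * (0.95 * before - before)
        expect[c] += 0.05
        np.testing.assert_allclose(after, expect, atol=1e-12)

    def test_corridor_convergence_to_shortest_path(self):
        """End-to-end: a FULL agent on a 1-D corridor learns the shortest
        path to the reward."""
        world = World.empty(10, 3, reward_cell=(8, 1))
        task = Task(worlds=[world], episodes_per_world=60)
        cfg = AgentConfig()
        prep = prepare_task(task, cfg)
        bundle = make_bundle(prep, cfg, Lesion.FULL)
        pol = PolicyParams(cfg.epsilon, cfg.tau)
        for ep in range(60):
            run_episode(bundle, 0, start_u=0 * 4 + 1, ep_seed=1000 + ep,
                        policy=pol, cap=500)
        # greedy evaluation from the west end facing east: 7 forward moves
        rec = run_episode(bundle, 0, start_u=0 * 4 + 1, ep_seed=9999,
                          policy=PolicyParams(0.0, 1e-9), cap=100)
        assert rec.done
        assert rec.counted_steps == 7
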