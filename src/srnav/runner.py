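"""Episode / task / paradigm orchestration and bookkeeping.

A *run* takes one agent through a task's worlds in order; nothing is
reset at a world switch, so the SR tables, codebook and Q-weights keep
adapting (the continual-learning setting).  Performance is reported as
*counted steps* — go-forward selections only, so that the two-stage
"turn then advance" realisation of allocentric choices is not penalised
— plus occupancy metrics (time inside barrier cavities, near walls, on
current/previous barrier sites).

Comparisons across lesion variants are paired: every variant sees the
bit-identical world sequence, start states and exploration draws for a
given task seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from ._kernel import run_episode_kernel
from .agent import Lesion, PolicyParams, QModel, agent_act_and_learn
from .config import AgentConfig, child_seed
from .grid import AgentState, World
from .sr import (EgoCodebook, SRSet, WorldTables, build_world_tables,
                 init_allocentric_sr, init_egocentric_sr)
from .worldgen import GeneratorParams, Task, generate_task

_DUMMY_MS = np.zeros((1, 1))
_DUMMY_M = np.zeros((4, 1, 1))
_DUMMY_VEC = np.zeros(0)
_DUMMY_I32 = np.zeros(1, dtype=np.int32)


@dataclass
class EpisodeRecord:
    world_index: int
    episode_index: int
    counted_steps: int
    primitive_steps: int
    hole_steps: int
    wall_steps: int
    current_barrier_steps: int
    prev_barrier_steps: tuple[int, ...]  # k worlds back, k = 1..world_index
    done: bool
    truncated: bool
    trajectory: np.ndarray | None = None  # pose ids, when recorded
    actions: np.ndarray | None = None

    @property
    def f_walls(self) -> float:
        return self.wall_steps / self.primitive_steps

    @property
    def f_current(self) -> float:
        return self.current_barrier_steps / self.primitive_steps

    @property
    def f_prev(self) -> tuple[float, ...]:
        return tuple(p / self.primitive_steps for p in self.prev_barrier_steps)


@dataclass
class RunResult:
    lesion: Lesion
    master_seed: int
    records: list[EpisodeRecord]
    n_worlds: int
    episodes_per_world: int
    world_hashes: list[str]
    barrier_pixels: list[int]

    def steps_matrix(self) -> np.ndarray:
        """(n_worlds, episodes_per_world) counted steps."""
        m = np.empty((self.n_worlds, self.episodes_per_world))
        for r in self.records:
            m[r.world_index, r.episode_index] = r.counted_steps
        return m

    def hole_matrix(self) -> np.ndarray:
        m = np.empty((self.n_worlds, self.episodes_per_world))
        for r in self.records:
            m[r.world_index, r.episode_index] = r.hole_steps
        return m

    def mean_steps_per_world(self) -> np.ndarray:
        return self.steps_matrix().mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "seed": self.master_seed, "variant": self.lesion.value,
            "world": r.world_index, "episode": r.episode_index,
            "counted_steps": r.counted_steps,
            "primitive_steps": r.primitive_steps,
            "hole_steps": r.hole_steps, "truncated": r.truncated,
        } for r in self.records])


# ---------------------------------------------------------------------------
# agent preparation


@lru_cache(maxsize=8)
def _allo_init_cached(width: int, height: int, gamma: float):
    M_s, M = init_allocentric_sr(width, height, gamma)
    M_s.setflags(write=False)
    M.setflags(write=False)
    return M_s, M


@dataclass
class PreparedTask:
    """Shared, immutable per-task state: codebook, tables, SR fixed points."""

    task: Task
    horizon: int
    codebook: EgoCodebook
    tables: list[WorldTables]
    M_s_A0: np.ndarray
    M_A0: np.ndarray
    M_s_E0: np.ndarray | None
    M_E0: np.ndarray | None


def prepare_task(task: Task, cfg: AgentConfig, need_ego_sr: bool = True) -> PreparedTask:
    """Enumerate views, tabulate dynamics and compute SR initialisations."""
    w0 = task.worlds[0]
    codebook = EgoCodebook(cfg.horizon)
    tables = [build_world_tables(w, cfg.horizon, codebook) for w in task.worlds]
    codebook.check_capacity()
    M_s_A0, M_A0 = _allo_init_cached(w0.width, w0.height, cfg.gamma_A)
    M_s_E0 = M_E0 = None
    if need_ego_sr:
        init_tables = tables[:1] if cfg.ego_init_single_world else tables
        M_s_E0, M_E0 = init_egocentric_sr(init_tables, cfg.gamma_E,
                                          codebook.n_views)
    return PreparedTask(task=task, horizon=cfg.horizon, codebook=codebook,
                        tables=tables, M_s_A0=M_s_A0, M_A0=M_A0,
                        M_s_E0=M_s_E0, M_E0=M_E0)


@dataclass
class AgentBundle:
    model: QModel
    sr: SRSet
    horizon: int
    prepared: PreparedTask


def make_bundle(prepared: PreparedTask, cfg: AgentConfig,
                lesion: Lesion) -> AgentBundle:
    """A fresh agent on a prepared task (SR tables copied, weights zero)."""
    n_allo = prepared.M_s_A0.shape[0]
    n_ego = prepared.codebook.n_views if lesion.uses_ego_block else 0
    if lesion.uses_ego_sr:
        if prepared.M_s_E0 is None:
            raise ValueError("prepared task lacks the egocentric SR this "
                             "lesion needs")
        M_s_E, M_E = prepared.M_s_E0.copy(), prepared.M_E0.copy()
    else:
        M_s_E = M_E = None
    sr = SRSet(M_s_A=prepared.M_s_A0.copy(), M_A=prepared.M_A0.copy(),
               M_s_E=M_s_E, M_E=M_E, gamma_A=cfg.gamma_A, gamma_E=cfg.gamma_E,
               alpha_A=cfg.alpha_A, alpha_E=cfg.alpha_E,
               codebook=prepared.codebook)
    model = QModel.zeros(n_allo, n_ego, eta=cfg.eta, beta1=cfg.beta1,
                         beta2=cfg.beta2, eps_adam=cfg.eps_adam,
                         gamma_Q=cfg.gamma_Q, adam_no_sqrt=cfg.adam_no_sqrt,
                         lesion=lesion)
    return AgentBundle(model=model, sr=sr, horizon=cfg.horizon,
                       prepared=prepared)


# ---------------------------------------------------------------------------
# episodes


def run_episode(bundle: AgentBundle, world_index: int, start_u: int,
                ep_seed: int, policy: PolicyParams, cap: int,
                prev_masks: np.ndarray | None = None,
                use_kernel: bool = True,
                record_trajectory: bool = False,
                episode_index: int = 0) -> EpisodeRecord:
    """One episode from a given start pose with a given episode seed."""
    wt = bundle.prepared.tables[world_index]
    if prev_masks is None:
        prev_masks = np.zeros((0, wt.n_cells), dtype=bool)
    if use_kernel:
        return _run_episode_fast(bundle, wt, world_index, start_u, ep_seed,
                                 policy, cap, prev_masks, record_trajectory,
                                 episode_index)
    return _run_episode_pure(bundle, wt, world_index, start_u, ep_seed,
                             policy, cap, prev_masks, record_trajectory,
                             episode_index)


def _kernel_args(bundle: AgentBundle):
    model, sr, lesion = bundle.model, bundle.sr, bundle.model.lesion
    M_s_E = sr.M_s_E if sr.M_s_E is not None else _DUMMY_MS
    M_E = sr.M_E if sr.M_E is not None else _DUMMY_M
    return model, sr, lesion, M_s_E, M_E


def _run_episode_fast(bundle, wt, world_index, start_u, ep_seed, policy, cap,
                      prev_masks, record_trajectory, episode_index):
    model, sr, lesion, M_s_E, M_E = _kernel_args(bundle)
    if record_trajectory:
        u_seq = np.zeros(cap, dtype=np.int32)
        a_seq = np.zeros(cap, dtype=np.int32)
    else:
        u_seq = a_seq = _DUMMY_I32
    t_arr = np.array([model.t], dtype=np.int64)
    out = run_episode_kernel(
        ep_seed, start_u, cap,
        wt.view_of_u, wt.next_u, wt.reward_index,
        wt.cavity_mask, wt.wallnear_mask, wt.barrier_mask, prev_masks,
        sr.M_s_A, sr.M_A, M_s_E, M_E,
        model.w_A, model.w_E if model.w_E.size else _DUMMY_VEC,
        model.m_A, model.m_E if model.m_E.size else _DUMMY_VEC,
        model.v_A, model.v_E if model.v_E.size else _DUMMY_VEC, t_arr,
        sr.alpha_A, sr.alpha_E, sr.gamma_A, sr.gamma_E, model.gamma_Q,
        model.eta, model.beta1, model.beta2, model.eps_adam,
        policy.epsilon, policy.tau,
        lesion.uses_allo, lesion.uses_ego_sr, lesion.uses_ego_onehot,
        lesion.uses_adam, model.adam_no_sqrt,
        record_trajectory, u_seq, a_seq)
    primitive, counted, done, hole, wall, curbar, prev_counts, _ = out
    model.t = int(t_arr[0])
    return EpisodeRecord(
        world_index=world_index, episode_index=episode_index,
        counted_steps=int(counted), primitive_steps=int(primitive),
        hole_steps=int(hole), wall_steps=int(wall),
        current_barrier_steps=int(curbar),
        prev_barrier_steps=tuple(int(p) for p in prev_counts),
        done=bool(done), truncated=not bool(done),
        trajectory=u_seq[:primitive].copy() if record_trajectory else None,
        actions=a_seq[:primitive].copy() if record_trajectory else None)


def _run_episode_pure(bundle, wt, world_index, start_u, ep_seed, policy, cap,
                      prev_masks, record_trajectory, episode_index):
    """Reference path: the same episode via the composable agent functions."""
    model, sr = bundle.model, bundle.sr
    world: World = wt.world
    iw = world.width - 2
    rng = np.random.RandomState(ep_seed)
    c, d = divmod(int(start_u), 4)
    y, x = divmod(c, iw)
    state = AgentState(x + 1, y + 1, d)
    counted = hole = wall = curbar = 0
    prev_counts = np.zeros(prev_masks.shape[0], dtype=np.int64)
    u_seq, a_seq = [], []
    done = False
    primitive = 0
    for it in range(cap):
        c = (state.y - 1) * iw + (state.x - 1)
        if wt.cavity_mask[c]:
            hole += 1
        if wt.wallnear_mask[c]:
            wall += 1
        if wt.barrier_mask[c]:
            curbar += 1
        for k in range(prev_masks.shape[0]):
            if prev_masks[k, c]:
                prev_counts[k] += 1
        u_seq.append(c * 4 + state.d)
        state, rec = agent_act_and_learn(model, sr, world, state, policy, rng,
                                         bundle.horizon)
        a_seq.append(rec.action)
        counted += rec.counted
        primitive = it + 1
        if rec.done:
            done = True
            break
    return EpisodeRecord(
        world_index=world_index, episode_index=episode_index,
        counted_steps=counted, primitive_steps=primitive, hole_steps=hole,
        wall_steps=wall, current_barrier_steps=curbar,
        prev_barrier_steps=tuple(int(p) for p in prev_counts),
        done=done, truncated=not done,
        trajectory=np.array(u_seq, dtype=np.int32) if record_trajectory else None,
        actions=np.array(a_seq, dtype=np.int32) if record_trajectory else None)


# ---------------------------------------------------------------------------
# tasks and paradigm comparisons


def sample_start(wt: WorldTables, rng: np.random.Generator) -> int:
    """Uniform over traversable poses excluding the reward cell."""
    return int(wt.free_poses[int(rng.integers(wt.free_poses.shape[0]))])


def _world_hash(world: World) -> str:
    return hashlib.md5(world.to_json().encode()).hexdigest()


def run_task(prepared: PreparedTask, cfg: AgentConfig, lesion: Lesion,
             master_seed: int, episodes_per_world: int | None = None,
             cap: int | None = None, use_kernel: bool = True) -> RunResult:
    """Run one agent through all worlds of a task, carrying all state across
    world switches.  Start poses and episode seeds depend only on
    (master_seed, world, episode), so paired variants see identical draws."""
    task = prepared.task
    episodes = (task.episodes_per_world if episodes_per_world is None
                else episodes_per_world)
    cap = cfg.episode_cap if cap is None else cap
    bundle = make_bundle(prepared, cfg, lesion)
    policy = PolicyParams(epsilon=cfg.epsilon, tau=cfg.tau)
    records: list[EpisodeRecord] = []
    for wi, wt in enumerate(prepared.tables):
        prev_masks = (np.stack([prepared.tables[wi - k].barrier_mask
                                for k in range(1, wi + 1)])
                      if wi else np.zeros((0, wt.n_cells), dtype=bool))
        for ep in range(episodes):
            start_rng = np.random.default_rng(
                np.random.SeedSequence([master_seed, 11, wi, ep]))
            start_u = sample_start(wt, start_rng)
            ep_seed = child_seed(master_seed, "episode", wi, ep)
            records.append(run_episode(
                bundle, wi, start_u, ep_seed, policy, cap,
                prev_masks=prev_masks, use_kernel=use_kernel,
                episode_index=ep))
    return RunResult(
        lesion=lesion, master_seed=master_seed, records=records,
        n_worlds=len(task.worlds), episodes_per_world=episodes,
        world_hashes=[_world_hash(w) for w in task.worlds],
        barrier_pixels=[w.barrier_pixel_count() for w in task.worlds])


@dataclass
class ComparisonResult:
    """Paired multi-seed lesion comparison on a shared task distribution."""

    variants: list[Lesion]
    results: dict[Lesion, list[RunResult]] = field(default_factory=dict)

    def mean_steps_curve(self, lesion: Lesion) -> np.ndarray:
        """Per-episode counted steps, averaged across seeds (flattened over
        worlds in task order)."""
        mats = [r.steps_matrix().ravel() for r in self.results[lesion]]
        return np.mean(mats, axis=0)

    def mean_hole_curve(self, lesion: Lesion) -> np.ndarray:
        mats = [r.hole_matrix().ravel() for r in self.results[lesion]]
        return np.mean(mats, axis=0)

    def step_ratio_histogram(self, num: Lesion, den: Lesion,
                             bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
        """Histogram of per-episode step ratios num/den across seeds."""
        ratios = []
        for rn, rd in zip(self.results[num], self.results[den]):
            n = rn.steps_matrix().ravel()
            d = rd.steps_matrix().ravel()
            ratios.append(n / np.maximum(d, 1.0))
        return np.histogram(np.concatenate(ratios), bins=bins)


def run_paradigm_comparison(params: GeneratorParams, variants: list[Lesion],
                            n_tasks: int, base_seed: int, cfg: AgentConfig,
                            episodes_per_world: int, cap: int | None = None,
                            ) -> ComparisonResult:
    """For each task seed, mint one task and run every variant on it (paired
    design: identical worlds, starts and exploration draws per seed)."""
    out = ComparisonResult(variants=list(variants))
    need_ego = any(v.uses_ego_sr for v in variants)
    for v in variants:
        out.results[v] = []
    for i in range(n_tasks):
        task_seed = child_seed(base_seed, "task", i)
        wg = np.random.default_rng(np.random.SeedSequence([task_seed, 5]))
        task = generate_task(params, wg, episodes_per_world=episodes_per_world)
        prepared = prepare_task(task, cfg, need_ego_sr=need_ego)
        for v in variants:
            out.results[v].append(run_task(prepared, cfg, v, task_seed,
                                           episodes_per_world, cap))
    return out


def horizon_sweep(horizons: list[int], params: GeneratorParams, n_tasks: int,
                  base_seed: int, cfg: AgentConfig, episodes_per_world: int,
                  cap: int | None = None) -> dict[int, ComparisonResult]:
    """FULL vs ALLO_ONLY at several view horizons on shared tasks.

    The allocentric-only agent has no egocentric input, so it is run once
    per task seed and shared across horizon entries (its curves are
    H-invariant by construction).
    """
    out: dict[int, ComparisonResult] = {
        H: ComparisonResult(variants=[Lesion.FULL, Lesion.ALLO_ONLY])
        for H in horizons}
    for H in horizons:
        out[H].results = {Lesion.FULL: [], Lesion.ALLO_ONLY: []}
    for i in range(n_tasks):
        task_seed = child_seed(base_seed, "task", i)
        wg = np.random.default_rng(np.random.SeedSequence([task_seed, 5]))
        task = generate_task(params, wg, episodes_per_world=episodes_per_world)
        allo_cfg = cfg.model_copy(update={"horizon": horizons[0]})
        prepared0 = prepare_task(task, allo_cfg, need_ego_sr=False)
        allo_result = run_task(prepared0, allo_cfg, Lesion.ALLO_ONLY,
                               task_seed, episodes_per_world, cap)
        for H in horizons:
            h_cfg = cfg.model_copy(update={"horizon": H})
            prepared = prepare_task(task, h_cfg, need_ego_sr=True)
            out[H].results[Lesion.FULL].append(
                run_task(prepared, h_cfg, Lesion.FULL, task_seed,
                         episodes_per_world, cap))
            out[H].results[Lesion.ALLO_ONLY].append(allo_result)
    return out


def results_table(comparison: ComparisonResult) -> pd.DataFrame:
    """Tidy per-episode table across variants and seeds."""
    frames = [r.to_dataframe() for v in comparison.variants
              for r in comparison.results[v]]
    return pd.concat(frames, ignore_index=True)
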