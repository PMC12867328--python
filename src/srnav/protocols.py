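"""Scaled study protocols and their summary statistics.

These are the package's standard experiment recipes: a paired lesion
comparison on the main barrier paradigm, the view-horizon sweep, and
simulate-and-refit recovery checks for the two behavioural GLMs.  The
default scale (5-10 task seeds, 5 worlds x 200 episodes, 2,000-step
episode cap) is a deliberately reduced version of the full study
(30 seeds x 1000 episodes) that preserves the qualitative contrasts;
docs/methods.md discusses the choice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .agent import Lesion
from .analysis import fit_barrier_poisson_glm, fit_occupancy_logistic_glm
from .config import AgentConfig
from .runner import ComparisonResult, horizon_sweep, run_paradigm_comparison
from .worldgen import GeneratorParams, Paradigm, generate_barrier_world

FAST_N_TASKS = 5
FAST_EPISODES = 200
FAST_CAP = 2000
POST_SWITCH_WINDOW = 100  # episodes scored after each world switch


def fast_lesion_protocol(base_seed: int, variants: list[Lesion] | None = None,
                         n_tasks: int = FAST_N_TASKS,
                         episodes: int = FAST_EPISODES, cap: int = FAST_CAP,
                         paradigm: Paradigm = Paradigm.MAIN,
                         cfg: AgentConfig | None = None) -> ComparisonResult:
    """Paired multi-variant comparison on the main paradigm at fast scale."""
    if variants is None:
        variants = [Lesion.FULL, Lesion.ALLO_ONLY]
    cfg = cfg or AgentConfig()
    params = GeneratorParams(paradigm=paradigm)
    return run_paradigm_comparison(params, variants, n_tasks, base_seed, cfg,
                                   episodes_per_world=episodes, cap=cap)


# ---------------------------------------------------------------------------
# summary statistics


def post_switch_seed_means(comp: ComparisonResult, lesion: Lesion,
                           first_n: int = POST_SWITCH_WINDOW) -> np.ndarray:
    """Per-seed mean counted steps over the first ``first_n`` episodes after
    each world switch (worlds 2..last), averaged over switches."""
    out = []
    for r in comp.results[lesion]:
        m = r.steps_matrix()
        out.append(np.mean([m[wi, :first_n].mean()
                            for wi in range(1, r.n_worlds)]))
    return np.array(out)


def post_switch_world_means(comp: ComparisonResult, lesion: Lesion,
                            first_n: int = POST_SWITCH_WINDOW) -> np.ndarray:
    """Aggregate (across seeds) mean counted steps per switch."""
    mats = np.stack([r.steps_matrix() for r in comp.results[lesion]])
    return mats[:, 1:, :first_n].mean(axis=(0, 2))


def hole_seed_means(comp: ComparisonResult, lesion: Lesion) -> np.ndarray:
    """Per-seed mean hole time (cavity-cell primitive steps) over worlds 2+."""
    return np.array([r.hole_matrix()[1:].mean() for r in comp.results[lesion]])


def overall_seed_means(comp: ComparisonResult, lesion: Lesion) -> np.ndarray:
    return np.array([r.steps_matrix().mean() for r in comp.results[lesion]])


def sign_test_less(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided paired sign test that a < b (p-value)."""
    n = len(a)
    wins = int(np.sum(a < b))
    return scipy.stats.binomtest(wins, n, 0.5, alternative="greater").pvalue


# ---------------------------------------------------------------------------
# horizon sweep


def horizon_advantage(base_seed: int, horizons: tuple[int, ...] = (2, 3, 4),
                      n_tasks: int = 10, episodes: int = FAST_EPISODES,
                      cap: int = FAST_CAP,
                      cfg: AgentConfig | None = None) -> dict[int, np.ndarray]:
    """Per-seed egocentric advantage (ALLO_ONLY minus FULL mean counted
    steps) at each view horizon, on shared tasks."""
    cfg = cfg or AgentConfig()
    params = GeneratorParams(paradigm=Paradigm.MAIN)
    sweep = horizon_sweep(list(horizons), params, n_tasks, base_seed, cfg,
                          episodes_per_world=episodes, cap=cap)
    out = {}
    for H, comp in sweep.items():
        full = overall_seed_means(comp, Lesion.FULL)
        allo = overall_seed_means(comp, Lesion.ALLO_ONLY)
        out[H] = allo - full
    return out


# ---------------------------------------------------------------------------
# GLM recovery (simulate from the model, refit, compare)


def poisson_recovery(seed: int, n_worlds: int = 200, beta0: float = 3.0,
                     beta1: float = 0.02) -> dict:
    """Simulate per-world mean steps from the barrier-count Poisson model on
    really generated worlds, refit, and report the recovery z-score."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
    params = GeneratorParams(paradigm=Paradigm.RANDOM_ORIENT_VARSIZE)
    corners = ["TR", "BR"]
    x = np.array([generate_barrier_world(params, corners[i % 2], rng)
                  .barrier_pixel_count() for i in range(n_worlds)], float)
    mu = np.exp(beta0 + beta1 * x)
    y = rng.poisson(mu).astype(float)
    fit = fit_barrier_poisson_glm(y, x)
    z = (fit.coef[1] - beta1) / fit.se[1]
    return {"beta1_true": beta1, "beta1_hat": float(fit.coef[1]),
            "se": float(fit.se[1]), "z": float(z)}


def logistic_recovery(seed: int, n_episodes: int = 2000) -> dict:
    """Simulate lesioned-vs-full labels from known occupancy coefficients,
    refit, and report the worst recovery z-score across terms."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 22]))
    beta = np.array([-0.5, 2.0, 3.0, -1.5])  # intercept, walls, current, prev1
    f_walls = rng.uniform(0, 0.8, n_episodes)
    f_current = rng.uniform(0, 0.4, n_episodes)
    f_prev1 = rng.uniform(0, 0.4, n_episodes)
    X = np.column_stack([f_walls, f_current, f_prev1])
    logit = beta[0] + X @ beta[1:]
    y = (rng.random(n_episodes) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    fit = fit_occupancy_logistic_glm(
        pd.DataFrame(X, columns=["f_walls", "f_current", "f_prev1"]), y)
    z = (fit.coef - beta) / fit.se
    worst = float(np.max(np.abs(z)))
    return {"beta": beta.tolist(), "beta_hat": fit.coef.tolist(),
            "se": fit.se.tolist(), "worst_z": worst}
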