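"""Analyses of trained agents: value decomposition, SR visualisation data,
and the two behavioural GLMs.

Because the Q-function is linear in the concatenated two-frame features,
the greedy state value splits *exactly* into an allocentric and an
egocentric contribution; the decomposition here is algebraic, not a fit.
The GLMs relate behaviour to world structure: a Poisson regression of
per-world mean step counts on barrier pixel counts, and a logistic
regression that predicts which agent (lesioned vs full) produced an
episode from its occupancy profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .agent import QModel, q_values
from .runner import EpisodeRecord
from .sr import SRSet, WorldTables

N_ACTIONS = 4


# ---------------------------------------------------------------------------
# value decomposition


@dataclass
class ValueDecomposition:
    """Greedy value and its exact frame-wise split on one world.

    Arrays are indexed ``[y-1, x-1, d]`` over interior cells; inaccessible
    cells are NaN.  ``V = V_a + V_e`` holds to machine precision at every
    accessible pose.
    """

    V: np.ndarray        # (ih, iw, 4)
    V_a: np.ndarray      # allocentric-block contribution at the greedy action
    V_e: np.ndarray      # egocentric-block contribution
    greedy_action: np.ndarray  # (ih, iw, 4) ego action argmax, int

    @property
    def V_mean(self) -> np.ndarray:
        return np.mean(self.V, axis=2)

    @property
    def V_e_mean(self) -> np.ndarray:
        """Head-direction average of the egocentric contribution."""
        return np.mean(self.V_e, axis=2)

    @property
    def V_a_mean(self) -> np.ndarray:
        return np.mean(self.V_a, axis=2)

    @property
    def V_e_residual(self) -> np.ndarray:
        """Direction-dependent egocentric residual (zero-mean over d)."""
        return self.V_e - self.V_e_mean[:, :, None]

    def filled(self, arr: np.ndarray) -> np.ndarray:
        """Inaccessible cells replaced by the mean of accessible ones
        (rendering convention for maps)."""
        out = arr.copy()
        out[np.isnan(out)] = np.nanmean(arr)
        return out


def decompose_value(model: QModel, sr: SRSet, wt: WorldTables) -> ValueDecomposition:
    """Split the greedy value into its two linear contributions.

    Both blocks are read at the total-Q argmax action (ties broken by fixed
    action order), which keeps the split exact.
    """
    if model.w_A.size == 0 and model.w_E.size == 0:
        raise ValueError("model has no trained weights")
    world = wt.world
    iw, ih = world.width - 2, world.height - 2
    V = np.full((ih, iw, 4), np.nan)
    V_a = np.full((ih, iw, 4), np.nan)
    V_e = np.full((ih, iw, 4), np.nan)
    greedy = np.full((ih, iw, 4), -1, dtype=np.int64)
    lesion = model.lesion
    for (x, y) in world.traversable_cells():
        c = (y - 1) * iw + (x - 1)
        for d in range(4):
            s_E = int(wt.view_of_u[c * 4 + d]) if lesion.uses_ego_block else 0
            q = q_values(model, sr, c, s_E, d)
            a = int(np.argmax(q))
            va = 0.0
            if lesion.uses_allo:
                va = float(sr.M_A[(d + a) % 4, c] @ model.w_A)
            if lesion.uses_ego_sr:
                ve = float(sr.M_E[a, s_E] @ model.w_E)
            elif lesion.uses_ego_onehot:
                ve = float(model.w_E[s_E])
            else:
                ve = 0.0
            # V is defined as the sum of the two block contributions at the
            # greedy action, which makes the split exact by construction
            # (it agrees with max_a Q to floating-point summation order)
            V[y - 1, x - 1, d] = va + ve
            V_a[y - 1, x - 1, d] = va
            V_e[y - 1, x - 1, d] = ve
            greedy[y - 1, x - 1, d] = a
    return ValueDecomposition(V=V, V_a=V_a, V_e=V_e, greedy_action=greedy)


# ---------------------------------------------------------------------------
# egocentric SR visualisation data


def ego_sr_egocentric_plot_data(M_s_E: np.ndarray, source: int):
    """Occupancy-binned view lists for an egocentric SR row.

    The row's positive support is split into 5 equal-width occupancy bins;
    the top 3 bins (descending) are returned as
    ``[(lo, hi), [view indices]], ...``.  Zero-occupancy views are excluded
    and membership is invariant to positive rescaling of the row.
    """
    row = np.asarray(M_s_E[source], dtype=float)
    pos = row > 0
    if not np.any(pos):
        raise ValueError("SR row has no positive occupancy")
    lo, hi = row[pos].min(), row[pos].max()
    if hi == lo:
        return [((lo, hi), sorted(np.nonzero(pos)[0].tolist()))]
    edges = np.linspace(lo, hi, 6)
    out = []
    for b in (4, 3, 2):  # top 60% of the occupancy range, descending
        lo_b, hi_b = edges[b], edges[b + 1]
        if b == 4:
            members = np.nonzero(pos & (row >= lo_b))[0]
        else:
            members = np.nonzero(pos & (row >= lo_b) & (row < hi_b))[0]
        out.append(((float(lo_b), float(hi_b)), sorted(members.tolist())))
    return out


def ego_sr_allocentric_plot_data(M_s_E: np.ndarray, source: int,
                                 wt: WorldTables) -> np.ndarray:
    """Four direction-indexed occupancy heat maps of an egocentric SR row.

    ``maps[d, y-1, x-1]`` is the expected future occupancy of the view seen
    at (x, y) facing d; aliased poses produce constant-valued blocks.
    Non-traversable cells are NaN.
    """
    world = wt.world
    iw, ih = world.width - 2, world.height - 2
    maps = np.full((4, ih, iw), np.nan)
    for (x, y) in world.traversable_cells():
        c = (y - 1) * iw + (x - 1)
        for d in range(4):
            v = wt.view_of_u[c * 4 + d]
            if v < 0:
                raise ValueError("world contains a view absent from the "
                                 "codebook")
            maps[d, y - 1, x - 1] = M_s_E[source, v]
    return maps


# ---------------------------------------------------------------------------
# GLMs


@dataclass
class GlmFit:
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    link: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms, "estimate": self.coef,
                             "se": self.se, "p": self.pvalues})


def fit_barrier_poisson_glm(mean_steps: np.ndarray,
                            barrier_pixels: np.ndarray) -> GlmFit:
    """Log-link Poisson regression of per-world mean steps on the number of
    barrier pixels (the barrier-count proxy)."""
    y = np.asarray(mean_steps, dtype=float)
    x = np.asarray(barrier_pixels, dtype=float)
    if len(y) < 2 or np.ptp(x) == 0:
        raise ValueError("need >= 2 worlds with non-constant barrier counts")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response")
    X = sm.add_constant(x)
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    return GlmFit(terms=["intercept", "barrier_count"], coef=res.params,
                  se=res.bse, pvalues=res.pvalues, link="log")


def fit_occupancy_logistic_glm(features: pd.DataFrame,
                               lesioned: np.ndarray) -> GlmFit:
    """Logistic regression of the lesioned-vs-full label on occupancy
    proportions (near walls, in current barriers, in each previous world's
    barrier sites).  Raises on perfect separation rather than dropping it."""
    y = np.asarray(lesioned, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both agent classes must be present")
    X = sm.add_constant(features.to_numpy(dtype=float))
    try:
        res = sm.Logit(y, X).fit(disp=0)
    except Exception as err:  # statsmodels raises on separation
        raise RuntimeError(f"logistic fit failed (possible perfect "
                           f"separation): {err}") from err
    terms = ["intercept"] + list(features.columns)
    return GlmFit(terms=terms, coef=res.params, se=res.bse,
                  pvalues=res.pvalues, link="logit")


def occupancy_features(record: EpisodeRecord, n_prev: int | None = None):
    """Proportions of primitive steps near walls, on current barrier sites,
    and on each previous world's barrier sites."""
    k = record.world_index if n_prev is None else n_prev
    if k > record.world_index:
        raise ValueError("world index out of range for requested history")
    f_prev = list(record.f_prev[:k])
    return record.f_walls, record.f_current, f_prev


def occupancy_feature_frame(records: list[EpisodeRecord],
                            n_prev: int) -> pd.DataFrame:
    rows = []
    for r in records:
        fw, fc, fk = occupancy_features(r, min(n_prev, r.world_index))
        fk = fk + [0.0] * (n_prev - len(fk))
        rows.append([fw, fc] + fk)
    cols = ["f_walls", "f_current"] + [f"f_prev{k}" for k in
                                       range(1, n_prev + 1)]
    return pd.DataFrame(rows, columns=cols)


def chunked_occupancy_glm(full_records: list[EpisodeRecord],
                          lesioned_records: list[EpisodeRecord],
                          chunk: int = 25) -> list[tuple[int, GlmFit]]:
    """Per-chunk logistic fits distinguishing the two agents.

    Records are grouped into consecutive chunks of ``chunk`` episodes
    (post-first-switch episodes are the intended input); each chunk is fit
    separately and returned as (chunk index, fit).
    """
    n = min(len(full_records), len(lesioned_records))
    fits = []
    for ci, lo in enumerate(range(0, n - chunk + 1, chunk)):
        sel_f = full_records[lo:lo + chunk]
        sel_l = lesioned_records[lo:lo + chunk]
        n_prev = max(r.world_index for r in sel_f + sel_l)
        X = occupancy_feature_frame(sel_f + sel_l, n_prev)
        # drop all-zero regressors (no previous-world history in this chunk)
        X = X.loc[:, (X != 0).any(axis=0)]
        y = np.array([0] * len(sel_f) + [1] * len(sel_l))
        fits.append((ci, fit_occupancy_logistic_glm(X, y)))
    return fits
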