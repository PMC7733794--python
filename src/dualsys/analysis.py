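"""Behavioral analyses: stay probabilities, model-based indices,
place-memory scores and correlation statistics.

The two-step analyses follow the standard convention: a trial "stays" if the
first-stage choice repeats the previous trial's choice, stratified by the
previous trial's reward (rewarded / unrewarded) and transition type
(common / rare).  A per-agent model-based (MB) planning index is the
reward-by-transition interaction coefficient from a logistic regression of
stay on previous reward, previous transition type and their product (both
coded +/-1); a pooled fixed-effects variant over many agents is available
behind a flag.

Allocentric place memory in the moving-platform water maze is the average
distance between the previous session's platform center and the argmax of
the agent's net value map at the start of the next session (smaller =
stronger memory).

Association between the two measures is reported as Fisher's z = atanh(r)
with the significance of r, and two arms are compared with the classical
Fisher r-to-z difference test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StayTable",
    "stay_trials",
    "stay_probabilities",
    "mb_index",
    "place_memory_score",
    "association_z",
    "compare_correlations",
]


@dataclass(frozen=True)
class StayTable:
    """Stay probability by previous reward x previous transition type."""

    rewarded_common: float
    rewarded_rare: float
    unrewarded_common: float
    unrewarded_rare: float
    counts: tuple[int, int, int, int] = (0, 0, 0, 0)

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.rewarded_common, self.rewarded_rare],
                [self.unrewarded_common, self.unrewarded_rare],
            ]
        )

    @property
    def reward_effect(self) -> float:
        """Main effect of previous reward on staying."""
        return 0.5 * (
            self.rewarded_common
            + self.rewarded_rare
            - self.unrewarded_common
            - self.unrewarded_rare
        )

    @property
    def interaction(self) -> float:
        """Reward x transition interaction (positive = model-based)."""
        return (
            self.rewarded_common
            - self.rewarded_rare
            - self.unrewarded_common
            + self.unrewarded_rare
        )


def stay_trials(records) -> pd.DataFrame:
    """Consecutive-trial pairs: stay flag plus previous reward/transition.

    ``records`` is an ordered sequence of graph-task :class:`TrialRecord`
    objects (fields ``choice1``, ``reward``, ``common``).
    """
    rows = []
    for prev, cur in zip(records[:-1], records[1:]):
        if prev.choice1 < 0 or cur.choice1 < 0:
            continue
        rows.append(
            {
                "stay": int(cur.choice1 == prev.choice1),
                "prev_reward": float(prev.reward),
                "prev_common": bool(prev.common),
            }
        )
    return pd.DataFrame(rows, columns=["stay", "prev_reward", "prev_common"])


def stay_probabilities(records) -> StayTable:
    """Stay probabilities in the four reward x transition cells."""
    df = stay_trials(records)
    if df.empty:
        raise ValueError("no consecutive-trial pairs to analyze")
    cells, counts = [], []
    for rew in (1.0, 0.0):
        for common in (True, False):
            sel = df[(df.prev_reward == rew) & (df.prev_common == common)]
            counts.append(len(sel))
            cells.append(float(sel.stay.mean()) if len(sel) else np.nan)
    return StayTable(*cells, counts=tuple(counts))


def mb_index(records, min_trials: int = 20, return_mf: bool = False):
    """Per-agent model-based planning index.

    Logistic regression of stay on previous reward, previous transition and
    their interaction (all predictors coded +/-1); the MB index is the
    interaction coefficient and the MF (reward main-effect) coefficient is
    optionally returned as well.  Returns ``nan`` for degenerate designs
    (too few trials, constant choices, or perfect separation).
    """
    import statsmodels.api as sm

    df = stay_trials(records)
    if len(df) < min_trials or df.stay.nunique() < 2:
        return (np.nan, np.nan) if return_mf else np.nan
    r = 2.0 * df.prev_reward.to_numpy() - 1.0
    t = np.where(df.prev_common.to_numpy(), 1.0, -1.0)
    X = sm.add_constant(np.column_stack([r, t, r * t]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(df.stay.to_numpy(), X).fit(disp=0, maxiter=200)
        coefs = fit.params
    except Exception:
        return (np.nan, np.nan) if return_mf else np.nan
    if not np.all(np.isfinite(coefs)) or np.max(np.abs(coefs)) > 20:
        return (np.nan, np.nan) if return_mf else np.nan
    return (float(coefs[3]), float(coefs[1])) if return_mf else float(coefs[3])


def pooled_mb_index(records_by_agent, min_trials: int = 20) -> float:
    """Pooled fixed-effects variant: one logistic fit over all agents."""
    import statsmodels.api as sm

    frames = [stay_trials(rs) for rs in records_by_agent]
    df = pd.concat([f for f in frames if len(f) >= min_trials], ignore_index=True)
    r = 2.0 * df.prev_reward.to_numpy() - 1.0
    t = np.where(df.prev_common.to_numpy(), 1.0, -1.0)
    X = sm.add_constant(np.column_stack([r, t, r * t]))
    fit = sm.Logit(df.stay.to_numpy(), X).fit(disp=0, maxiter=200)
    return float(fit.params[3])


def place_memory_score(
    value_maps: np.ndarray,
    centers: np.ndarray,
    platform_history: np.ndarray,
) -> float:
    """Mean distance from the previous platform to the value-map argmax.

    ``value_maps[k]`` is the net value map (over states) at the *start* of
    session ``k+2``; ``platform_history[k]`` is the platform center of
    session ``k+1`` (the previous session).  ``centers`` holds the state
    coordinates.  A flat map is scored at the distance from the previous
    platform to the state nearest the arena centroid (tie-break), which is
    also used among exactly tied maxima.
    """
    value_maps = np.atleast_2d(np.asarray(value_maps, dtype=float))
    platform_history = np.atleast_2d(np.asarray(platform_history, dtype=float))
    if len(value_maps) != len(platform_history):
        raise ValueError("need one value map per previous platform location")
    centroid = centers.mean(axis=0)
    dists = []
    for vmap, prev in zip(value_maps, platform_history):
        vmax = vmap.max()
        ties = np.flatnonzero(vmap >= vmax - 1e-12)
        if len(ties) > 1:  # flat or tied map: nearest-to-centroid tie-break
            k = ties[np.argmin(np.linalg.norm(centers[ties] - centroid, axis=1))]
        else:
            k = ties[0]
        dists.append(float(np.linalg.norm(centers[k] - prev)))
    return float(np.mean(dists))


def association_z(x, y) -> tuple[float, float, float]:
    """Pearson association as (r, Fisher z = atanh(r), two-sided p).

    The p value tests r != 0 via the Fisher transform with standard error
    ``1/sqrt(n - 3)``.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -0.999999, 0.999999))
    z = float(np.arctanh(r))
    p = float(2 * stats.norm.sf(abs(z) * np.sqrt(n - 3)))
    return r, z, p


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z test of the difference between two correlations."""
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n1 < 4 or n2 < 4:
        raise ValueError("need at least 4 observations per sample")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = float((np.arctanh(r1) - np.arctanh(r2)) / se)
    p = float(2 * stats.norm.sf(abs(z)))
    return z, p
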