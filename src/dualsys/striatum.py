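"""Dorsolateral-striatal model-free learner.

Q-learning over sensory features with eligibility traces.  Action values are
a linear readout of the feature vector, ``Q(s, a) = sum_i w[i, a] f_i(s)``;
the TD reward-prediction error ``delta_r = r + gamma max_a' Q(s', a') -
Q(s, a)`` updates all weights in proportion to their eligibility trace.
Traces accumulate feature-action coactivity for the executed action and
decay by ``lambda`` each step; they are reset between trials (episodes are
independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StriatalState", "q_dls", "rpe", "update_traces", "update_weights", "reset_traces"]


@dataclass
class StriatalState:
    """Weights, traces and learning parameters of the striatal system."""

    n_features: int
    n_actions: int
    alpha: float = 0.1  # Q learning rate
    lam: float = 0.9  # eligibility-trace decay
    gamma: float = 0.95
    w: np.ndarray = field(default=None)  # (n_features, n_actions)
    e: np.ndarray = field(default=None)

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if self.w is None:
            self.w = np.zeros((self.n_features, self.n_actions))
        if self.e is None:
            self.e = np.zeros((self.n_features, self.n_actions))


def q_dls(features: np.ndarray, state: StriatalState) -> np.ndarray:
    """Action-value vector: linear all-to-all readout of the features."""
    if features.shape[0] != state.n_features:
        raise ValueError("feature length does not match weight matrix")
    return state.w.T @ features


def rpe(reward: float, q_sa: float, q_next_max: float, gamma: float) -> float:
    """TD reward-prediction error (``q_next_max`` must be 0 at terminals)."""
    return reward + gamma * q_next_max - q_sa


def update_traces(state: StriatalState, features: np.ndarray, action: int) -> None:
    """Decay all traces by lambda, then add the executed action's coactivity.

    The striatal activity term for the chosen action is taken as its
    indicator (1 for the executed action, 0 otherwise), so
    ``e[:, a] <- f + lambda e[:, a]`` and ``e[:, a'] <- lambda e[:, a']``.
    """
    state.e *= state.lam
    state.e[:, action] += features


def update_weights(state: StriatalState, delta_r: float, feature_norm: float = 1.0) -> None:
    """Three-factor update: ``dw = alpha * delta_r * e`` (linear in delta).

    ``feature_norm`` is the squared norm of the current feature vector; the
    step is divided by ``max(1, feature_norm)`` so that learning stays
    stable when the sensory population grows (e.g. a second landmark's
    cells appearing).  For one-hot features this is a no-op.
    """
    state.w += (state.alpha / max(1.0, feature_norm)) * delta_r * state.e


def reset_traces(state: StriatalState) -> None:
    """Zero the eligibility traces (between-trial housekeeping)."""
    state.e[:] = 0.0
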