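"""Hippocampal successor-representation learner.

Two interchangeable forms:

* **Tabular SR** — a matrix ``M[s, s']`` of expected discounted future
  occupancies of every state ``s'`` from ``s``, learned by temporal-
  difference updates on the successor prediction error, together with a
  per-state reward vector ``R`` learned by a delta rule.  State value
  factorizes as ``V = M @ R``, so editing the reward vector instantly
  revalues every predecessor state (the SR's fast revaluation).

* **Successor features (SF)** — the linear-function-approximation analogue:
  features ``f(s)`` (e.g. place-cell rates) replace punctate states; a
  weight matrix ``W`` encodes how much each feature predicts the discounted
  future activity of every other feature, ``psi(s) = W^T f(s)``, with a
  feature-reward vector ``u`` and ``V(s) = psi(s)^T u``.  With one-hot
  features the SF rules reduce exactly to the tabular ones.

Action values use one-step lookahead through a known transition model:
``Q(s, a) = r(s) + gamma E[V(s') | s, a]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TabularSR",
    "SuccessorFeatures",
    "random_walk_sr",
    "identity_sr",
    "sr_td_update",
    "reward_update",
    "v_hpc",
    "q_hpc",
    "sf_estimate",
    "sf_td_update",
    "feature_reward_update",
    "v_sf",
    "devalue",
]


def random_walk_sr(T: np.ndarray, gamma: float) -> np.ndarray:
    """Closed-form SR of a random walk: ``M = (I - gamma T)^-1``."""
    n = T.shape[0]
    return np.linalg.inv(np.eye(n) - gamma * T)


def identity_sr(n_states: int) -> np.ndarray:
    """SR encoding only that every state predicts itself."""
    if n_states < 1:
        raise ValueError("need at least one state")
    return np.eye(n_states)


def sr_td_update(
    M: np.ndarray, s: int, s_next: int, terminal: bool, alpha_m: float, gamma: float
) -> np.ndarray:
    """TD update of row ``s`` of the SR; returns the SPE vector.

    ``delta_M(s') = I(s = s') + gamma M[s_next, s'] - M[s, s']``.  At a
    terminal successor the bootstrap uses the one-hot of ``s_next`` (a
    terminal state is occupied once and predicts nothing further), so the
    learned row correctly counts the discounted visit to the terminal state
    without inheriting that state's prior (e.g. random-walk) row.
    """
    delta = -M[s].copy()
    delta[s] += 1.0
    if terminal:
        delta[s_next] += gamma
    else:
        delta += gamma * M[s_next]
    M[s] += alpha_m * delta
    return delta


def reward_update(R: np.ndarray, s: int, r: float, alpha_r: float) -> float:
    """Delta-rule update of the reward vector at the visited state."""
    err = r - R[s]
    R[s] += alpha_r * err
    return err


def v_hpc(M: np.ndarray, R: np.ndarray) -> np.ndarray:
    """State values from the SR factorization, ``V = M @ R``."""
    if M.shape[1] != R.shape[0]:
        raise ValueError("SR and reward vector shapes disagree")
    return M @ R


def q_hpc(r_s: float, v_next: float, gamma: float) -> float:
    """One-step-lookahead action value ``Q = r(s) + gamma E[V(s')]``."""
    return r_s + gamma * v_next


@dataclass
class TabularSR:
    """Tabular SR learner over a discrete state set."""

    n_states: int
    alpha_m: float = 0.1
    alpha_r: float = 0.3
    gamma: float = 0.95
    M: np.ndarray = None
    R: np.ndarray = None

    def __post_init__(self):
        if self.M is None:
            self.M = identity_sr(self.n_states)
        if self.R is None:
            self.R = np.zeros(self.n_states)

    def td_update(self, s: int, s_next: int, terminal: bool) -> np.ndarray:
        return sr_td_update(self.M, s, s_next, terminal, self.alpha_m, self.gamma)

    def learn_reward(self, s: int, r: float) -> float:
        return reward_update(self.R, s, r, self.alpha_r)

    def values(self) -> np.ndarray:
        return v_hpc(self.M, self.R)

    def action_values(self, s: int, model) -> np.ndarray:
        """Q over actions via one-step lookahead through ``model``.

        ``model`` maps (s, a) to either a successor state (deterministic
        adjacency, an (S, A) integer array) or a distribution over states
        (an (S, A, S) tensor of transition probabilities).
        """
        V = self.values()
        if model.ndim == 2:
            v_next = V[model[s]]
        else:
            v_next = model[s] @ V
        return q_hpc(self.R[s], v_next, self.gamma)


def sf_estimate(W: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Successor-feature estimate ``psi = W^T f``."""
    if W.shape[0] != f.shape[0]:
        raise ValueError("weight/feature shapes disagree")
    return W.T @ f


def sf_td_update(
    W: np.ndarray,
    f: np.ndarray,
    f_next: np.ndarray,
    terminal: bool,
    alpha_m: float,
    gamma: float,
) -> np.ndarray:
    """Linear-TD update of the SF weights; returns the feature SPE vector.

    ``delta = f + gamma psi(s_next) - W^T f`` where the terminal successor
    contributes its raw features (``psi(terminal) = f(terminal)``), matching
    the tabular terminal convention; ``W <- W + alpha_m * outer(f, delta) /
    max(1, ||f||^2)``.  The step-size floor guards against divergence at
    population-activity peaks while leaving the rule identical to the
    tabular SR update for one-hot features (where ``||f||^2 = 1``).
    """
    delta = f - W.T @ f
    if terminal:
        delta = delta + gamma * f_next
    else:
        delta = delta + gamma * (W.T @ f_next)
    W += (alpha_m / max(1.0, float(f @ f))) * np.outer(f, delta)
    return delta


def feature_reward_update(
    u: np.ndarray, f: np.ndarray, r: float, alpha_r: float, nonneg: bool = True
) -> float:
    """LMS delta rule moving the feature-reward weights toward observed reward.

    With ``nonneg`` (default) the weights are clipped at zero after each
    step: reward expectations per feature cannot go negative in
    appetitive-only tasks, mirroring the tabular reward vector, whose
    delta-rule estimates stay within the observed reward range.  Without the
    constraint, overlapping features acquire compensatory negative weights
    along unrewarded stretches, which surface as spurious repulsive value
    once co-active features are removed from the environment.
    """
    err = r - float(f @ u)
    norm = float(f @ f)
    if norm > 0:
        u += alpha_r * err * f / norm
        if nonneg:
            np.maximum(u, 0.0, out=u)
    return err


def v_sf(psi: np.ndarray, u: np.ndarray) -> float:
    """Value from successor features, ``V = psi^T u``."""
    return float(psi @ u)


@dataclass
class SuccessorFeatures:
    """Successor-feature learner over a fixed feature bank.

    ``lam`` adds an eligibility trace over past features (TD(lambda) on the
    SF weights), which propagates successor predictions along whole
    trajectories instead of single steps; ``lam=0`` recovers the plain
    one-step rule (and, with one-hot features, the tabular SR update).
    Traces are reset at trial boundaries via :meth:`reset_trace`.
    """

    n_features: int
    alpha_m: float = 0.05
    alpha_r: float = 0.3
    gamma: float = 0.95
    lam: float = 0.0
    W: np.ndarray = None
    u: np.ndarray = None
    z: np.ndarray = None  # eligibility trace over features

    def __post_init__(self):
        if self.W is None:
            self.W = np.eye(self.n_features)
        if self.u is None:
            self.u = np.zeros(self.n_features)
        if self.z is None:
            self.z = np.zeros(self.n_features)

    def reset_trace(self) -> None:
        self.z[:] = 0.0

    def td_update(self, f: np.ndarray, f_next: np.ndarray, terminal: bool) -> np.ndarray:
        if self.lam == 0.0:
            return sf_td_update(self.W, f, f_next, terminal, self.alpha_m, self.gamma)
        delta = f - self.W.T @ f
        if terminal:
            delta = delta + self.gamma * f_next
        else:
            delta = delta + self.gamma * (self.W.T @ f_next)
        self.z = self.gamma * self.lam * self.z + f
        self.W += (self.alpha_m / max(1.0, float(self.z @ self.z))) * np.outer(
            self.z, delta
        )
        return delta

    def learn_reward(self, f: np.ndarray, r: float) -> float:
        return feature_reward_update(self.u, f, r, self.alpha_r)

    def value(self, f: np.ndarray) -> float:
        return v_sf(sf_estimate(self.W, f), self.u)

    def values(self, F: np.ndarray) -> np.ndarray:
        """Values for a table of feature vectors (n_states, n_features)."""
        return (F @ self.W) @ self.u

    def action_values(self, s: int, adjacency: np.ndarray, F: np.ndarray) -> np.ndarray:
        """Lookahead Q over actions from a deterministic adjacency table."""
        V = self.values(F)
        r_s = float(F[s] @ self.u)
        return q_hpc(r_s, V[adjacency[s]], self.gamma)


def devalue(reward_repr: np.ndarray, factor: float) -> np.ndarray:
    """Scale the hippocampal reward representation (R or u) in place.

    Models reinforcer devaluation (e.g. prefeeding): only the SR system's
    reward knowledge changes; striatal weights are untouched, capturing the
    model-free system's insensitivity to devaluation without re-experience.
    """
    if not 0.0 <= factor <= 1.0:
        raise ValueError("devaluation factor must lie in [0, 1]")
    reward_repr *= factor
    return reward_repr
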