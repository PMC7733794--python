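"""Spatial arenas and discrete decision-task graphs.

Spatial environments are uniform square-grid discretizations of a continuous
allocentric plane (origin at the arena center).  The agent occupies grid-cell
centers and moves to the adjacent cell in one of a fixed set of compass
directions; moves into a boundary are clipped (no-op).  A trial ends when the
agent enters the circular goal region (reward drawn as a Bernoulli with the
goal's reward probability) or when a step cap is reached.

Nonspatial tasks are :class:`TaskGraph` objects: a discrete state set with
per-state actions, a stochastic transition tensor and terminal outcome states
whose reward probabilities follow a bounded Gaussian random walk (as in the
two-step decision task, where the four outcome probabilities drift within
[0.25, 0.75]).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Arena",
    "TaskGraph",
    "Transition",
    "build_arena",
    "configure_session",
    "step",
    "build_task_graph",
    "graph_step",
    "COMPASS_8",
    "COMPASS_4",
]

# Allocentric action directions as (dx, dy) grid offsets, index = heading id.
# 8-compass order: E, NE, N, NW, W, SW, S, SE (counterclockwise from east).
COMPASS_8 = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)],
    dtype=int,
)
# 4-compass order: E, N, W, S.
COMPASS_4 = np.array([(1, 0), (0, 1), (-1, 0), (0, -1)], dtype=int)


@dataclass(frozen=True)
class Transition:
    """One experienced step ``(s, a, r, s')`` plus bookkeeping."""

    state: int
    action: int
    reward: float
    next_state: int
    pose: tuple[float, float, int] | None = None  # (x, y, heading index)
    next_pose: tuple[float, float, int] | None = None
    terminal: bool = False
    trial: int = 0
    step: int = 0


@dataclass
class Arena:
    """A discretized allocentric arena.

    ``grid_shape`` is (nx, ny); cell (i, j) has center
    ``origin + (i + 0.5, j + 0.5) * cell_size``.  ``mask`` flags which cells
    are part of reachable space (plus-maze corridors, for example).  ``walls``
    are the *perceptible* boundary segments that drive boundary-vector-cell
    input; movement is constrained by ``mask`` regardless of walls.
    """

    kind: str
    grid_shape: tuple[int, int]
    cell_size: float = 1.0
    mask: np.ndarray | None = None  # bool (nx, ny); None = all reachable
    walls: list[tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=list
    )
    landmarks: list[tuple[tuple[float, float], str]] = field(default_factory=list)
    goal: tuple[tuple[float, float], float, float] | None = None  # center, radius, p
    start_poses: list[tuple[float, float, int]] = field(default_factory=list)
    actions: np.ndarray = field(default_factory=lambda: COMPASS_8.copy())
    max_steps: int = 1000
    # Water-maze session schedule: list of platform centers; landmark sits at
    # platform + landmark_offset in every session.
    platform_sessions: list[tuple[float, float]] = field(default_factory=list)
    landmark_offset: tuple[float, float] = (0.0, 2.0)
    terminal_cells: list[int] = field(default_factory=list)  # extra absorbing cells
    # states that cannot be entered (e.g. a blocked maze arm); unlike mask
    # changes this preserves the state indexing across configurations
    blocked_states: frozenset = frozenset()

    # ------------------------------------------------------------------ #
    # geometry helpers
    # ------------------------------------------------------------------ #
    def __post_init__(self) -> None:
        nx, ny = self.grid_shape
        if nx < 1 or ny < 1:
            raise ValueError("degenerate (zero-area) arena")
        if self.mask is None:
            self.mask = np.ones(self.grid_shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("degenerate arena: no reachable cells")
        names = [name for _, name in self.landmarks]
        if len(names) != len(set(names)):
            raise ValueError("landmark identities must be unique")
        # state index <-> cell index maps (states enumerate masked cells)
        self._cells = np.argwhere(self.mask)
        self._state_of = -np.ones(self.grid_shape, dtype=int)
        for s, (i, j) in enumerate(self._cells):
            self._state_of[i, j] = s
        if self.goal is not None and self.state_at(self.goal[0]) is None:
            raise ValueError("goal center outside the reachable arena")

    @property
    def n_states(self) -> int:
        return len(self._cells)

    @property
    def n_actions(self) -> int:
        return len(self.actions)

    @property
    def origin(self) -> np.ndarray:
        nx, ny = self.grid_shape
        return -0.5 * self.cell_size * np.array([nx, ny])

    def cell_center(self, state: int) -> np.ndarray:
        i, j = self._cells[state]
        return self.origin + (np.array([i, j]) + 0.5) * self.cell_size

    def centers(self) -> np.ndarray:
        """(n_states, 2) array of cell-center coordinates."""
        return self.origin + (self._cells + 0.5) * self.cell_size

    def state_at(self, xy: Sequence[float]) -> int | None:
        ij = np.floor((np.asarray(xy, dtype=float) - self.origin) / self.cell_size)
        i, j = ij.astype(int)
        nx, ny = self.grid_shape
        if not (0 <= i < nx and 0 <= j < ny) or not self.mask[i, j]:
            return None
        return int(self._state_of[i, j])

    def neighbor(self, state: int, action: int) -> int:
        """Successor state under the (deterministic) movement model."""
        i, j = self._cells[state]
        di, dj = self.actions[action]
        ni, nj = i + di, j + dj
        nx, ny = self.grid_shape
        if not (0 <= ni < nx and 0 <= nj < ny) or not self.mask[ni, nj]:
            return state
        nxt = int(self._state_of[ni, nj])
        if nxt in self.blocked_states:
            return state
        return nxt

    def adjacency(self) -> np.ndarray:
        """(n_states, n_actions) table of successor states."""
        out = np.empty((self.n_states, self.n_actions), dtype=int)
        for s in range(self.n_states):
            for a in range(self.n_actions):
                out[s, a] = self.neighbor(s, a)
        return out

    def random_walk_matrix(self) -> np.ndarray:
        """Uniform-over-actions transition matrix (clipped moves self-loop)."""
        T = np.zeros((self.n_states, self.n_states))
        adj = self.adjacency()
        for s in range(self.n_states):
            for a in range(self.n_actions):
                T[s, adj[s, a]] += 1.0 / self.n_actions
        return T

    def in_goal(self, xy: Sequence[float]) -> bool:
        if self.goal is None:
            return False
        center, radius, _ = self.goal
        return float(np.hypot(*(np.asarray(xy) - np.asarray(center)))) <= radius

    def heading_angle(self, heading: int) -> float:
        dx, dy = self.actions[heading]
        return float(np.arctan2(dy, dx))


# ---------------------------------------------------------------------- #
# arena construction
# ---------------------------------------------------------------------- #

def _box_walls(half: float) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    h = half
    return [
        ((-h, -h), (h, -h)),
        ((h, -h), (h, h)),
        ((h, h), (-h, h)),
        ((-h, h), (-h, -h)),
    ]


def _pearce_platform_sessions(n_sessions: int = 11) -> list[tuple[float, float]]:
    """Scattered platform centers, one per session (golden-angle layout).

    The original study shows the candidate locations graphically; here they
    are placed deterministically at alternating radii around the tank center
    so that consecutive sessions are well separated.
    """
    out = []
    for k in range(n_sessions):
        ang = np.deg2rad(20.0 + k * 137.5)
        rad = 3.0 if k % 2 == 0 else 5.5
        out.append((float(rad * np.cos(ang)), float(rad * np.sin(ang))))
    return out


def build_arena(kind: str, **kw) -> Arena:
    """Construct one of the standard arenas.

    Parameters
    ----------
    kind:
        ``linear_track`` | ``water_maze`` | ``plus_maze`` | ``open_field``.
    kw:
        Geometry overrides (``n`` for the track, ``size`` for grids,
        ``reward_prob``, ``arm_length`` for the plus maze, ...).
    """
    if kind == "linear_track":
        n = int(kw.get("n", 5))
        p = float(kw.get("reward_prob", 0.8))
        if n < 2:
            raise ValueError("linear track needs at least 2 states")
        return Arena(
            kind=kind,
            grid_shape=(n, 1),
            actions=np.array([(1, 0), (-1, 0)]),
            goal=((n / 2.0 - 0.5, 0.0), 0.4, p),
            start_poses=[(-n / 2.0 + 0.5, 0.0, 0)],
            max_steps=int(kw.get("max_steps", 200)),
        )
    if kind == "water_maze":
        size = int(kw.get("size", 20))
        sessions = kw.get("platform_sessions") or _pearce_platform_sessions(
            int(kw.get("n_sessions", 11))
        )
        offset = tuple(kw.get("landmark_offset", (0.0, 2.0)))
        radius = float(kw.get("platform_radius", 1.2))
        p = float(kw.get("reward_prob", 1.0))
        half = size / 2.0
        edge = half - 0.5
        arena = Arena(
            kind=kind,
            grid_shape=(size, size),
            walls=_box_walls(half),
            goal=(tuple(sessions[0]), radius, p),
            landmarks=[],
            start_poses=[
                (-edge, 0.0, 0),
                (edge, 0.0, 4),
                (0.0, -edge, 2),
                (0.0, edge, 6),
            ],
            platform_sessions=[tuple(c) for c in sessions],
            landmark_offset=offset,
            max_steps=int(kw.get("max_steps", 1000)),
        )
        return configure_session(arena, 1)
    if kind == "plus_maze":
        return _build_plus_maze(**kw)
    if kind == "open_field":
        size = int(kw.get("size", 20))
        arena = Arena(
            kind=kind,
            grid_shape=(size, size),
            walls=list(kw.get("walls", [])),
            landmarks=list(kw.get("landmarks", [])),
            goal=kw.get("goal"),
            start_poses=list(kw.get("start_poses", [])) or [(0.0, -size / 2 + 0.5, 2)],
            max_steps=int(kw.get("max_steps", 1000)),
        )
        return arena
    raise ValueError(f"unknown arena kind: {kind!r}")


_ARMS = {"E": 0, "N": 1, "W": 2, "S": 3}


def _build_plus_maze(
    arm_length: int = 3,
    start_arm: str = "S",
    goal_arm: str = "W",
    blocked_arm: str = "N",
    reward_prob: float = 1.0,
    probe: bool = False,
    max_steps: int = 200,
) -> Arena:
    """Plus maze: four single-cell-wide arms around a central choice point.

    During training one arm is blocked (its cells cannot be entered; the
    state indexing is unchanged so learned representations carry over to
    probes).  In a probe trial (``probe=True``) the agent starts at the end
    of the previously blocked arm, no arm is blocked, there is no reward,
    and both potential goal-arm ends are absorbing (the probe run is
    classified by which end is reached).
    """
    L = arm_length
    n = 2 * L + 1
    mask = np.zeros((n, n), dtype=bool)
    mask[L, :] = True
    mask[:, L] = True

    def arm_end_xy(arm: str) -> tuple[float, float]:
        dx, dy = COMPASS_4[_ARMS[arm]]
        return (float(L * dx), float(L * dy))

    start = start_arm if not probe else blocked_arm
    sx, sy = arm_end_xy(start)
    heading = int((_ARMS[start] + 2) % 4)  # facing the center
    arena = Arena(
        kind="plus_maze",
        grid_shape=(n, n),
        mask=mask,
        actions=COMPASS_4.copy(),
        goal=None if probe else (arm_end_xy(goal_arm), 0.4, reward_prob),
        landmarks=[((0.0, 0.0), "center")],
        start_poses=[(sx, sy, heading)],
        max_steps=max_steps,
    )
    if not probe and blocked_arm is not None:
        dx, dy = COMPASS_4[_ARMS[blocked_arm]]
        arena.blocked_states = frozenset(
            arena.state_at((float(k * dx), float(k * dy))) for k in range(1, L + 1)
        )
    if probe:
        # both the trained goal arm and its opposite are absorbing
        opp = {"E": "W", "W": "E", "N": "S", "S": "N"}[goal_arm]
        arena.terminal_cells = [
            arena.state_at(arm_end_xy(goal_arm)),
            arena.state_at(arm_end_xy(opp)),
        ]
    return arena


def configure_session(arena: Arena, session_index: int) -> Arena:
    """Return the water-maze arena configured for 1-based ``session_index``.

    The platform (goal) moves to the session's location and the landmark
    moves with it, keeping the landmark-platform offset identical across
    sessions.
    """
    if arena.kind != "water_maze":
        raise ValueError("configure_session applies to water_maze arenas")
    if not 1 <= session_index <= len(arena.platform_sessions):
        raise ValueError(
            f"session index {session_index} exceeds configured "
            f"{len(arena.platform_sessions)} locations"
        )
    center = arena.platform_sessions[session_index - 1]
    _, radius, p = arena.goal if arena.goal is not None else ((0, 0), 1.2, 1.0)
    off = np.asarray(arena.landmark_offset)
    lm = tuple(np.asarray(center) + off)
    new = replace(
        arena,
        goal=(tuple(center), radius, p),
        landmarks=[(lm, "cue")],
        mask=arena.mask.copy(),
    )
    return new


# ---------------------------------------------------------------------- #
# spatial stepping
# ---------------------------------------------------------------------- #

def step(
    arena: Arena,
    pose: tuple[float, float, int],
    action: int,
    rng: np.random.Generator,
    trial: int = 0,
    step_index: int = 0,
) -> Transition:
    """Advance one grid step in allocentric direction ``action``.

    The next pose is the adjacent cell center in the chosen direction
    (clipped at boundaries, in which case the position is unchanged but the
    heading still turns).  Entering the goal region draws a Bernoulli reward
    and terminates the trial.
    """
    x, y, _ = pose
    s = arena.state_at((x, y))
    if s is None:
        raise ValueError(f"pose {pose} outside the arena")
    if not 0 <= action < arena.n_actions:
        raise ValueError(f"action {action} not in the action set")
    s_next = arena.neighbor(s, action)
    nxt = arena.cell_center(s_next)
    reward, terminal = 0.0, False
    if arena.in_goal(nxt):
        _, _, p = arena.goal
        reward = float(rng.random() < p)
        terminal = True
    if s_next in arena.terminal_cells:
        terminal = True
    return Transition(
        state=s,
        action=action,
        reward=reward,
        next_state=s_next,
        pose=(x, y, pose[2]),
        next_pose=(float(nxt[0]), float(nxt[1]), action),
        terminal=terminal,
        trial=trial,
        step=step_index,
    )


# ---------------------------------------------------------------------- #
# task graphs
# ---------------------------------------------------------------------- #

@dataclass
class TaskGraph:
    """Discrete decision task with drifting terminal reward probabilities."""

    n_states: int
    n_actions: int
    P: np.ndarray  # (n_states, n_actions, n_states)
    terminal: np.ndarray  # bool (n_states,)
    reward_probs: np.ndarray  # (n_states,); 0 for nonterminal states
    drift_sd: float = 0.025
    prob_bounds: tuple[float, float] = (0.25, 0.75)
    start_state: int = 0

    def __post_init__(self) -> None:
        rows = self.P[~self.terminal].sum(axis=-1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")

    def drift(self, rng: np.random.Generator) -> None:
        """Advance the bounded Gaussian random walk on the reward probs."""
        lo, hi = self.prob_bounds
        mask = self.terminal
        self.reward_probs[mask] = np.clip(
            self.reward_probs[mask] + rng.normal(0.0, self.drift_sd, mask.sum()),
            lo,
            hi,
        )


def build_task_graph(
    variant: str,
    common_prob: float = 0.7,
    drift_sd: float = 0.025,
    prob_bounds: tuple[float, float] = (0.25, 0.75),
    rng: np.random.Generator | None = None,
) -> TaskGraph:
    """Two-step decision tasks.

    ``daw_two_step``: one start state with two actions leading to one of two
    second-stage states with probability ``common_prob`` (common) versus
    ``1 - common_prob`` (rare); second-stage choices lead deterministically to
    four terminal outcomes whose reward probabilities drift within
    ``prob_bounds``.  ``deterministic_two_step``: same structure with
    deterministic first-stage transitions.
    """
    if variant not in {"daw_two_step", "deterministic_two_step"}:
        raise ValueError(f"unknown task-graph variant: {variant!r}")
    if not 0.5 < common_prob <= 1.0:
        raise ValueError("common transitions must be more likely than rare ones")
    rng = rng or np.random.default_rng(0)
    n_states, n_actions = 7, 2  # 0 root; 1,2 stage two; 3-6 outcomes
    P = np.zeros((n_states, n_actions, n_states))
    c = common_prob if variant == "daw_two_step" else 1.0
    P[0, 0, 1], P[0, 0, 2] = c, 1.0 - c
    P[0, 1, 2], P[0, 1, 1] = c, 1.0 - c
    P[1, 0, 3] = P[1, 1, 4] = P[2, 0, 5] = P[2, 1, 6] = 1.0
    terminal = np.zeros(n_states, dtype=bool)
    terminal[3:] = True
    lo, hi = prob_bounds
    probs = np.zeros(n_states)
    probs[3:] = rng.uniform(lo, hi, 4)
    return TaskGraph(
        n_states=n_states,
        n_actions=n_actions,
        P=P,
        terminal=terminal,
        reward_probs=probs,
        drift_sd=drift_sd,
        prob_bounds=prob_bounds,
    )


def graph_step(
    graph: TaskGraph,
    state: int,
    action: int,
    rng: np.random.Generator,
    trial: int = 0,
    step_index: int = 0,
) -> Transition:
    """Sample one graph transition; at trial end advance the reward drift."""
    if not 0 <= state < graph.n_states or graph.terminal[state]:
        raise ValueError(f"invalid (nonchoice) state {state}")
    if not 0 <= action < graph.n_actions:
        raise ValueError(f"invalid action {action}")
    s_next = int(rng.choice(graph.n_states, p=graph.P[state, action]))
    reward, terminal = 0.0, False
    if graph.terminal[s_next]:
        reward = float(rng.random() < graph.reward_probs[s_next])
        terminal = True
        graph.drift(rng)
    return Transition(
        state=state,
        action=action,
        reward=reward,
        next_state=s_next,
        terminal=terminal,
        trial=trial,
        step=step_index,
    )
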