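"""Agent runtime: composing the two learners and the arbitrator.

The agent carries a striatal model-free learner over egocentric sensory
features, a hippocampal SR (tabular or successor-feature) learner over
allocentric features, and a reliability-based arbitrator.  On every step it
computes both systems' action values, mixes them as

    Q_net = P_SR * Q_HPC + (1 - P_SR) * Q_DLS

(the arbitrator combines values, not actions), draws an action from a
softmax, observes the transition, and updates both learners and both
reliability trackers regardless of which system dominated the choice.

In spatial arenas the striatal action space is egocentric (rotations
relative to the current heading); its values are rotated into the shared
allocentric action frame before mixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arbitration import ArbitrationParams, Arbitrator
from .environments import Arena, TaskGraph, graph_step, step
from .features import (
    LandmarkCellBank,
    PlaceCellBank,
    build_lc_bank,
    feature_table_lc,
    feature_table_pc,
)
from .hippocampus import SuccessorFeatures, TabularSR, identity_sr, random_walk_sr
from .striatum import StriatalState, q_dls, reset_traces, rpe, update_traces, update_weights

__all__ = [
    "AgentConfig",
    "TrialRecord",
    "SpatialAgent",
    "GraphAgent",
    "combined_q",
    "select_action",
    "softmax_probs",
    "run_experiment",
]


@dataclass(frozen=True)
class AgentConfig:
    """All tunable parameters of the composed agent."""

    gamma: float = 0.95
    alpha_q: float = 0.1  # striatal learning rate
    lam: float = 0.9  # eligibility-trace decay
    alpha_m: float = 0.1  # SR learning rate
    alpha_r: float = 0.3  # reward-vector learning rate
    eta: float = 0.03  # reliability learning rate
    delta_max: float = 1.0
    arb_params: ArbitrationParams = field(default_factory=ArbitrationParams)
    beta_softmax: float = 30.0  # inverse temperature
    hpc_lesion: float = 0.0  # severity in [0, 1]; 1 pins P_SR = 0
    dls_lesion: float = 0.0  # severity in [0, 1]; 1 pins P_SR = 1
    sr_init: str = "random_walk"  # "random_walk" (pre-explored arenas) | "identity"
    hpc_form: str = "tabular"  # "tabular" | "sf"
    dls_features: str = "landmark"  # "landmark" | "one_hot"
    sf_lambda: float = 0.0  # eligibility-trace decay of the SF learner
    ego_actions: bool = True  # striatal action space egocentric?
    omega_mf0: float = 1.0
    omega_sr0: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if self.beta_softmax <= 0:
            raise ValueError("softmax inverse temperature must be positive")


@dataclass
class TrialRecord:
    """Per-trial outcome summary (full transitions optional)."""

    trial: int
    steps: int
    reward: float
    terminal: bool  # False when the step cap was exhausted
    final_state: int
    visited: np.ndarray  # states entered this trial (occupancy)
    mean_psr: float
    start_psr: float
    mean_omega_mf: float
    mean_abs_rpe: float
    transitions: list | None = None
    # graph-task fields
    choice1: int = -1
    stage2: int = -1
    common: bool = True


def combined_q(q_hpc: np.ndarray, q_dls: np.ndarray, psr: float) -> np.ndarray:
    """Reliability-weighted mixture of the two systems' action values."""
    q_hpc, q_dls = np.asarray(q_hpc), np.asarray(q_dls)
    if q_hpc.shape != q_dls.shape:
        raise ValueError("action sets of the two systems do not match")
    return psr * q_hpc + (1.0 - psr) * q_dls


def softmax_probs(q: np.ndarray, beta: float) -> np.ndarray:
    """Softmax choice probabilities with inverse temperature ``beta``."""
    q = np.asarray(q, dtype=float)
    if q.size == 0:
        raise ValueError("empty action set")
    if np.isinf(beta):
        p = (q == q.max()).astype(float)
        return p / p.sum()
    z = beta * (q - q.max())
    e = np.exp(z)
    return e / e.sum()


def select_action(q: np.ndarray, beta: float, rng: np.random.Generator) -> int:
    """Softmax draw; argmax (ties uniform) in the zero-temperature limit."""
    if not np.all(np.isfinite(np.asarray(q, dtype=float))):
        raise ValueError("action values must be finite")
    return int(rng.choice(len(q), p=softmax_probs(q, beta)))


# ---------------------------------------------------------------------- #
# spatial agent
# ---------------------------------------------------------------------- #

class SpatialAgent:
    """Dual-system agent for grid arenas."""

    def __init__(
        self,
        arena: Arena,
        config: AgentConfig,
        rng: np.random.Generator,
        lc_bank: LandmarkCellBank | None = None,
        pc_bank: PlaceCellBank | None = None,
        lc_table: np.ndarray | None = None,
        pc_table: np.ndarray | None = None,
    ):
        self.cfg = config
        self.rng = rng
        self.pc_bank = pc_bank
        if config.dls_features == "landmark":
            idents = sorted({name for _, name in arena.landmarks}) or ["cue"]
            self.lc_bank = lc_bank or build_lc_bank(idents)
            n_f = self.lc_bank.n_features
        else:
            self.lc_bank = None
            n_f = arena.n_states
        self._init_arena(arena, lc_table, pc_table)
        self.striatum = StriatalState(
            n_f, arena.n_actions, config.alpha_q, config.lam, config.gamma
        )
        if config.hpc_form == "sf":
            if pc_bank is None:
                raise ValueError("successor-feature agent needs a place-cell bank")
            self.hpc = SuccessorFeatures(
                pc_bank.n_features,
                config.alpha_m,
                config.alpha_r,
                config.gamma,
                lam=config.sf_lambda,
            )
        else:
            if config.sr_init == "random_walk":
                M0 = random_walk_sr(arena.random_walk_matrix(), config.gamma)
            else:
                M0 = identity_sr(arena.n_states)
            self.hpc = TabularSR(
                arena.n_states, config.alpha_m, config.alpha_r, config.gamma, M=M0
            )
        self.arb = Arbitrator(
            params=config.arb_params,
            eta=config.eta,
            delta_max=config.delta_max,
            omega_mf=config.omega_mf0,
            omega_sr=config.omega_sr0,
            spe_scale=1.0 - config.gamma,
        )
        self.arb.influence.psr = 0.5
        if config.hpc_lesion > 0:
            self.arb.lesion("HPC", config.hpc_lesion)
        if config.dls_lesion > 0:
            self.arb.lesion("DLS", config.dls_lesion)

    # -- arena (re)configuration ---------------------------------------- #
    def _init_arena(self, arena: Arena, lc_table=None, pc_table=None) -> None:
        self.arena = arena
        self.adj = arena.adjacency()
        if self.lc_bank is not None:
            self.lc_table = (
                lc_table if lc_table is not None else feature_table_lc(arena, self.lc_bank)
            )
        if self.pc_bank is not None:
            self.F = (
                pc_table if pc_table is not None else feature_table_pc(arena, self.pc_bank)
            )

    def set_arena(self, arena: Arena, lc_table=None, pc_table=None) -> None:
        """Swap the arena (new session/phase) while keeping learned state."""
        self._init_arena(arena, lc_table, pc_table)

    # -- value computation ---------------------------------------------- #
    def dls_features(self, s: int, h: int) -> np.ndarray:
        if self.lc_bank is not None:
            return self.lc_table[s, h]
        f = np.zeros(self.arena.n_states)
        f[s] = 1.0
        return f

    def q_dls_allocentric(self, q_ego: np.ndarray, h: int) -> np.ndarray:
        """Rotate egocentric striatal values into the allocentric frame.

        Egocentric action k means "heading + k" in the allocentric index, so
        allocentric action a reads egocentric slot (a - h) mod A.
        """
        if not self.cfg.ego_actions:
            return q_ego
        A = len(q_ego)
        idx = (np.arange(A) - h) % A
        return q_ego[idx]

    def q_hpc_values(self, s: int) -> np.ndarray:
        if self.cfg.hpc_form == "sf":
            W, u = self.hpc.W, self.hpc.u
            wu = W @ u
            r_s = float(self.F[s] @ u)
            return r_s + self.cfg.gamma * (self.F[self.adj[s]] @ wu)
        M, R = self.hpc.M, self.hpc.R
        return R[s] + self.cfg.gamma * (M[self.adj[s]] @ R)

    def net_value_map(self) -> np.ndarray:
        """Combined state-value map, P_SR V_HPC + (1-P_SR) V_DLS.

        V_DLS(s) is the best striatal action value at s, maximized over
        headings (the striatal map depends on the egocentric view).
        """
        psr = self.arb.psr
        if self.cfg.hpc_form == "sf":
            v_hpc = (self.F @ self.hpc.W) @ self.hpc.u
        else:
            v_hpc = self.hpc.M @ self.hpc.R
        if self.lc_bank is not None:
            # (S, H, F) @ (F, A) -> max over headings and actions
            q = np.einsum("shf,fa->sha", self.lc_table, self.striatum.w)
            v_dls = q.max(axis=(1, 2))
        else:
            v_dls = self.striatum.w.max(axis=1)
        return psr * v_hpc + (1.0 - psr) * v_dls

    # -- the learning loop ---------------------------------------------- #
    def run_trial(
        self,
        trial: int = 0,
        start_pose=None,
        record_steps: bool = False,
        learn: bool = True,
    ) -> TrialRecord:
        arena, cfg, rng = self.arena, self.cfg, self.rng
        if start_pose is None:
            start_pose = arena.start_poses[rng.integers(len(arena.start_poses))]
        pose = tuple(start_pose)
        s = arena.state_at(pose[:2])
        h = int(pose[2])
        reset_traces(self.striatum)
        if self.cfg.hpc_form == "sf":
            self.hpc.reset_trace()
        visited = [s]
        psr_sum = omega_sum = rpe_sum = 0.0
        start_psr = self.arb.psr
        transitions = [] if record_steps else None
        reward = 0.0
        terminal = False
        n = 0
        for t in range(arena.max_steps):
            f = self.dls_features(s, h)
            q_ego = q_dls(f, self.striatum)
            q_d = self.q_dls_allocentric(q_ego, h)
            q_h = self.q_hpc_values(s)
            q_net = combined_q(q_h, q_d, self.arb.psr)
            a = select_action(q_net, cfg.beta_softmax, rng)
            tr = step(arena, pose, a, rng, trial=trial, step_index=t)
            s_next, r, terminal = tr.next_state, tr.reward, tr.terminal
            h_next = a
            if learn:
                ego_a = (a - h) % arena.n_actions if cfg.ego_actions else a
                if terminal:
                    q_next_max = 0.0
                else:
                    f_next = self.dls_features(s_next, h_next)
                    q_next_max = float(np.max(q_dls(f_next, self.striatum)))
                delta_r = rpe(r, float(q_ego[ego_a]), q_next_max, cfg.gamma)
                update_traces(self.striatum, f, ego_a)
                update_weights(self.striatum, delta_r, float(f @ f))
                if cfg.hpc_form == "sf":
                    delta_m = self.hpc.td_update(self.F[s], self.F[s_next], terminal)
                    self.hpc.learn_reward(self.F[s_next], r)
                else:
                    delta_m = self.hpc.td_update(s, s_next, terminal)
                    self.hpc.learn_reward(s_next, r)
                self.arb.step(abs(delta_r), delta_m)
                rpe_sum += abs(delta_r)
            psr_sum += self.arb.psr
            omega_sum += self.arb.omega_mf
            visited.append(s_next)
            if record_steps:
                transitions.append(tr)
            n = t + 1
            reward = r
            s, h, pose = s_next, h_next, tr.next_pose
            if terminal:
                break
        return TrialRecord(
            trial=trial,
            steps=n,
            reward=reward,
            terminal=terminal,
            final_state=s,
            visited=np.asarray(visited, dtype=np.int32),
            mean_psr=psr_sum / max(n, 1),
            start_psr=start_psr,
            mean_omega_mf=omega_sum / max(n, 1),
            mean_abs_rpe=rpe_sum / max(n, 1),
            transitions=transitions,
        )


# ---------------------------------------------------------------------- #
# graph agent (two-step tasks)
# ---------------------------------------------------------------------- #

class GraphAgent:
    """Dual-system agent for discrete task graphs (one-hot features)."""

    def __init__(self, graph: TaskGraph, config: AgentConfig, rng: np.random.Generator):
        self.graph = graph
        self.cfg = config
        self.rng = rng
        n, A = graph.n_states, graph.n_actions
        self.striatum = StriatalState(n, A, config.alpha_q, config.lam, config.gamma)
        # task graphs carry no pre-exposure: the SR starts at the identity
        self.hpc = TabularSR(n, config.alpha_m, config.alpha_r, config.gamma)
        self.arb = Arbitrator(
            params=config.arb_params,
            eta=config.eta,
            delta_max=config.delta_max,
            omega_mf=config.omega_mf0,
            omega_sr=config.omega_sr0,
            spe_scale=1.0 - config.gamma,
        )
        self.arb.influence.psr = 0.5
        if config.hpc_lesion > 0:
            self.arb.lesion("HPC", config.hpc_lesion)
        if config.dls_lesion > 0:
            self.arb.lesion("DLS", config.dls_lesion)

    def q_values(self, s: int) -> tuple[np.ndarray, np.ndarray]:
        q_d = self.striatum.w[s]
        V = self.hpc.M @ self.hpc.R
        q_h = self.hpc.R[s] + self.cfg.gamma * (self.graph.P[s] @ V)
        return q_h, q_d

    def run_trial(self, trial: int = 0) -> TrialRecord:
        graph, cfg, rng = self.graph, self.cfg, self.rng
        s = graph.start_state
        reset_traces(self.striatum)
        choice1, stage2 = -1, -1
        visited = [s]
        psr_sum = omega_sum = rpe_sum = 0.0
        start_psr = self.arb.psr
        n = 0
        terminal = False
        reward = 0.0
        while not terminal:
            q_h, q_d = self.q_values(s)
            q_net = combined_q(q_h, q_d, self.arb.psr)
            a = select_action(q_net, cfg.beta_softmax, rng)
            tr = graph_step(graph, s, a, rng, trial=trial, step_index=n)
            s_next, r, terminal = tr.next_state, tr.reward, tr.terminal
            if n == 0:
                choice1 = a
            if not graph.terminal[s_next] and s_next != graph.start_state:
                stage2 = s_next
            q_next_max = 0.0 if terminal else float(np.max(self.striatum.w[s_next]))
            delta_r = rpe(r, float(self.striatum.w[s, a]), q_next_max, cfg.gamma)
            self.striatum.e *= cfg.lam
            self.striatum.e[s, a] += 1.0
            update_weights(self.striatum, delta_r)
            delta_m = self.hpc.td_update(s, s_next, terminal)
            self.hpc.learn_reward(s_next, r)
            self.arb.step(abs(delta_r), delta_m)
            psr_sum += self.arb.psr
            omega_sum += self.arb.omega_mf
            rpe_sum += abs(delta_r)
            visited.append(s_next)
            reward = r
            n += 1
            s = s_next
        common = (choice1 == 0 and stage2 == 1) or (choice1 == 1 and stage2 == 2)
        return TrialRecord(
            trial=trial,
            steps=n,
            reward=reward,
            terminal=True,
            final_state=s,
            visited=np.asarray(visited, dtype=np.int32),
            mean_psr=psr_sum / max(n, 1),
            start_psr=start_psr,
            mean_omega_mf=omega_sum / max(n, 1),
            mean_abs_rpe=rpe_sum / max(n, 1),
            choice1=choice1,
            stage2=stage2,
            common=common,
        )


def run_experiment(protocol, n_agents: int, seeds=None):
    """Run ``protocol(rng) -> result`` for independently seeded agents.

    ``protocol`` is any callable taking a ``numpy.random.Generator``;
    ``seeds`` defaults to ``0 .. n_agents-1``.  Returns the list of results.
    """
    if seeds is None:
        seeds = range(n_agents)
    seeds = list(seeds)[:n_agents]
    return [protocol(np.random.default_rng(seed)) for seed in seeds]
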