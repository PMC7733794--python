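"""The five simulated protocols and their aggregation logic.

Each ``run_*`` function simulates one behavioral protocol with a population
of independently seeded agents and returns the quantities the corresponding
behavioral analyses operate on:

* ``run_linear_track`` — arbitration dynamics demo: reliability of both
  systems and the SR system's influence P_SR over trials on a five-state
  track with probabilistic terminal reward.
* ``run_pearce`` — the moving-platform water maze (platform + landmark
  jointly relocated at the start of every four-trial session) with control
  and hippocampus-lesioned arms; yields escape latencies, first-trial
  occupancy relative to the previous platform, and per-agent allocentric
  place-memory scores.
* ``run_plus_maze`` — place/response strategy competition with probe trials
  from the opposite start arm, optional reinforcer devaluation, and
  control / HPC-inactivated / DLS-inactivated arms.
* ``run_blocking`` — landmark versus boundary blocking: three 10-trial
  phases (single cue, compound, first cue removed).
* ``run_two_step`` — the probabilistic two-step decision task under
  striatal-only, hippocampal-only, or full arbitration control.
* ``run_correlation_study`` — heterogeneous agents run both the two-step
  and the water-maze protocols; per-agent model-based indices are
  associated with allocentric place-memory scores in intact and partially
  HPC-lesioned arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .agent import AgentConfig, GraphAgent, SpatialAgent, TrialRecord
from .analysis import (
    StayTable,
    association_z,
    compare_correlations,
    mb_index,
    place_memory_score,
    stay_probabilities,
)
from .arbitration import ArbitrationParams
from .environments import build_arena, build_task_graph, configure_session
from .features import build_lc_bank, build_place_cell_bank, feature_table_lc, feature_table_pc
from .hippocampus import devalue

__all__ = [
    "run_linear_track",
    "run_pearce",
    "run_plus_maze",
    "classify_strategy",
    "run_blocking",
    "run_two_step",
    "run_correlation_study",
    "PearceResult",
    "PlusMazeResult",
    "BlockingResult",
    "CorrelationResult",
]


# ---------------------------------------------------------------------- #
# linear track (arbitration demo)
# ---------------------------------------------------------------------- #

def run_linear_track(
    rng: np.random.Generator,
    n_trials: int = 30,
    config: AgentConfig | None = None,
):
    """Train one agent on the five-state track; return per-trial records.

    States are uniquely identified by landmarks, so the striatal system sees
    one-hot features; the SR starts from the random-walk prior (the track is
    freely explored before training).
    """
    cfg = config or AgentConfig(
        dls_features="one_hot",
        ego_actions=False,
        sr_init="random_walk",
        beta_softmax=5.0,
        eta=0.01,
    )
    arena = build_arena("linear_track", n=5, reward_prob=0.8)
    agent = SpatialAgent(arena, cfg, rng)
    records = [agent.run_trial(trial=t) for t in range(n_trials)]
    return records, agent


# ---------------------------------------------------------------------- #
# Pearce moving-platform water maze
# ---------------------------------------------------------------------- #

@dataclass
class PearceResult:
    latencies: np.ndarray  # (n_agents, n_sessions, trials_per_session)
    rel_occupancy: np.ndarray  # first-trial occupancy, previous-platform-centered
    memory_scores: np.ndarray  # (n_agents,) place-memory distances
    arm: str = "control"

    def trial_curve(self, trial: int) -> np.ndarray:
        """Mean latency across agents for 1-based ``trial`` of each session."""
        return self.latencies[:, :, trial - 1].mean(axis=0)


def _pearce_tables(arena, sessions, lc_bank):
    tables = {}
    for k in range(1, sessions + 1):
        tables[k] = feature_table_lc(configure_session(arena, k), lc_bank)
    return tables


def pearce_single_run(
    rng: np.random.Generator,
    config: AgentConfig,
    n_sessions: int = 11,
    trials_per_session: int = 4,
    arena=None,
    lc_bank=None,
    lc_tables=None,
):
    """One agent through the full session schedule.

    Returns (latencies, value_maps, platform_history, occupancy, arena):
    ``value_maps[k]`` is the net value map at the start of session k+2 and
    ``platform_history[k]`` the session-(k+1) platform center; ``occupancy``
    accumulates first-trial visits of sessions >= 2 in coordinates centered
    on the previous platform cell.
    """
    arena = arena or build_arena("water_maze", n_sessions=n_sessions)
    lc_bank = lc_bank or build_lc_bank(["cue"])
    if lc_tables is None:
        lc_tables = _pearce_tables(arena, n_sessions, lc_bank)
    sess1 = configure_session(arena, 1)
    agent = SpatialAgent(sess1, config, rng, lc_bank=lc_bank, lc_table=lc_tables[1])
    size = arena.grid_shape[0]
    latencies = np.zeros((n_sessions, trials_per_session))
    occupancy = np.zeros((2 * size + 1, 2 * size + 1))
    value_maps, platform_history = [], []
    centers = arena.centers()
    for k in range(1, n_sessions + 1):
        sess = configure_session(arena, k)
        agent.set_arena(sess, lc_table=lc_tables[k])
        if k >= 2:
            value_maps.append(agent.net_value_map())
            platform_history.append(arena.platform_sessions[k - 2])
        for t in range(trials_per_session):
            rec = agent.run_trial(trial=(k - 1) * trials_per_session + t)
            latencies[k - 1, t] = rec.steps
            if t == 0 and k >= 2:
                prev = np.asarray(arena.platform_sessions[k - 2])
                rel = np.round(
                    (centers[rec.visited] - prev) / arena.cell_size
                ).astype(int)
                np.add.at(
                    occupancy,
                    (rel[:, 0] + size, rel[:, 1] + size),
                    1.0,
                )
    score = place_memory_score(np.array(value_maps), centers, np.array(platform_history))
    return latencies, np.array(value_maps), np.array(platform_history), occupancy, score


def run_pearce(
    n_agents: int = 20,
    arm: str = "control",
    n_sessions: int = 11,
    trials_per_session: int = 4,
    config: AgentConfig | None = None,
    seed: int = 0,
) -> PearceResult:
    """Population run of the moving-platform task for one arm."""
    base = config or AgentConfig(eta=2e-4, alpha_q=0.3)
    if arm == "hpc_lesion":
        base = replace(base, hpc_lesion=1.0)
    elif arm == "dls_lesion":
        base = replace(base, dls_lesion=1.0)
    elif arm != "control":
        raise ValueError(f"unknown arm {arm!r}")
    arena = build_arena("water_maze", n_sessions=n_sessions)
    lc_bank = build_lc_bank(["cue"])
    lc_tables = _pearce_tables(arena, n_sessions, lc_bank)
    lat, occ, scores = [], None, []
    for i in range(n_agents):
        rng = np.random.default_rng(seed + 1000 * i + 17)
        L, _, _, O, s = pearce_single_run(
            rng, base, n_sessions, trials_per_session, arena, lc_bank, lc_tables
        )
        lat.append(L)
        occ = O if occ is None else occ + O
        scores.append(s)
    return PearceResult(np.array(lat), occ, np.array(scores), arm=arm)


# ---------------------------------------------------------------------- #
# plus maze
# ---------------------------------------------------------------------- #

def classify_strategy(record: TrialRecord, place_state: int, response_state: int) -> str:
    """Label a probe run: ``place`` (trained allocentric goal arm reached),
    ``response`` (arm reached by repeating the trained egocentric turn), or
    ``unclassified`` (step cap hit before either arm end)."""
    if not record.terminal:
        return "unclassified"
    if record.final_state == place_state:
        return "place"
    if record.final_state == response_state:
        return "response"
    return "unclassified"


@dataclass
class PlusMazeResult:
    # proportions[probe][label] over classified agents
    proportions: list[dict]
    deval_proportions: list[dict]
    arm: str = "control"


def _plus_probe(agent, probe_arena, pc_place, pc_response, probe_tables):
    agent_arena = agent.arena
    agent.set_arena(probe_arena, lc_table=probe_tables)
    rec = agent.run_trial(learn=False, start_pose=probe_arena.start_poses[0])
    agent.set_arena(agent_arena)
    return classify_strategy(rec, pc_place, pc_response)


def run_plus_maze(
    n_agents: int = 20,
    arm: str = "control",
    devaluation_factor: float = 0.0,
    n_days: int = 16,
    trials_per_day: int = 6,
    probe_days: tuple[int, ...] = (8, 16),
    lesion_severity: float = 0.9,
    config: AgentConfig | None = None,
    seed: int = 0,
) -> PlusMazeResult:
    """Plus-maze training with probe trials from the opposite arm.

    At each probe day every agent is classified twice: once as trained, and
    once after temporarily devaluing the hippocampal reward representation
    (scaled by ``devaluation_factor``; striatal weights untouched).
    """
    base = config or AgentConfig(beta_softmax=30.0, eta=0.003, alpha_q=0.25)
    if arm == "hpc":
        base = replace(base, hpc_lesion=lesion_severity)
    elif arm == "dls":
        base = replace(base, dls_lesion=lesion_severity)
    elif arm != "control":
        raise ValueError(f"unknown arm {arm!r}")
    train = build_arena("plus_maze")
    probe = build_arena("plus_maze", probe=True)
    lc_bank = build_lc_bank(["center"], radii=(1.0, 2.0, 3.0), sigma_d=1.0)
    train_tables = feature_table_lc(train, lc_bank)
    probe_tables = feature_table_lc(probe, lc_bank)
    # probe starts in the north arm heading south; trained turn (S->W, a
    # right turn at the center) now leads east.
    pc_place = probe.state_at((-3.0, 0.0))  # west arm end (trained goal)
    pc_response = probe.state_at((3.0, 0.0))  # east arm end
    labels: dict[int, list[str]] = {d: [] for d in probe_days}
    deval_labels: dict[int, list[str]] = {d: [] for d in probe_days}
    for i in range(n_agents):
        rng = np.random.default_rng(seed + 1000 * i + 29)
        agent = SpatialAgent(probe, base, rng, lc_bank=lc_bank, lc_table=probe_tables)
        agent.set_arena(train, lc_table=train_tables)
        trial = 0
        for day in range(1, n_days + 1):
            for _ in range(trials_per_day):
                agent.run_trial(trial=trial)
                trial += 1
            if day in probe_days:
                labels[day].append(
                    _plus_probe(agent, probe, pc_place, pc_response, probe_tables)
                )
                saved = agent.hpc.R.copy()
                devalue(agent.hpc.R, devaluation_factor)
                deval_labels[day].append(
                    _plus_probe(agent, probe, pc_place, pc_response, probe_tables)
                )
                agent.hpc.R = saved
    def props(lab_lists):
        out = []
        for d in probe_days:
            ls = [l for l in lab_lists[d] if l != "unclassified"]
            n = max(len(ls), 1)
            out.append(
                {
                    "day": d,
                    "place": sum(l == "place" for l in ls) / n,
                    "response": sum(l == "response" for l in ls) / n,
                    "n": len(ls),
                    "unclassified": len(lab_lists[d]) - len(ls),
                }
            )
        return out

    return PlusMazeResult(props(labels), props(deval_labels), arm=arm)


# ---------------------------------------------------------------------- #
# blocking
# ---------------------------------------------------------------------- #

_BLOCK_PLATFORM = (2.0, 1.0)
_LEFT_WALL = ((-6.0, -5.0), (-6.0, 5.0))
_RIGHT_WALL = ((6.0, -5.0), (6.0, 5.0))


@dataclass
class BlockingResult:
    escape: np.ndarray  # (n_agents, n_trials)
    phase_len: int = 10
    condition: str = "landmark"

    def phase_means(self) -> np.ndarray:
        k = self.phase_len
        return np.array(
            [
                self.escape[:, :k].mean(),
                self.escape[:, k : 2 * k].mean(),
                self.escape[:, 2 * k :].mean(),
            ]
        )


def _blocking_arena(condition: str, phase: int, max_steps: int):
    p = np.asarray(_BLOCK_PLATFORM)
    landmarks, walls = [], []
    if condition == "landmark":
        l1 = (tuple(p + (3.0, 0.0)), "L1")
        l2 = (tuple(p + (-2.0, 2.0)), "L2")
        landmarks = [[l1], [l1, l2], [l2]][phase]
    else:
        walls = [[_LEFT_WALL], [_LEFT_WALL, _RIGHT_WALL], [_RIGHT_WALL]][phase]
    return build_arena(
        "open_field",
        size=20,
        landmarks=landmarks,
        walls=walls,
        goal=(tuple(p), 1.5, 1.0),
        start_poses=[(0.0, -9.5, 2), (0.0, 9.5, 6)],
        max_steps=max_steps,
    )


def run_blocking(
    n_agents: int = 20,
    condition: str = "landmark",
    trials_per_phase: int = 10,
    max_steps: int = 500,
    config: AgentConfig | None = None,
    seed: int = 0,
) -> BlockingResult:
    """Three-phase blocking protocol (cue A, compound AB, B alone).

    In the landmark condition there are no boundaries, place-cell input is
    absent and behavior is carried by the striatal system; in the boundary
    condition there are no landmarks and behavior is carried by the
    hippocampal successor-feature system over boundary-driven place cells.
    """
    if condition not in {"landmark", "boundary"}:
        raise ValueError(f"unknown condition {condition!r}")
    arenas = [_blocking_arena(condition, ph, max_steps) for ph in range(3)]
    if condition == "landmark":
        base = config or AgentConfig(hpc_lesion=1.0, beta_softmax=50.0, alpha_q=0.1)
        lc_bank = build_lc_bank(["L1", "L2"])
        lc_tables = [feature_table_lc(a, lc_bank) for a in arenas]
        pc_bank, pc_tables = None, [None] * 3
    else:
        base = config or AgentConfig(
            dls_lesion=1.0,
            hpc_form="sf",
            beta_softmax=30.0,
            alpha_m=0.1,
            sf_lambda=0.9,
            alpha_r=0.6,
        )
        lc_bank, lc_tables = None, [None] * 3
        pc_bank = build_place_cell_bank(
            arenas[1], spacing=2, mode="per_wall", threshold_frac=0.5
        )
        pc_tables = [feature_table_pc(a, pc_bank, walls=a.walls) for a in arenas]
    n_trials = 3 * trials_per_phase
    escape = np.zeros((n_agents, n_trials))
    for i in range(n_agents):
        rng = np.random.default_rng(seed + 1000 * i + 41)
        agent = SpatialAgent(
            arenas[0],
            base,
            rng,
            lc_bank=lc_bank,
            pc_bank=pc_bank,
            lc_table=lc_tables[0],
            pc_table=pc_tables[0],
        )
        for trial in range(n_trials):
            phase = trial // trials_per_phase
            if trial % trials_per_phase == 0 and trial > 0:
                agent.set_arena(arenas[phase], lc_table=lc_tables[phase], pc_table=pc_tables[phase])
            # counterbalanced start positions, as in the behavioral protocols
            start = arenas[phase].start_poses[trial % len(arenas[phase].start_poses)]
            rec = agent.run_trial(trial=trial, start_pose=start)
            escape[i, trial] = rec.steps
    return BlockingResult(escape, trials_per_phase, condition)


# ---------------------------------------------------------------------- #
# two-step task
# ---------------------------------------------------------------------- #

def run_two_step(
    rng: np.random.Generator,
    model: str = "full",
    n_trials: int = 300,
    variant: str = "daw_two_step",
    config: AgentConfig | None = None,
    lesion_severity: float = 1.0,
):
    """One agent on the two-step task; returns the trial records.

    ``model``: ``dls_only`` (HPC lesioned), ``hpc_only`` (DLS lesioned) or
    ``full`` (reliability arbitration).
    """
    cfg = config or AgentConfig(
        beta_softmax=5.0,
        sr_init="identity",
        dls_features="one_hot",
        ego_actions=False,
        lam=0.9,
        alpha_q=0.3,
        alpha_m=0.3,
        alpha_r=0.6,
        eta=0.01,
    )
    if model == "dls_only":
        cfg = replace(cfg, hpc_lesion=lesion_severity)
    elif model == "hpc_only":
        cfg = replace(cfg, dls_lesion=lesion_severity)
    elif model != "full":
        raise ValueError(f"unknown model arm {model!r}")
    graph = build_task_graph(variant, rng=rng)
    agent = GraphAgent(graph, cfg, rng)
    records = [agent.run_trial(trial=t) for t in range(n_trials)]
    return records, agent


def two_step_stay_table(
    model: str = "full",
    n_agents: int = 20,
    n_trials: int = 300,
    seed: int = 0,
    **kw,
) -> StayTable:
    """Population-average stay table for one model arm."""
    tables = []
    for i in range(n_agents):
        rng = np.random.default_rng(seed + 1000 * i + 53)
        records, _ = run_two_step(rng, model=model, n_trials=n_trials, **kw)
        tables.append(stay_probabilities(records).as_array())
    arr = np.nanmean(np.array(tables), axis=0)
    return StayTable(arr[0, 0], arr[0, 1], arr[1, 0], arr[1, 1])


# ---------------------------------------------------------------------- #
# correlation study
# ---------------------------------------------------------------------- #

@dataclass
class CorrelationResult:
    mb: np.ndarray
    memory: np.ndarray  # place-memory distances (smaller = stronger)
    r: float
    z: float
    p: float
    n_excluded: int
    arm: str = "intact"


def sample_heterogeneous_config(
    rng: np.random.Generator,
    log_ratio_range=(-5.0, 5.0),
    beta_range=(8.0, 12.0),
) -> AgentConfig:
    """Sample one agent's hippocampal-striatal tradeoff parameters.

    The tradeoff is controlled by the log ratio ``x = ln(A_alpha / A_beta)``
    of the two arbitration transition-rate amplitudes, drawn uniformly: the
    equilibrium SR influence ``P_SR = alpha / (alpha + beta)`` is strictly
    increasing in ``x`` in every task (only the operating point shifts with
    each task's error statistics), so a single draw spans agents from
    striatally to hippocampally dominated in a task-consistent way.
    Amplitudes are capped at 1 so the influence dynamics remain stable.  The
    softmax inverse temperature is drawn uniformly as well.
    """
    x = float(rng.uniform(*log_ratio_range))
    return AgentConfig(
        arb_params=ArbitrationParams(
            A_alpha=float(min(1.0, np.exp(x))),
            A_beta=float(min(1.0, np.exp(-x))),
        ),
        beta_softmax=float(rng.uniform(*beta_range)),
    )


def run_correlation_study(
    n_agents: int = 20,
    n_trials_two_step: int = 500,
    n_sessions: int = 11,
    lesion_severity: float = 0.9,
    seed: int = 0,
    arms: tuple[str, ...] = ("intact", "lesioned"),
):
    """MB planning versus allocentric place memory across agents.

    Each sampled agent performs the two-step task (yielding an MB index)
    and the moving-platform water maze (yielding a place-memory distance).
    The association within each arm is reported as Fisher's z of the
    Pearson correlation between MB index and place-memory *strength*
    (negated distance), and the two arms' correlations are compared with
    the Fisher r-to-z difference test.
    """
    arena = build_arena("water_maze", n_sessions=n_sessions)
    lc_bank = build_lc_bank(["cue"])
    lc_tables = _pearce_tables(arena, n_sessions, lc_bank)
    results: dict[str, CorrelationResult] = {}
    for arm in arms:
        mbs, mems = [], []
        for i in range(n_agents):
            rng = np.random.default_rng(seed + 1000 * i + (67 if arm == "intact" else 71))
            cfg = sample_heterogeneous_config(rng)
            if arm == "lesioned":
                cfg = replace(cfg, hpc_lesion=lesion_severity)
            records, _ = run_two_step(
                rng,
                model="full",
                n_trials=n_trials_two_step,
                config=replace(
                    cfg,
                    sr_init="identity",
                    dls_features="one_hot",
                    ego_actions=False,
                    alpha_q=0.3,
                    alpha_m=0.3,
                    alpha_r=0.6,
                    eta=0.01,
                ),
            )
            mbs.append(mb_index(records))
            spatial_cfg = replace(cfg, beta_softmax=50.0, eta=1e-3, alpha_q=0.3, alpha_r=0.5)
            _, _, _, _, score = pearce_single_run(
                rng, spatial_cfg, n_sessions, 4, arena, lc_bank, lc_tables
            )
            mems.append(score)
        mb = np.array(mbs)
        mem = np.array(mems)
        ok = np.isfinite(mb) & np.isfinite(mem)
        r, z, p = association_z(mb[ok], -mem[ok])
        results[arm] = CorrelationResult(
            mb, mem, r, z, p, int((~ok).sum()), arm=arm
        )
    out = {"arms": results}
    if {"intact", "lesioned"} <= set(results):
        ri, rl = results["intact"], results["lesioned"]
        ni = int(np.isfinite(ri.mb).sum())
        nl = int(np.isfinite(rl.mb).sum())
        zd, pd = compare_correlations(ri.r, ni, rl.r, nl)
        out["z_diff"], out["p_diff"] = zd, pd
    return out
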