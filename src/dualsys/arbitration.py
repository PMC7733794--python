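"""Reliability-weighted arbitration between the two systems.

Each system's reliability is tracked from a Pearce-Hall-style running
average of its absolute prediction errors (reward-prediction errors for the
model-free striatal system, successor prediction errors for the SR system):

    Omega <- Omega + eta (|delta| - Omega)
    chi = (delta_max - min(Omega, delta_max)) / delta_max

Reliabilities drive a push-pull differential equation over the proportion of
influence of the SR system, P_SR, via logistic transition rates:

    alpha(chi_MF) = A_alpha / (1 + exp(B_alpha chi_MF))    (MF -> SR)
    beta(chi_SR)  = A_beta  / (1 + exp(B_beta  chi_SR))    (SR -> MF)
    dP_SR/dt = alpha (1 - P_SR) - beta P_SR

so an unreliable MF system pushes influence toward the SR system and vice
versa; the equilibrium is alpha / (alpha + beta).  The default steepness
asymmetry (B_alpha >> B_beta) suppresses MF->SR transitions sharply once the
MF system is reliable, expressing a bias toward the computationally cheaper
system.  Lesions and partial inactivations clamp P_SR to a subinterval of
[0, 1]; a full hippocampal lesion pins P_SR = 0 and a full striatal lesion
pins P_SR = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArbitrationParams",
    "InfluenceState",
    "Arbitrator",
    "update_omega",
    "reliability",
    "transition_rates",
    "update_psr",
    "apply_lesion",
    "sr_spe_magnitude",
]


def update_omega(omega: float, abs_delta: float, eta: float) -> float:
    """Running average of absolute prediction errors."""
    if abs_delta < 0:
        raise ValueError("|delta| must be nonnegative")
    return omega + eta * (abs_delta - omega)


def reliability(omega: float, delta_max: float = 1.0) -> float:
    """Reliability chi = (delta_max - min(Omega, delta_max)) / delta_max."""
    if delta_max <= 0:
        raise ValueError("delta_max must be positive")
    return (delta_max - min(omega, delta_max)) / delta_max


@dataclass(frozen=True)
class ArbitrationParams:
    """Amplitudes and steepnesses of the two logistic transition rates."""

    A_alpha: float = 1.0
    B_alpha: float = 10.0
    A_beta: float = 1.0
    B_beta: float = 6.0

    def __post_init__(self):
        if self.A_alpha <= 0 or self.A_beta <= 0:
            raise ValueError("transition-rate amplitudes must be positive")


def transition_rates(
    chi_mf: float, chi_sr: float, params: ArbitrationParams
) -> tuple[float, float]:
    """Logistic transition rates (alpha: MF->SR, beta: SR->MF)."""
    alpha = params.A_alpha / (1.0 + np.exp(params.B_alpha * chi_mf))
    beta = params.A_beta / (1.0 + np.exp(params.B_beta * chi_sr))
    return float(alpha), float(beta)


@dataclass
class InfluenceState:
    """P_SR plus its lesion clamp interval."""

    psr: float = 0.5
    psr_min: float = 0.0
    psr_max: float = 1.0

    def clamp(self) -> None:
        self.psr = float(np.clip(self.psr, self.psr_min, self.psr_max))


def update_psr(state: InfluenceState, alpha: float, beta: float, dt: float = 1.0) -> float:
    """Euler step of the push-pull influence dynamics, then clamp."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.psr += dt * (alpha * (1.0 - state.psr) - beta * state.psr)
    state.psr = float(np.clip(state.psr, 0.0, 1.0))
    state.clamp()
    return state.psr


def apply_lesion(state: InfluenceState, target: str, severity: float) -> InfluenceState:
    """Clamp P_SR to model a lesion or partial inactivation.

    A hippocampal lesion lowers the upper clamp toward 0 (less SR influence);
    a striatal lesion raises the lower clamp toward 1.  ``severity=1`` pins
    P_SR entirely.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    if target == "HPC":
        state.psr_max = min(state.psr_max, 1.0 - severity)
    elif target == "DLS":
        state.psr_min = max(state.psr_min, severity)
    else:
        raise ValueError(f"unknown lesion target {target!r}")
    state.clamp()
    return state


def sr_spe_magnitude(
    delta_m: np.ndarray, delta_max: float = 1.0, scale: float = 1.0
) -> float:
    """Scalar reduction of the SPE vector: max-norm clipped to [0, delta_max].

    The max-norm is bounded and order-invariant.  ``scale`` rescales the raw
    SPE before clipping; the agent uses ``scale = 1 - gamma``, i.e. the error
    on the *normalized* discounted-occupancy distribution, so that successor
    errors live on the same [0, 1] scale as the reward-prediction errors
    (raw SR entries grow as 1/(1-gamma) and would otherwise saturate the
    clip).
    """
    if delta_m.size == 0:
        return 0.0
    return float(min(scale * np.max(np.abs(delta_m)), delta_max))


@dataclass
class Arbitrator:
    """Bundles both reliability trackers and the influence dynamics."""

    params: ArbitrationParams = field(default_factory=ArbitrationParams)
    eta: float = 0.03
    delta_max: float = 1.0
    omega_mf: float = 1.0  # MF starts maximally unreliable (no reward learning yet)
    omega_sr: float = 0.1  # prior SR mismatch at episode start is small
    influence: InfluenceState = field(default_factory=InfluenceState)
    dt: float = 1.0
    spe_scale: float = 1.0  # rescales SPEs to the normalized-occupancy scale

    @property
    def chi_mf(self) -> float:
        return reliability(self.omega_mf, self.delta_max)

    @property
    def chi_sr(self) -> float:
        return reliability(self.omega_sr, self.delta_max)

    @property
    def psr(self) -> float:
        return self.influence.psr

    def lesion(self, target: str, severity: float) -> None:
        apply_lesion(self.influence, target, severity)

    def step(self, abs_rpe: float, delta_m: np.ndarray | float) -> float:
        """Update both reliabilities and advance P_SR by one time step."""
        spe = sr_spe_magnitude(
            np.asarray(delta_m, dtype=float).ravel(), self.delta_max, self.spe_scale
        )
        self.omega_mf = update_omega(self.omega_mf, min(abs_rpe, self.delta_max), self.eta)
        self.omega_sr = update_omega(self.omega_sr, spe, self.eta)
        alpha, beta = transition_rates(self.chi_mf, self.chi_sr, self.params)
        return update_psr(self.influence, alpha, beta, self.dt)
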