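"""Levodopa pharmacokinetics and terminal pharmacodynamics.

An oral dose enters a gut depot and is absorbed first-order into the
central (plasma) compartment, exchanges with a peripheral compartment and
is cleared; the full linear system is advanced with the exact matrix
exponential, so mass balance and superposition hold to machine precision.
Plasma levodopa is transported into dopaminergic terminals through the
aromatic amino-acid transporter (AAT), in competition with tyrosine and
tryptophan, and converted to dopamine by aromatic amino-acid decarboxylase
(AADC).

Units: amounts in mg, concentrations in mg/L, rate constants in 1/h,
volumes in L.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

__all__ = [
    "PKParams",
    "PKState",
    "DoseSchedule",
    "pk_step",
    "simulate_pk",
    "aat_transport_flux",
    "terminal_ldopa_step",
]


@dataclass(frozen=True)
class PKParams:
    """Two-compartment PK constants.

    Defaults give a plasma peak within about an hour of an oral dose and
    near-complete washout by ~6 h, matching a 10-h observation window.
    ``literal_infusion=True`` switches to the literal constant-infusion
    reading of the absorption term (the depot then drains at a constant
    rate ``k01 * dose`` until exhausted) for fidelity testing.
    """

    V_CC: float = 11.0   # central volume (L)
    V_PC: float = 27.0   # peripheral volume (L)
    k01: float = 2.5     # absorption rate (1/h)
    k12: float = 0.2     # central -> peripheral (L/h as printed flux coeff)
    k21: float = 0.4     # peripheral -> central
    k1e: float = 2.8     # clearance from central
    literal_infusion: bool = False

    def __post_init__(self) -> None:
        for name in ("V_CC", "V_PC", "k01", "k12", "k21", "k1e"):
            if getattr(self, name) < 0 or (name.startswith("V") and getattr(self, name) <= 0):
                raise ValueError(f"PKParams.{name} invalid")

    def system_matrix(self) -> np.ndarray:
        """Generator of the linear ODE in x = [depot, C_cc, C_pc]."""
        return np.array(
            [
                [-self.k01, 0.0, 0.0],
                [self.k01 / self.V_CC, -(self.k12 + self.k1e) / self.V_CC, self.k21 / self.V_CC],
                [0.0, self.k12 / self.V_PC, -self.k21 / self.V_PC],
            ]
        )


@dataclass(frozen=True)
class PKState:
    """Gut depot (mg), central and peripheral concentrations (mg/L), clock (h)."""

    depot: float = 0.0
    LDOPA_CC: float = 0.0
    LDOPA_PC: float = 0.0
    t: float = 0.0

    def total_mass(self, params: PKParams) -> float:
        return self.depot + params.V_CC * self.LDOPA_CC + params.V_PC * self.LDOPA_PC

    def with_dose(self, dose_mg: float) -> "PKState":
        return replace(self, depot=self.depot + dose_mg)


@dataclass(frozen=True)
class DoseSchedule:
    """Oral doses as (time_h, dose_mg) pairs over a simulation horizon."""

    doses: tuple[tuple[float, float], ...] = ()
    horizon_h: float = 12.0
    sample_every_h: float = 0.5

    def __post_init__(self) -> None:
        ts = [t for t, _ in self.doses]
        if any(t < 0 for t in ts) or sorted(ts) != list(ts):
            raise ValueError("dose times must be non-negative and sorted")
        if self.horizon_h <= 0 or self.sample_every_h <= 0:
            raise ValueError("horizon and sampling interval must be > 0")


def pk_step(state: PKState, params: PKParams, dt_h: float) -> PKState:
    """Advance the PK state by ``dt_h`` hours (exact linear propagator)."""
    if dt_h <= 0:
        raise ValueError("dt_h must be > 0")
    x = np.array([state.depot, state.LDOPA_CC, state.LDOPA_PC])
    if params.literal_infusion and state.depot > 0:
        # constant influx k01 * initial-dose until the depot empties; within a
        # short step the depot drain is approximated as linear
        rate = params.k01 * state.depot
        drained = min(rate * dt_h, state.depot)
        m = params.system_matrix().copy()
        m[0, 0] = 0.0
        m[1, 0] = 0.0
        x2 = x + m @ x * dt_h
        x2[0] = x[0] - drained
        x2[1] += drained / params.V_CC
    else:
        x2 = expm(params.system_matrix() * dt_h) @ x
    x2 = np.maximum(x2, 0.0)
    if not np.all(np.isfinite(x2)):
        raise ArithmeticError("PK integration produced non-finite state")
    return PKState(depot=float(x2[0]), LDOPA_CC=float(x2[1]), LDOPA_PC=float(x2[2]), t=state.t + dt_h)


def simulate_pk(
    schedule: DoseSchedule, params: PKParams, dt_h: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Plasma concentration curve over the schedule horizon.

    Returns ``(times_h, LDOPA_CC)`` sampled on the integration grid.  The
    system is linear, so doubling every dose doubles the whole curve.
    """
    n = int(round(schedule.horizon_h / dt_h))
    times = np.arange(n + 1) * dt_h
    conc = np.zeros(n + 1)
    state = PKState()
    prop = expm(params.system_matrix() * dt_h)  # reused exact one-step propagator
    pending = list(schedule.doses)
    for i, t in enumerate(times):
        while pending and pending[0][0] <= t + 1e-12:
            state = state.with_dose(pending.pop(0)[1])
        conc[i] = state.LDOPA_CC
        if i < n:
            if params.literal_infusion:
                state = pk_step(state, params, dt_h)
            else:
                x = prop @ np.array([state.depot, state.LDOPA_CC, state.LDOPA_PC])
                state = PKState(float(x[0]), float(x[1]), float(x[2]), t + dt_h)
    return times, conc


def aat_transport_flux(
    ldopa_cc: float,
    tyr_e: float,
    trp_e: float,
    v_max: float,
    K_ldopa_e: float,
    K_tyr_e: float,
    K_trp_e: float,
) -> float:
    """Carrier-mediated levodopa influx with amino-acid competition.

    ``J = Vmax * L / (K_L * (1 + TYR/K_tyr + TRP/K_trp) + L)`` -- a
    Michaelis-Menten flux whose apparent affinity is degraded by the
    competing aromatic amino acids.
    """
    if min(ldopa_cc, tyr_e, trp_e) < 0:
        raise ValueError("concentrations must be >= 0")
    k_app = K_ldopa_e * (1.0 + tyr_e / K_tyr_e + trp_e / K_trp_e)
    return v_max * ldopa_cc / (k_app + ldopa_cc)


def terminal_ldopa_step(
    ldopa: float,
    j_aat: float,
    j_synt: float,
    dt: float,
    V_aadc: float,
    K_aadc: float,
) -> tuple[float, float]:
    """One Euler step of terminal levodopa; returns ``(ldopa, J_ldopa)``.

    ``J_ldopa`` is the AADC conversion flux credited to cytosolic
    dopamine by the caller.  ``dt`` is in the caller's time unit and must
    match the flux units.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    j_ldopa = V_aadc * ldopa / (K_aadc + ldopa)
    new = max(ldopa + dt * (j_aat + j_synt - j_ldopa), 0.0)
    return new, j_ldopa
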