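"""Network of dopaminergic SNc neurons with biochemical terminals.

Each neuron has a reduced single-compartment soma -- a fast inward
current, a delayed-rectifier potassium current with one gating variable,
a passive leak folded into the potassium flux, an L-type calcium current,
a plasma-membrane calcium pump (PMCA) and a sodium-calcium exchanger
(NCX) -- that pacemakes autonomously at a few hertz and whose calcium
oscillations drive the terminal.  The terminal converts tyrosine-derived
levodopa to cytosolic dopamine (AADC), packs it into a vesicular pool
(VMAT) that sets the readily releasable pool, releases it into the
extracellular space with a calcium-dependent probability, and clears it
by DAT reuptake and enzymatic degradation.  Striatal GABA feedback
inhibits the soma; pooled extracellular dopamine is read back out as the
dopamine-derived value difference.

Units: membrane potential in mV, time in ms, intracellular calcium in
uM, terminal levodopa / cytosolic / vesicular dopamine in uM,
extracellular dopamine in nM.  The flux-to-voltage conversion constant
``F * vol_cyt`` is normalised to 1 so fluxes are numerically equal to
currents; the lumped membrane constant ``C_snc * AR_pmu`` appears as
``C_m``.  These nondimensionalisations are documented in the methods
note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ldopa_pkpd import aat_transport_flux

__all__ = [
    "SNcParams",
    "DACalibration",
    "DANetworkState",
    "make_network",
    "gaba_current_from_delta_v",
    "soma_step",
    "release_probability",
    "dopamine_release_flux",
    "synthesis_velocity",
    "synthesis_flux",
    "terminal_step",
    "extracellular_da_step",
    "run_snc_window",
    "equilibrate_terminals",
    "pooled_dopamine",
    "delta_v_from_dopamine",
]

V_DEAD = -80.0  # clamped membrane potential of killed neurons (mV)


@dataclass(frozen=True)
class SNcParams:
    """Soma, terminal and synaptic constants of one SNc neuron.

    Defaults are the shipped fixture values, chosen so the soma pacemakes
    at a few hertz with calcium excursions of a few tenths of a uM, and
    the pooled extracellular dopamine of a healthy population sits near
    50 nM at zero value difference and peaks in the 150-400 nM range when
    striatal inhibition is released.
    """

    # soma (Morris-Lecar-style pacemaker)
    C_m: float = 20.0
    g_fast: float = 4.4
    E_fast: float = 120.0
    V1: float = -1.2
    V2: float = 18.0
    g_K: float = 8.0
    E_K: float = -84.0
    V3: float = 2.0
    V4: float = 30.0
    phi_w: float = 0.04
    g_L: float = 2.0
    E_L: float = -20.0
    # calcium
    g_CaL: float = 0.5
    E_Ca: float = 120.0
    V_ca_half: float = -15.0
    k_ca_slope: float = 7.0
    v_pmca: float = 2.0
    K_pmca: float = 0.3
    v_ncx: float = 4.0
    k_ca_flux: float = 0.002   # converts Ca current (uA-equivalent) to uM/ms
    k_calb: float = 0.01       # calbindin buffering (1/ms)
    k_cam: float = 0.005       # calmodulin buffering (1/ms), enters as 4*J_cam
    # synaptic
    I_nmda_ampa: float = -8.0  # tonic excitatory background (inward, negative)
    I_gaba_max: float = 45.0
    gaba_slope: float = 0.05   # value-difference scale of the GABA sigmoid
    # terminal: synthesis
    V_synt_max: float = 0.02   # uM/ms
    K_synt: float = 0.25       # uM calcium sensitivity (Hill-4)
    K_TYR: float = 46.0        # uM
    TYR: float = 126.0         # uM terminal tyrosine (held constant)
    K_i_cda: float = 110.0     # uM
    K_i_eda: float = 460.0     # nM
    # terminal: AADC conversion and vesicular packing
    V_aadc: float = 0.02       # uM/ms
    K_aadc: float = 130.0      # uM
    V_vmat: float = 0.1        # uM/ms
    K_vmat: float = 0.3        # uM
    k_cdeg: float = 0.0001     # cytosolic MAO degradation (1/ms)
    # release
    psi: float = 22.0         # nM/ms per unit pool, release flux scale
    p_spont: float = 0.09     # calcium-independent spontaneous release probability
    n_max: float = 1.0
    K_v: float = 250.0         # uM vesicular half-filling
    k_vleak: float = 1.0e-5    # vesicular monoamine leak/turnover (1/ms)
    K_rel: float = 0.25        # uM calcium half-point of release (Hill-4)
    # clearance of extracellular dopamine
    V_DAT: float = 6.0         # nM/ms
    K_DAT: float = 200.0       # nM
    k_edao: float = 0.02       # 1/ms
    # AAT transport of plasma levodopa (plasma concentration in mg/L)
    V_aat_max: float = 0.0005  # uM/ms
    K_ldopa_e: float = 1.0     # mg/L
    TYR_e: float = 63.0        # uM
    TRP_e: float = 82.0        # uM
    K_tyr_e: float = 64.0      # uM
    K_trp_e: float = 15.0      # uM


@dataclass(frozen=True)
class DACalibration:
    """Affine map from pooled extracellular dopamine to the SNc-derived
    value difference, with clipping."""

    gain: float = 0.001      # per nM
    offset: float = 50.0     # nM at which the value difference is zero
    delta_min: float = -0.5
    delta_max: float = 0.5


@dataclass
class DANetworkState:
    """Vectorised state of the SNc population (arrays of length N)."""

    V: np.ndarray
    w: np.ndarray
    Ca: np.ndarray
    LDOPA: np.ndarray
    DA_c: np.ndarray
    DA_v: np.ndarray
    DA_e: np.ndarray
    alive: np.ndarray
    het: np.ndarray  # per-neuron multiplicative heterogeneity of g_fast/phi_w

    @property
    def n(self) -> int:
        return self.V.shape[0]

    def copy(self) -> "DANetworkState":
        return DANetworkState(*(a.copy() for a in (
            self.V, self.w, self.Ca, self.LDOPA, self.DA_c,
            self.DA_v, self.DA_e, self.alive, self.het)))


def make_network(
    n: int = 64,
    params: SNcParams | None = None,
    seed: int | np.random.Generator = 0,
    jitter: float = 0.05,
) -> DANetworkState:
    """A healthy SNc population with seeded +-``jitter`` heterogeneity and
    random pacemaking phases."""
    if n < 1:
        raise ValueError("network needs >= 1 neuron")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    het = 1.0 + jitter * rng.uniform(-1, 1, n)
    return DANetworkState(
        V=rng.uniform(-60.0, -20.0, n),
        w=rng.uniform(0.0, 0.3, n),
        Ca=np.full(n, 0.1),
        LDOPA=np.full(n, 3.0),
        DA_c=np.full(n, 10.0),
        DA_v=np.full(n, 250.0),
        DA_e=np.full(n, 50.0),
        alive=np.ones(n, dtype=bool),
        het=het,
    )


def gaba_current_from_delta_v(delta_v: float, params: SNcParams) -> float:
    """Striatal GABAergic inhibition of SNc as a decreasing sigmoid of the
    value difference: half-maximal at zero, saturating to ``I_gaba_max``
    for strongly negative value differences and to zero for strongly
    positive ones."""
    return params.I_gaba_max / (1.0 + np.exp(delta_v / params.gaba_slope))


def _m_inf(V: np.ndarray, p: SNcParams) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh((V - p.V1) / p.V2))


def _w_inf(V: np.ndarray, p: SNcParams) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh((V - p.V3) / p.V4))


def _tau_w(V: np.ndarray, p: SNcParams) -> np.ndarray:
    return 1.0 / np.cosh((V - p.V3) / (2.0 * p.V4))


def _ca_gate(V: np.ndarray, p: SNcParams) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(V - p.V_ca_half) / p.k_ca_slope))


def soma_step(
    state: DANetworkState, params: SNcParams, I_gaba: float, dt: float
) -> None:
    """One Euler step of every living soma (V, w, Ca); dead cells stay
    clamped at the resting potential with zero calcium flux."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = params
    V, w, Ca = state.V, state.w, state.Ca
    alive = state.alive
    I_fast = p.g_fast * state.het * _m_inf(V, p) * (V - p.E_fast)
    I_K = p.g_K * w * (V - p.E_K) + p.g_L * (V - p.E_L)  # leak folded into K flux
    I_CaL = p.g_CaL * _ca_gate(V, p) * (V - p.E_Ca)
    I_pmca = p.v_pmca * Ca / (Ca + p.K_pmca)
    I_NaCaX = -p.v_ncx * Ca            # inward current, calcium extrusion
    J_syn = -(I_gaba + p.I_nmda_ampa)  # F*vol_cyt normalised to 1
    J_Na = -I_fast
    J_K = -I_K
    J_Ca_mem = -(I_CaL + 2.0 * I_pmca - 2.0 * I_NaCaX) / 2.0  # z_Ca = 2
    dV = (J_Na + 2.0 * J_Ca_mem + J_K + J_syn) / p.C_m
    dw = p.phi_w * state.het * (_w_inf(V, p) - w) / _tau_w(V, p)
    dCa = p.k_ca_flux * 2.0 * J_Ca_mem - (p.k_calb + 4.0 * p.k_cam) * Ca
    state.V = np.where(alive, V + dt * dV, V_DEAD)
    state.w = np.where(alive, w + dt * dw, 0.0)
    state.Ca = np.where(alive, np.maximum(Ca + dt * dCa, 0.0), 0.0)
    if not np.all(np.isfinite(state.V)):
        raise ArithmeticError("SNc soma state blew up; reduce dt")


def release_probability(Ca: np.ndarray, K_rel: float) -> np.ndarray:
    """Fourth-order Hill function of intracellular calcium, in [0, 1]."""
    ca = np.maximum(np.asarray(Ca, float), 0.0)
    c4 = ca**4
    return c4 / (K_rel**4 + c4)


def dopamine_release_flux(
    psi: float, n_rrp: np.ndarray, p_rel: np.ndarray
) -> np.ndarray:
    """Release flux = per-vesicle flux * releasable pool * release
    probability."""
    return psi * n_rrp * p_rel


def synthesis_velocity(Ca: np.ndarray, params: SNcParams) -> np.ndarray:
    """Calcium-dependent maximal levodopa synthesis velocity (Hill-4)."""
    ca = np.maximum(np.asarray(Ca, float), 0.0)
    c4 = ca**4
    return params.V_synt_max * c4 / (params.K_synt**4 + c4)


def synthesis_flux(
    V_synt: np.ndarray,
    DA_c: np.ndarray,
    DA_e: np.ndarray,
    params: SNcParams,
    TYR: float | None = None,
) -> np.ndarray:
    """Tyrosine-hydroxylase flux with substrate limitation and end-product
    inhibition by cytosolic and extracellular dopamine (autoreceptors)."""
    tyr = params.TYR if TYR is None else TYR
    if tyr <= 0:
        raise ValueError("terminal tyrosine must be > 0")
    inhib = 1.0 + (params.K_TYR / tyr) * (
        1.0 + DA_c / params.K_i_cda + DA_e / params.K_i_eda
    )
    return V_synt / inhib


def extracellular_da_step(
    DA_e: np.ndarray, J_rel: np.ndarray, params: SNcParams, dt: float
) -> np.ndarray:
    """Euler update of extracellular dopamine: release minus saturable DAT
    reuptake minus first-order enzymatic degradation; clipped at zero."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    J_dat = params.V_DAT * DA_e / (params.K_DAT + DA_e)
    J_edao = params.k_edao * DA_e
    return np.maximum(DA_e + dt * (J_rel - J_dat - J_edao), 0.0)


def terminal_step(
    state: DANetworkState,
    params: SNcParams,
    plasma_ldopa: float,
    dt: float,
) -> None:
    """One Euler step of every terminal (levodopa, cytosolic, vesicular and
    extracellular dopamine).  ``plasma_ldopa`` is the plasma levodopa
    concentration in mg/L (0 when unmedicated)."""
    p = params
    alive = state.alive
    v_synt = synthesis_velocity(state.Ca, p)
    j_synt = synthesis_flux(v_synt, state.DA_c, state.DA_e, p)
    j_aat = aat_transport_flux(
        plasma_ldopa, p.TYR_e, p.TRP_e, p.V_aat_max,
        p.K_ldopa_e, p.K_tyr_e, p.K_trp_e,
    )
    j_aadc = p.V_aadc * state.LDOPA / (p.K_aadc + state.LDOPA)
    j_vmat = p.V_vmat * state.DA_c / (p.K_vmat + state.DA_c)
    n_rrp = p.n_max * state.DA_v / (p.K_v + state.DA_v)
    p_rel = release_probability(state.Ca, p.K_rel) + p.p_spont
    j_rel = dopamine_release_flux(p.psi, n_rrp, p_rel)
    state.LDOPA = np.where(
        alive, np.maximum(state.LDOPA + dt * (j_aat + j_synt - j_aadc), 0.0), 0.0
    )
    state.DA_c = np.where(
        alive,
        np.maximum(state.DA_c + dt * (j_aadc - j_vmat - p.k_cdeg * state.DA_c), 0.0),
        0.0,
    )
    # vesicular pool in uM; release drains it at the nM release scale / 1000
    state.DA_v = np.where(
        alive,
        np.maximum(state.DA_v + dt * (j_vmat - j_rel / 1000.0
                                      - p.k_vleak * state.DA_v), 0.0),
        0.0,
    )
    state.DA_e = np.where(
        alive, extracellular_da_step(state.DA_e, j_rel, p, dt), 0.0
    )


def run_snc_window(
    state: DANetworkState,
    params: SNcParams,
    I_gaba: float,
    n_steps: int = 2000,
    dt: float = 0.025,
    plasma_ldopa: float = 0.0,
    terminal_every: int = 10,
    use_fastpath: bool = True,
) -> float:
    """Advance the population through one behavioural window.

    The soma integrates every fine step; the (much slower) terminal
    chemistry integrates every ``terminal_every``-th step with a
    correspondingly larger timestep.  Returns the pooled extracellular
    dopamine averaged over the window (nM) -- the quantity the striatum
    integrates over a behavioural step.
    """
    from . import _fastpath as _fp

    if use_fastpath and _fp.HAVE_NUMBA:
        p = params
        j_aat = aat_transport_flux(
            plasma_ldopa, p.TYR_e, p.TRP_e, p.V_aat_max,
            p.K_ldopa_e, p.K_tyr_e, p.K_trp_e,
        )
        da = _fp.snc_window_kernel(
            state.V, state.w, state.Ca, state.LDOPA, state.DA_c,
            state.DA_v, state.DA_e, state.alive, state.het,
            _fp.snc_param_vector(p), float(I_gaba), float(j_aat),
            n_steps, dt, terminal_every,
        )
        if not np.all(np.isfinite(state.V)):
            raise ArithmeticError("SNc soma state blew up; reduce dt")
        return float(da)

    dt_term = dt * terminal_every
    da_sum, da_count = 0.0, 0
    for i in range(n_steps):
        soma_step(state, params, I_gaba, dt)
        if (i + 1) % terminal_every == 0:
            terminal_step(state, params, plasma_ldopa, dt_term)
            da_sum += pooled_dopamine(state)
            da_count += 1
    return da_sum / max(da_count, 1)


def equilibrate_terminals(
    state: DANetworkState,
    params: SNcParams,
    plasma_ldopa: float,
    duration_s: float = 300.0,
    dt_ms: float = 20.0,
) -> None:
    """Fast-forward the terminal chemistry to its quasi-steady state for a
    sustained plasma levodopa level, holding calcium at its running value.

    Used when a medication session samples the plasma curve: the slow
    pools (levodopa, cytosolic and vesicular dopamine) reach equilibrium
    over minutes of exposure, far longer than a 5-s reaching trial.
    """
    n = int(round(duration_s * 1000.0 / dt_ms))
    for _ in range(n):
        terminal_step(state, params, plasma_ldopa, dt_ms)


def pooled_dopamine(state: DANetworkState) -> float:
    """Striatal dopamine pool: per-terminal extracellular dopamine summed
    over living cells and scaled by the configured population size, so the
    pool shrinks proportionally with cell death."""
    if state.n < 1:
        raise ValueError("empty SNc network")
    return float(np.sum(state.DA_e[state.alive]) / state.n)


def delta_v_from_dopamine(DA_e: float, calib: DACalibration) -> float:
    """Affine read-out of pooled dopamine as a value difference, clipped to
    the configured range (the floor is the negative value reported for a
    fully silent pool)."""
    raw = calib.gain * (DA_e - calib.offset)
    return float(np.clip(raw, calib.delta_min, calib.delta_max))
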