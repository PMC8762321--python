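"""Multi-rate scheduler wiring the sensory-motor, cortico-BG and
nigrostriatal loops, plus training, calibration and experiment protocols.

One behavioural step is 50 ms.  Within each step the SNc-striatum loop
runs 2000 fine iterations (0.025 ms) and the STN-GPe lattice 2500
iterations (0.02 ms); the motor-cortex and thalamus attractor networks
take one Euler step per behavioural step.  A reaching trial lasts at most
100 behavioural steps (5 s); a trial that never enters the reach
threshold is non-reachable.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import zoom

from . import arm_model as arm
from . import basal_ganglia as bg
from . import cortical_maps as cm
from . import ldopa_pkpd as pk
from . import metrics as mx
from . import pd_lesion as pdl
from . import snc_dopamine as snc
from .config import SimulationConfig, dump_config

__all__ = [
    "TrainedMaps",
    "SessionResult",
    "train_model",
    "run_reach_trial",
    "calibrate",
    "pd_sweep",
    "ldopa_session",
    "dose_grid",
    "capped_movement_time",
]

TRIAL_HORIZON_S = 5.0


# ---------------------------------------------------------------------------
# Trained maps
# ---------------------------------------------------------------------------

@dataclass
class TrainedMaps:
    """All trained cortical structures needed for a reach-only run."""

    pc_som: cm.SOMNetwork
    pfc_som: cm.SOMNetwork
    mc_som: cm.SOMNetwork
    W_pfc_mc: np.ndarray
    W_mc_mn: np.ndarray
    trained: bool = True
    loop_mae: float = float("nan")

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name, som in (("PC", self.pc_som), ("PFC", self.pfc_som), ("MC", self.mc_som)):
                f.create_dataset(f"W_{name}", data=som.W)
                f[f"W_{name}"].attrs["sigma_resp"] = som.sigma_resp
            f.create_dataset("W_PFC_MC", data=self.W_pfc_mc)
            f.create_dataset("W_MC_MN", data=self.W_mc_mn)
            f.attrs["trained"] = self.trained
            f.attrs["loop_mae"] = self.loop_mae

    @classmethod
    def load(cls, path) -> "TrainedMaps":
        import h5py

        with h5py.File(path, "r") as f:
            soms = {
                name: cm.SOMNetwork(
                    W=f[f"W_{name}"][...],
                    sigma_resp=float(f[f"W_{name}"].attrs["sigma_resp"]),
                )
                for name in ("PC", "PFC", "MC")
            }
            return cls(
                pc_som=soms["PC"],
                pfc_som=soms["PFC"],
                mc_som=soms["MC"],
                W_pfc_mc=f["W_PFC_MC"][...],
                W_mc_mn=f["W_MC_MN"][...],
                trained=bool(f.attrs["trained"]),
                loop_mae=float(f.attrs["loop_mae"]),
            )


def _init_som(samples: np.ndarray, N: int, sigma: float, rng) -> cm.SOMNetwork:
    idx = rng.integers(0, samples.shape[0], size=N * N)
    W = samples[idx].reshape(N, N, samples.shape[1]).astype(float)
    W = W + 0.01 * samples.std(axis=0) * rng.standard_normal(W.shape)
    return cm.SOMNetwork(W=W, sigma_resp=sigma)


def _mc_cann(cfg: SimulationConfig) -> cm.CANNNetwork:
    c = cfg.maps.mc_cann
    return cm.CANNNetwork(N=cfg.maps.N_mc, tau=c.tau, A_lat=c.A_lat,
                          sigma_lat=c.sigma_lat, K=c.K, b=c.b)


def _thal_cann(cfg: SimulationConfig) -> cm.CANNNetwork:
    c = cfg.maps.thal_cann
    return cm.CANNNetwork(N=cfg.maps.N_thal, tau=c.tau, A_lat=c.A_lat,
                          sigma_lat=c.sigma_lat, K=c.K, b=c.b)


def _relax_mc(cfg: SimulationConfig, I_grid: np.ndarray) -> np.ndarray:
    """Steady MC CANN output for a static input (used during training)."""
    net = _mc_cann(cfg)
    G = cm.cann_output(net)
    for _ in range(cfg.maps.mc_relax_steps):
        G = cm.cann_step(net, I_grid, cfg.timing.dt_mc_ms)
    return G


def train_model(cfg: SimulationConfig, seed: int | None = None,
                max_attempts: int = 3) -> TrainedMaps:
    """Train all maps from motor babbling, restarting on failed convergence.

    Training is stochastic (babbling, map initialisation); occasionally a
    realisation leaves the closed-loop equilibrium for the configured
    target outside the reach threshold.  Each attempt is validated by
    ``target_equilibrium_error``; a failed attempt restarts with a derived
    seed (multi-initialisation, as in clustering).  If no attempt passes,
    the best one is returned rather than failing silently.
    """
    seed = cfg.seed if seed is None else seed
    best, best_score = None, np.inf
    for attempt in range(max_attempts):
        attempt_seed = (seed + attempt * 1000003) % (2**31)
        maps = _train_model_once(cfg, attempt_seed)
        hover = target_equilibrium_error(cfg, maps)
        score = hover + maps.loop_mae
        if hover <= 0.07 and maps.loop_mae <= 0.1:
            # full closed-loop probes: two reaching trials with the
            # fixture's calibration must both succeed briskly
            ok = True
            for k in (1, 2):
                probe = run_reach_trial(
                    cfg, maps, seed=(attempt_seed + k) % 97 + 1,
                    record_stn=False)
                if not (probe.metrics.reached
                        and probe.metrics.movement_time <= 1.5):
                    ok = False
                    break
            if ok:
                return maps
            score += 1.0
        if score < best_score:
            best, best_score = maps, score
    return best


def target_equilibrium_error(cfg: SimulationConfig, maps: TrainedMaps,
                             n_steps: int = 30) -> float:
    """Distance from the configured target of the BG-free closed-loop
    equilibrium (posture/recall mixture iterated to convergence)."""
    geom = _geom(cfg)
    target = np.asarray(cfg.target, float)
    u_pfc = cm.som_activation(target, maps.pfc_som)
    recall = cm.pfc_drive(u_pfc, maps.W_pfc_mc)
    phi_vec = np.asarray(cfg.arm.start_phi, float)
    net = _mc_cann(cfg)
    for _ in range(n_steps):
        st = arm.arm_state_from_activations(arm.MuscleActivations(phi_vec), geom)
        u = cm.som_activation(st.M_L, maps.pc_som)
        g_pc = cm.som_activation(u.ravel(), maps.mc_som)
        G = cm.cann_step(net, cfg.bg.A_PC * g_pc + cfg.bg.A_PFC * recall,
                         cfg.timing.dt_mc_ms)
        phi_vec = cm.mn_activation(G, maps.W_mc_mn, cfg.bg.A_MN)
    st = arm.arm_state_from_activations(arm.MuscleActivations(phi_vec), geom)
    return float(np.linalg.norm(st.X_arm - target))


def _train_model_once(cfg: SimulationConfig, seed: int) -> TrainedMaps:
    """One training realisation.

    Babbling draws desired activations on the complementary manifold
    (agonist + antagonist = 1 per joint), drives the arm, and yields
    (phi_D, M_L, X_arm) triples.  The PC SOM learns muscle lengths, the
    PFC SOM learns reachable positions, the MC feature map learns PC
    activation patterns.  The MC->MN readout is trained supervised
    against the desired activations, and the PFC->MC projection learns to
    recall, for every reachable position, the MC pattern active when the
    arm is at that position -- the pattern observed whenever that position
    is successfully "reached".
    """
    rng = np.random.default_rng(seed)
    geom = _geom(cfg)
    m = cfg.maps
    if m.n_babble < 1:
        return TrainedMaps(None, None, None, None, None, trained=False)  # type: ignore[arg-type]

    phis = arm.sample_babbling_activations(rng, m.n_babble, complementary=True)
    ml = np.empty((m.n_babble, 4))
    xs = np.empty((m.n_babble, 2))
    for i in range(m.n_babble):
        st = arm.arm_state_from_activations(arm.MuscleActivations(phis[i]), geom)
        ml[i] = st.M_L
        xs[i] = st.X_arm

    pc_som = cm.train_som(_init_som(ml, m.N_pc, m.sigma_pc, rng), ml,
                          n_epochs=m.som_epochs, seed=rng)
    pfc_som = cm.train_som(_init_som(xs, m.N_pfc, m.sigma_pfc, rng), xs,
                           n_epochs=m.som_epochs, seed=rng)

    U_pc = np.empty((m.n_babble, m.N_pc * m.N_pc))
    for i in range(m.n_babble):
        U_pc[i] = cm.som_activation(ml[i], pc_som).ravel()
    mc_som = cm.train_som(_init_som(U_pc, m.N_mc, m.sigma_mc, rng), U_pc,
                          n_epochs=max(m.som_epochs // 2, 2), seed=rng)

    n_mc2 = m.N_mc * m.N_mc
    G_feat = np.empty((m.n_babble, n_mc2))
    for i in range(m.n_babble):
        G_feat[i] = cm.som_activation(U_pc[i], mc_som).ravel()

    # PFC -> MC recall of the reached-posture pattern (normalised delta
    # rule).  The recall target is the MC feature-layer activation observed
    # with the arm at that position, so the PFC drive arrives on the same
    # scale as the proprioceptive drive and mixtures interpolate.
    U_pfc = np.empty((m.n_babble, m.N_pfc * m.N_pfc))
    for i in range(m.n_babble):
        U_pfc[i] = cm.som_activation(xs[i], pfc_som).ravel()
    # recall target: a sharpened, peak-normalised copy of the feature
    # pattern -- a narrow goal spike whose mass is small (so the unaided
    # prefrontal pull is slow) but whose peak exceeds the proprioceptive
    # bump (so the Go-gated BG focusing loop amplifies it selectively)
    G_goal = np.empty_like(G_feat)
    for i in range(m.n_babble):
        g = G_feat[i]
        G_goal[i] = m.recall_amp * (g / max(g.max(), 1e-12)) ** m.recall_sharpen
    W_pfc = np.zeros((n_mc2, m.N_pfc * m.N_pfc))
    norm_u = float(np.mean(np.sum(U_pfc**2, axis=1)))
    for _ in range(m.readout_epochs):
        for i in rng.permutation(m.n_babble):
            pred = W_pfc @ U_pfc[i]
            W_pfc = cm.train_pfc_to_mc(W_pfc, U_pfc[i], G_goal[i], pred,
                                       m.eta_pfc_mc / norm_u)

    # steady MC outputs under proprioceptive drive AND under prefrontal
    # recall of the same posture: the closed-loop cortical state mixes
    # both, so the readout is supervised on both families of patterns.
    G_ss = np.empty((2 * m.n_babble, n_mc2))
    phi_targets = np.empty((2 * m.n_babble, 4))
    for i in range(m.n_babble):
        g_pc = cm.som_activation(U_pc[i], mc_som)
        G_ss[2 * i] = _relax_mc(cfg, g_pc).ravel()
        recall = (W_pfc @ U_pfc[i]).reshape(m.N_mc, m.N_mc)
        G_ss[2 * i + 1] = _relax_mc(cfg, recall).ravel()
        phi_targets[2 * i] = phis[i]
        phi_targets[2 * i + 1] = phis[i]
    G_ss /= np.maximum(G_ss.sum(axis=1, keepdims=True), 1e-12)

    # supervised MC -> MN readout (normalised LMS on unit-mass patterns)
    W_mn = np.zeros((4, n_mc2))
    norm_g = float(np.mean(np.sum(G_ss**2, axis=1)))
    for _ in range(m.readout_epochs):
        for i in rng.permutation(G_ss.shape[0]):
            phi_hat = cm.mn_activation(G_ss[i], W_mn, cfg.bg.A_MN)
            W_mn = cm.train_mc_to_mn(W_mn, phi_targets[i], phi_hat, G_ss[i],
                                     m.eta_mc_mn / norm_g)

    maps = TrainedMaps(pc_som=pc_som, pfc_som=pfc_som, mc_som=mc_som,
                       W_pfc_mc=W_pfc, W_mc_mn=W_mn)

    # closed-loop aim correction: the equilibrium of the pose/recall mixture
    # lands slightly short of the commanded position (a bias that varies
    # with the local map geometry); re-aim each recall at the posture whose
    # equilibrium cancels the bias, and retrain the projection.
    def _feature_of_posture(phi_vec):
        st = arm.arm_state_from_activations(arm.MuscleActivations(phi_vec), geom)
        u = cm.som_activation(st.M_L, pc_som)
        return cm.som_activation(u.ravel(), mc_som)

    def _sharpen(gfeat):
        return m.recall_amp * (gfeat / max(gfeat.max(), 1e-12)) ** m.recall_sharpen

    def _equilibrium(target_idx):
        recall = (maps.W_pfc_mc @ U_pfc[target_idx]).reshape(m.N_mc, m.N_mc)
        phi_vec = phis[target_idx].copy()
        net = _mc_cann(cfg)
        for _ in range(25):
            g_pc = _feature_of_posture(phi_vec)
            G = cm.cann_step(net, cfg.bg.A_PC * g_pc +
                             cfg.bg.A_PFC * recall, cfg.timing.dt_mc_ms)
            phi_vec = cm.mn_activation(G, maps.W_mc_mn, cfg.bg.A_MN)
        st = arm.arm_state_from_activations(arm.MuscleActivations(phi_vec), geom)
        return st.X_arm

    n_aim = min(m.aim_samples, m.n_babble)
    aim_idx = rng.permutation(m.n_babble)[:n_aim]
    aims = xs[aim_idx].copy()
    for _ in range(m.aim_rounds):
        for j, i in enumerate(aim_idx):
            err = xs[i] - _equilibrium(i)
            aims[j] = aims[j] + 0.8 * err
            th_s, th_e = arm.inverse_kinematics(aims[j], geom)
            phi_aim = arm.complementary_activations(th_s, th_e)
            G_goal[i] = _sharpen(_feature_of_posture(phi_aim).ravel())
        for _ in range(m.readout_epochs // 2):
            for i in rng.permutation(m.n_babble):
                pred = maps.W_pfc_mc @ U_pfc[i]
                maps.W_pfc_mc = cm.train_pfc_to_mc(
                    maps.W_pfc_mc, U_pfc[i], G_goal[i], pred,
                    m.eta_pfc_mc / norm_u)

    maps.loop_mae = loop_consistency_error(cfg, maps, n=100, seed=seed + 1)
    return maps


def loop_consistency_error(
    cfg: SimulationConfig, maps: TrainedMaps, n: int = 100, seed: int = 0
) -> float:
    """Mean absolute error of the round trip phi_D -> arm -> PC -> MC -> MN
    on held-out complementary activations."""
    rng = np.random.default_rng(seed)
    geom = _geom(cfg)
    phis = arm.sample_babbling_activations(rng, n, complementary=True)
    errs = np.empty(n)
    for i in range(n):
        st = arm.arm_state_from_activations(arm.MuscleActivations(phis[i]), geom)
        u_pc = cm.som_activation(st.M_L, maps.pc_som)
        g_pc = cm.som_activation(u_pc.ravel(), maps.mc_som)
        g_mc = _relax_mc(cfg, cfg.bg.A_PC * g_pc)
        phi_hat = cm.mn_activation(g_mc, maps.W_mc_mn, cfg.bg.A_MN)
        errs[i] = np.mean(np.abs(phi_hat - phis[i]))
    return float(np.mean(errs))


def _geom(cfg: SimulationConfig) -> arm.ArmGeometry:
    a = cfg.arm
    return arm.ArmGeometry(l_S=a.l_S, l_E=a.l_E, a_S=a.a_S, b_S=a.b_S,
                           a_E=a.a_E, b_E=a.b_E)


# ---------------------------------------------------------------------------
# Closed-loop reaching trial
# ---------------------------------------------------------------------------

@dataclass
class SessionResult:
    """Everything recorded in one reaching trial."""

    trajectory: mx.ReachTrajectory
    metrics: mx.ReachMetrics
    da_trace: np.ndarray          # pooled extracellular DA per window (nM)
    eps_trace: np.ndarray         # STN lateral strength per window
    delta_v_trace: np.ndarray
    delta_v_snc_trace: np.ndarray
    sync_blocks: np.ndarray       # synchrony per block of windows (or empty)
    mean_synchrony: float
    stn_mean_trace: np.ndarray    # mean STN output, fine-sampled (or empty)
    seed: int
    config_hash: str

    def trajectory_frame(self, geom: arm.ArmGeometry) -> pd.DataFrame:
        """Per-timestep CSV rows (t, theta_S, theta_E, x1, x2)."""
        # joint angles recovered from positions are not stored; re-derive
        # is not possible in general, so store positions with time only.
        return pd.DataFrame({
            "t": self.trajectory.times,
            "x1": self.trajectory.positions[:, 0],
            "x2": self.trajectory.positions[:, 1],
        })


def config_hash(cfg: SimulationConfig) -> str:
    import io
    import yaml

    from .config import _as_plain

    return hashlib.md5(
        yaml.safe_dump(_as_plain(cfg), sort_keys=True).encode()
    ).hexdigest()[:12]


def capped_movement_time(mt: float, horizon: float = TRIAL_HORIZON_S) -> float:
    """Non-reachable trials contribute the full trial horizon to means."""
    return min(mt, horizon)


def run_reach_trial(
    cfg: SimulationConfig,
    maps: TrainedMaps,
    lesion: pdl.LesionConfig | None = None,
    seed: int = 0,
    plasma_ldopa: float = 0.0,
    record_stn: bool = True,
    early_stop: bool = True,
) -> SessionResult:
    """One closed-loop reaching trial toward the configured target."""
    if maps is None or not maps.trained:
        raise ValueError("run_reach_trial requires trained maps")
    lesion = lesion or pdl.LesionConfig()
    rng = np.random.default_rng(seed)
    geom = _geom(cfg)
    t_cfg = cfg.timing
    b_cfg = cfg.bg
    dt_mc = t_cfg.dt_mc_ms

    # --- build subsystems (all seeds derived from the trial seed) ---
    stn_seed = int(rng.integers(2**31))
    snc_seed = int(rng.integers(2**31))
    stn_cfg = b_cfg.stn
    stn_net = bg.STNGPeNetwork(
        N=stn_cfg.N, tau_GPe=stn_cfg.tau_GPe, tau_STN=stn_cfg.tau_STN,
        eps_g=stn_cfg.eps_g, eps_s=cfg.eps.eps_map.eps_lo,
        w_sg=stn_cfg.w_sg, w_gs=stn_cfg.w_gs, lambda_STN=stn_cfg.lambda_STN,
        sigma_lat_g=stn_cfg.sigma_lat_g, sigma_lat_s=stn_cfg.sigma_lat_s,
        tau_jitter=stn_cfg.tau_jitter, noise_amp=stn_cfg.noise_amp,
        seed=stn_seed,
    )
    net = snc.make_network(cfg.snc.n, cfg.snc.params, seed=snc_seed,
                           jitter=cfg.snc.jitter)
    net = pdl.apply_lesion(net, lesion)
    params = cfg.snc.params
    calib = cfg.snc.calibration
    eps_map = cfg.eps.eps_map

    # settle the SNc population at the zero-value-difference operating point
    i_gaba0 = snc.gaba_current_from_delta_v(0.0, params)
    for _ in range(cfg.snc.settle_windows):
        snc.run_snc_window(net, params, i_gaba0, t_cfg.n_snc_steps,
                           t_cfg.dt_snc_ms, plasma_ldopa,
                           t_cfg.terminal_every)
    # slow terminal pools reach their steady state for the ambient plasma
    # level (minutes of exposure) before the 5-s trial starts
    snc.equilibrate_terminals(net, params, plasma_ldopa,
                              duration_s=cfg.pk.equilibrate_s)

    mc_net = _mc_cann(cfg)
    thal_net = _thal_cann(cfg)

    # pre-charge MC with the resting proprioceptive drive (cortical state
    # encodes the current posture before the go cue)
    start_state = arm.arm_state_from_activations(
        arm.MuscleActivations(np.asarray(cfg.arm.start_phi, float)), geom)
    u_pc0 = cm.som_activation(start_state.M_L, maps.pc_som)
    g_pc0 = cm.som_activation(u_pc0.ravel(), maps.mc_som)
    for _ in range(cfg.maps.mc_relax_steps):
        cm.cann_step(mc_net, cfg.bg.A_PC * g_pc0, cfg.timing.dt_mc_ms)

    # --- fixed drives ---
    target = np.asarray(cfg.target, float)
    u_pfc = cm.som_activation(target, maps.pfc_som)
    g_pfc_drive = cm.pfc_drive(u_pfc, maps.W_pfc_mc)

    phi = arm.MuscleActivations(np.asarray(cfg.arm.start_phi, float))
    phi_exc = phi.phi.copy()   # muscle excitation stage (second-order filter)
    st = arm.arm_state_from_activations(phi, geom)
    positions = [st.X_arm.copy()]
    gating = bg.MSNGating(a_D1=b_cfg.a_D1, theta_D1=b_cfg.theta_D1,
                          theta_D2=b_cfg.theta_D2)
    v_prev = bg.compute_value(st.X_arm, target, b_cfg.sigma_V)
    g_mc = cm.cann_output(mc_net)
    g_mc_prev = g_mc.copy()

    da_trace, eps_trace, dv_trace, dvs_trace = [], [], [], []
    stn_window_traces = [] if record_stn else None
    n_stn = stn_cfg.N

    n_steps = t_cfg.n_mc_steps
    reached_at = None
    for step in range(n_steps):
        # sensory and value signals
        u_pc = cm.som_activation(st.M_L, maps.pc_som)
        g_pc = cm.som_activation(u_pc.ravel(), maps.mc_som)
        v_now = bg.compute_value(st.X_arm, target, b_cfg.sigma_V)
        delta_v = bg.value_difference(v_now, v_prev)
        v_prev = v_now

        # nigrostriatal loop: GABA feedback -> dopamine -> value surrogate
        i_gaba = snc.gaba_current_from_delta_v(delta_v, params)
        da = snc.run_snc_window(net, params, i_gaba, t_cfg.n_snc_steps,
                                t_cfg.dt_snc_ms, plasma_ldopa,
                                t_cfg.terminal_every)
        delta_v_snc = snc.delta_v_from_dopamine(da, calib)

        # striatal gating and STN-GPe dynamics
        lam_d1, lam_d2 = bg.msn_gating(delta_v_snc, gating)
        # the striatum processes the MC output pattern itself (the cortical
        # drive G(t)); the direct pathway then acts as a dopamine-gated
        # focusing loop through GPi and thalamus
        y_d1, y_d2 = bg.striatal_outputs(
            g_mc, lam_d1, lam_d2, gain_d1=b_cfg.d1_gain,
            gain_d2=b_cfg.d2_gain, y_sat=b_cfg.y_sat,
            y_sat_d1=b_cfg.y_sat_d1)
        y_d2_small = zoom(y_d2, n_stn / y_d2.shape[0], order=1)
        eps_s = pdl.epsilon_s_source(lesion, delta_v, delta_v_snc, eps_map)
        stn_net.eps_s = eps_s
        traces = bg.run_stn_gpe_window(
            stn_net, y_d2_small, t_cfg.dt_stn_ms, t_cfg.n_stn_steps,
            record_every=b_cfg.record_every,
        )
        if stn_window_traces is not None:
            stn_window_traces.append(traces)
        # the thalamus relays the STN modulation *envelope* over the
        # behavioural window: the lattice oscillates at tens of Hz, so an
        # instantaneous 50-ms sample would alias to zero
        y_stn_env = np.sqrt(np.mean(traces**2, axis=1)).reshape(n_stn, n_stn)
        y_stn_up = zoom(y_stn_env, cfg.maps.N_thal / n_stn, order=1)
        y_gpi = bg.gpi_combine(y_d1, y_stn_up, b_cfg.A_D1, b_cfg.A_D2)

        # thalamic relay and motor cortex update
        g_bg = cm.cann_step(thal_net, y_gpi, dt_mc)
        i_mc = cm.mc_total_input(
            g_pc, g_pfc_drive, g_bg,
            cm.ProjectionGains(b_cfg.A_PC, b_cfg.A_PFC, b_cfg.A_BG, b_cfg.A_MN),
        )
        g_mc_prev = g_mc
        g_mc = cm.cann_step(mc_net, i_mc, dt_mc)

        # motor output: MN command through second-order muscle
        # excitation-activation dynamics (bell-shaped velocity profiles)
        phi_cmd = cm.mn_activation(g_mc, maps.W_mc_mn, b_cfg.A_MN)
        phi_exc = phi_exc + b_cfg.mn_beta * (phi_cmd - phi_exc)
        phi = arm.MuscleActivations(
            phi.phi + b_cfg.mn_beta * (phi_exc - phi.phi))
        st = arm.arm_state_from_activations(phi, geom)
        positions.append(st.X_arm.copy())

        da_trace.append(da)
        eps_trace.append(eps_s)
        dv_trace.append(delta_v)
        dvs_trace.append(delta_v_snc)

        dist = float(np.linalg.norm(st.X_arm - target))
        if dist < cfg.arm.eps_reach and reached_at is None:
            reached_at = step
            if early_stop:
                break

    positions = np.asarray(positions)
    times = np.arange(positions.shape[0]) * (dt_mc / 1000.0)
    traj = mx.ReachTrajectory(times=times, positions=positions, target=target,
                              eps_reach=cfg.arm.eps_reach)
    metrics = mx.compute_reach_metrics(traj)

    sync_blocks = np.array([])
    mean_sync = float("nan")
    stn_mean = np.array([])
    if stn_window_traces:
        block = b_cfg.sync_block_windows
        all_traces = np.concatenate(stn_window_traces, axis=1)
        stn_mean = all_traces.mean(axis=0)
        n_per_window = stn_window_traces[0].shape[1]
        blocks = []
        for i in range(0, len(stn_window_traces), block):
            seg = all_traces[:, i * n_per_window:(i + block) * n_per_window]
            if seg.shape[1] >= 2 * n_per_window or len(stn_window_traces) <= block:
                try:
                    blocks.append(mx.synchrony(seg))
                except ValueError:
                    pass
        sync_blocks = np.asarray(blocks)
        mean_sync = float(np.mean(sync_blocks)) if sync_blocks.size else float("nan")

    return SessionResult(
        trajectory=traj, metrics=metrics,
        da_trace=np.asarray(da_trace), eps_trace=np.asarray(eps_trace),
        delta_v_trace=np.asarray(dv_trace),
        delta_v_snc_trace=np.asarray(dvs_trace),
        sync_blocks=sync_blocks, mean_synchrony=mean_sync,
        stn_mean_trace=stn_mean, seed=seed, config_hash=config_hash(cfg),
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate(
    cfg: SimulationConfig, seed: int = 0, hold_windows: int = 8
) -> tuple[SimulationConfig, dict]:
    """Fit the dopamine read-out and the STN coupling map on control runs.

    (a) Scans held value differences, records the settled pooled dopamine
    response and fits the affine dopamine -> value-difference read-out;
    (b) reports the dopamine peak of the scan (the control operating
    range); (c) scans the STN lateral strength for its synchrony curve and
    anchors the dopamine -> coupling map so that deep, sustained dopamine
    collapse (low survival) drives the lattice into its synchronised
    regime while the healthy operating point stays desynchronised.
    Returns the updated configuration and a diagnostics dict.
    """
    t_cfg = cfg.timing
    params = cfg.snc.params

    deltas = np.array([-0.25, -0.15, -0.1, -0.05, -0.02, 0.0,
                       0.02, 0.05, 0.1, 0.15, 0.25])
    da_resp = np.empty_like(deltas)
    base = snc.make_network(cfg.snc.n, params, seed=seed, jitter=cfg.snc.jitter)
    i0 = snc.gaba_current_from_delta_v(0.0, params)
    for _ in range(cfg.snc.settle_windows * 2):
        snc.run_snc_window(base, params, i0, t_cfg.n_snc_steps, t_cfg.dt_snc_ms,
                           0.0, t_cfg.terminal_every)
    snc.equilibrate_terminals(base, params, 0.0,
                              duration_s=cfg.pk.equilibrate_s)
    for k, d in enumerate(deltas):
        state = base.copy()
        ig = snc.gaba_current_from_delta_v(float(d), params)
        for _ in range(hold_windows):
            da = snc.run_snc_window(state, params, ig, t_cfg.n_snc_steps,
                                    t_cfg.dt_snc_ms, 0.0, t_cfg.terminal_every)
        da_resp[k] = da

    # unanchored least-squares affine fit delta ~ gain * (DA - crossing).
    # The saturating positive branch pulls the zero crossing well above the
    # resting dopamine level, so partial lesions (which cap the pool below
    # the crossing) read out as persistently negative value differences.
    da_rest = float(da_resp[deltas == 0.0][0])
    A = np.stack([da_resp, np.ones_like(da_resp)], axis=1)
    coef, *_ = np.linalg.lstsq(A, deltas, rcond=None)
    gain = float(coef[0])
    crossing = float(-coef[1] / max(gain, 1e-12))
    pred = np.clip(gain * (da_resp - crossing), cfg.snc.calibration.delta_min,
                   cfg.snc.calibration.delta_max)
    mae = float(np.mean(np.abs(pred - deltas)))

    e = cfg.eps
    eps_grid = np.linspace(e.scan_lo, e.scan_hi, e.scan_n)
    s = cfg.bg.stn
    sync_curve = bg.synchrony_vs_coupling_curve(
        eps_grid, duration_ms=1000.0, dt=t_cfg.dt_stn_ms, N=s.N, seed=seed,
        tau_GPe=s.tau_GPe, tau_STN=s.tau_STN, eps_g=s.eps_g, w_sg=s.w_sg,
        w_gs=s.w_gs, lambda_STN=s.lambda_STN, sigma_lat_g=s.sigma_lat_g,
        sigma_lat_s=s.sigma_lat_s, tau_jitter=s.tau_jitter,
        noise_amp=s.noise_amp,
    )
    # eps_lo: largest coupling in the *contiguous* low-synchrony prefix
    # (the curve can show spurious zero-synchrony frozen states at strong
    # coupling, which must not be mistaken for desynchronisation)
    above = np.flatnonzero(sync_curve > e.sync_low_target)
    if above.size == 0:
        eps_lo = float(e.scan_lo)
    elif above[0] == 0:
        eps_lo = float(e.scan_lo)
    else:
        eps_lo = float(eps_grid[above[0] - 1])
    high = eps_grid[sync_curve >= e.sync_high_target]
    # the unforced scan underestimates the coupling needed to lock the
    # lattice under striatal drive; apply a robustness margin
    eps_hi = float(high.min()) if high.size else float(e.scan_hi)
    eps_hi = min(eps_hi * e.eps_hi_margin, float(e.scan_hi))

    # coupling anchors, expressed relative to the healthy resting read-out:
    # the span runs from the control population at rest down to a 25%-
    # survival population at rest.  Anchors as fractions of that span are
    # invariant to calibration-to-calibration shifts of the crossing, so the
    # healthy operating point keeps a fixed safety margin below the anchor.
    delta_rest = gain * (da_rest - crossing)
    span = gain * 0.75 * da_rest   # rest level minus the 25%-survival level
    delta_hi = delta_rest - e.rest_frac_hi * span
    delta_lo = delta_rest - e.rest_frac_lo * span

    new_calib = dataclasses.replace(cfg.snc.calibration, gain=gain,
                                    offset=crossing)
    new_map = pdl.EpsilonMap(eps_lo=eps_lo, eps_hi=eps_hi,
                             delta_lo=delta_lo, delta_hi=delta_hi)
    new_cfg = dataclasses.replace(
        cfg,
        snc=dataclasses.replace(cfg.snc, calibration=new_calib),
        eps=dataclasses.replace(cfg.eps, eps_map=new_map),
    )
    diag = {
        "deltas": deltas, "da_response": da_resp, "gain": gain,
        "offset": crossing, "da_rest": da_rest, "mean_abs_error": mae,
        "da_peak_scan": float(da_resp.max()),
        "eps_grid": eps_grid, "sync_curve": sync_curve,
        "eps_lo": eps_lo, "eps_hi": eps_hi,
        "delta_lo": delta_lo, "delta_hi": delta_hi,
        "delta_rest": delta_rest,
    }
    return new_cfg, diag


# ---------------------------------------------------------------------------
# Experiment protocols
# ---------------------------------------------------------------------------

def pd_sweep(
    cfg: SimulationConfig,
    maps: TrainedMaps,
    modes: tuple[str, ...] = ("PD1", "PD2"),
    losses: tuple[float, ...] = (25.0, 37.0, 50.0, 62.0, 75.0),
    n_trials: int = 3,
    seed: int = 0,
    record_stn: bool = False,
) -> pd.DataFrame:
    """Reach metrics across lesion modes and cell-loss percentages."""
    rows = []
    rng = np.random.default_rng(seed)
    for mode in modes:
        for loss in losses:
            for k in range(n_trials):
                trial_seed = int(rng.integers(2**31))
                lesion = pdl.LesionConfig(mode=mode, P_SNc=100.0 - loss,
                                          seed=trial_seed)
                r = run_reach_trial(cfg, maps, lesion, seed=trial_seed,
                                    record_stn=record_stn)
                rows.append({
                    "mode": mode, "cell_loss": loss, "trial": k,
                    "movement_time": capped_movement_time(r.metrics.movement_time),
                    "reached": r.metrics.reached,
                    "peak_velocity": r.metrics.peak_velocity,
                    "time_to_peak": r.metrics.time_to_peak,
                    "average_velocity": r.metrics.average_velocity,
                    "rms_acceleration": r.metrics.rms_acceleration,
                    "da_peak": float(r.da_trace.max()),
                    "synchrony": r.mean_synchrony,
                })
    return pd.DataFrame(rows)


def ldopa_session(
    cfg: SimulationConfig,
    maps: TrainedMaps,
    lesion: pdl.LesionConfig,
    dose_mg: float | None = None,
    seed: int = 0,
    n_trials: int | None = None,
    sample_every_h: float | None = None,
) -> pd.DataFrame:
    """Hourly movement-time series across one oral levodopa dose.

    Simulates the plasma curve, samples it on a regular grid (2 h of
    pre-dose baseline included) and runs a short reaching session at each
    sample with the terminals equilibrated to that plasma level.
    """
    dose = cfg.pk.dose_mg if dose_mg is None else dose_mg
    n_tr = cfg.pk.session_trials if n_trials is None else n_trials
    every = cfg.pk.sample_every_h if sample_every_h is None else sample_every_h
    sched = pk.DoseSchedule(doses=((cfg.pk.dose_time_h, dose),) if dose > 0 else (),
                            horizon_h=cfg.pk.horizon_h, sample_every_h=every)
    t_curve, conc = pk.simulate_pk(sched, cfg.pk.params)
    sample_hours = np.arange(0.0, cfg.pk.horizon_h + 1e-9, every)
    rng = np.random.default_rng(seed)
    rows = []
    for h in sample_hours:
        plasma = float(np.interp(h, t_curve, conc))
        mts = []
        for _ in range(n_tr):
            ts = int(rng.integers(2**31))
            lesion_k = dataclasses.replace(lesion, seed=ts)
            r = run_reach_trial(cfg, maps, lesion_k, seed=ts,
                                plasma_ldopa=plasma, record_stn=False)
            mts.append(capped_movement_time(r.metrics.movement_time))
        mean_mt = float(np.mean(mts))
        rows.append({
            "time_h": float(h), "plasma_mg_per_l": plasma,
            "movement_time": mean_mt,
            "colour": mx.classify_movement_time(mean_mt),
        })
    df = pd.DataFrame(rows)
    df.attrs["therapeutic_window_h"] = mx.therapeutic_window(
        df["time_h"].to_numpy(), df["movement_time"].to_numpy(),
        cfg.pk.dose_time_h)
    return df


def dose_grid(
    cfg: SimulationConfig,
    maps: TrainedMaps,
    doses: tuple[float, ...],
    losses: tuple[float, ...],
    mode: str = "PD1",
    seed: int = 0,
    **session_kwargs,
) -> pd.DataFrame:
    """Therapeutic window for every (dose, cell-loss) combination."""
    rows = []
    rng = np.random.default_rng(seed)
    for dose in doses:
        for loss in losses:
            lesion = pdl.LesionConfig(mode=mode, P_SNc=100.0 - loss, seed=seed)
            df = ldopa_session(cfg, maps, lesion, dose_mg=dose,
                               seed=int(rng.integers(2**31)), **session_kwargs)
            rows.append({
                "dose_mg": dose, "cell_loss": loss, "mode": mode,
                "window_h": df.attrs["therapeutic_window_h"],
            })
    return pd.DataFrame(rows)
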