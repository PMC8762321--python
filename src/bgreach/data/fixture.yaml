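arm:
  l_S: 0.3
  l_E: 0.35
  a_S: 0.05
  b_S: 0.05
  a_E: 0.05
  b_E: 0.05
  start_phi:
  - 0.5
  - 0.5
  - 0.5
  - 0.5
  eps_reach: 0.1
maps:
  N_pc: 20
  N_pfc: 20
  N_mc: 20
  N_thal: 20
  sigma_pc: 0.02
  sigma_pfc: 0.15
  sigma_mc: 1.2
  n_babble: 1500
  som_epochs: 8
  mc_relax_steps: 30
  readout_epochs: 40
  eta_mc_mn: 0.15
  eta_pfc_mc: 0.3
  aim_rounds: 2
  aim_samples: 400
  recall_sharpen: 3.0
  recall_amp: 1.2
  closed_loop_trials: 0
  mc_cann:
    tau: 150.0
    A_lat: 0.15
    sigma_lat: 1.5
    K: 0.01
    b: 1.5
  thal_cann:
    tau: 150.0
    A_lat: 0.05
    sigma_lat: 1.5
    K: 0.0
    b: 0.05
bg:
  sigma_V: 0.8
  a_D1: 30.0
  theta_D1: 0.08
  theta_D2: 0.08
  A_D1: 0.2
  A_D2: 0.8
  d1_gain: 1.0
  d2_gain: 8.0
  y_sat: 100.0
  y_sat_d1: 100.0
  A_PC: 1.0
  A_PFC: 0.65
  A_BG: 40.0
  A_MN: 1.0
  mn_beta: 0.35
  stn:
    N: 8
    tau_GPe: 20.0
    tau_STN: 10.0
    eps_g: 0.2
    w_sg: 2.5
    w_gs: 2.5
    lambda_STN: 3.0
    sigma_lat_g: 0.9
    sigma_lat_s: 0.9
    tau_jitter: 0.05
    noise_amp: 0.15
  record_every: 25
  sync_block_windows: 4
snc:
  n: 64
  jitter: 0.05
  settle_windows: 10
  params:
    C_m: 20.0
    g_fast: 4.4
    E_fast: 120.0
    V1: -1.2
    V2: 18.0
    g_K: 8.0
    E_K: -84.0
    V3: 2.0
    V4: 30.0
    phi_w: 0.04
    g_L: 2.0
    E_L: -20.0
    g_CaL: 0.5
    E_Ca: 120.0
    V_ca_half: -15.0
    k_ca_slope: 7.0
    v_pmca: 2.0
    K_pmca: 0.3
    v_ncx: 4.0
    k_ca_flux: 0.002
    k_calb: 0.01
    k_cam: 0.005
    I_nmda_ampa: -8.0
    I_gaba_max: 45.0
    gaba_slope: 0.05
    V_synt_max: 0.02
    K_synt: 0.25
    K_TYR: 46.0
    TYR: 126.0
    K_i_cda: 110.0
    K_i_eda: 460.0
    V_aadc: 0.02
    K_aadc: 130.0
    V_vmat: 0.1
    K_vmat: 0.3
    k_cdeg: 0.0001
    psi: 22.0
    p_spont: 0.09
    n_max: 1.0
    K_v: 250.0
    k_vleak: 1.0e-05
    K_rel: 0.25
    V_DAT: 6.0
    K_DAT: 200.0
    k_edao: 0.02
    V_aat_max: 0.0005
    K_ldopa_e: 1.0
    TYR_e: 63.0
    TRP_e: 82.0
    K_tyr_e: 64.0
    K_trp_e: 15.0
  calibration:
    gain: 0.000900187137981436
    offset: 129.65915384747743
    delta_min: -0.5
    delta_max: 0.5
eps:
  eps_map:
    eps_lo: 0.15
    eps_hi: 1.5042857142857144
    delta_lo: -0.10378107419339222
    delta_hi: -0.09028219236209152
  scan_lo: 0.15
  scan_hi: 3.0
  scan_n: 8
  sync_low_target: 0.1
  sync_high_target: 0.9
  rest_frac_hi: 0.55
  rest_frac_lo: 0.95
  eps_hi_margin: 2.7
pk:
  params:
    V_CC: 11.0
    V_PC: 27.0
    k01: 2.5
    k12: 0.2
    k21: 0.4
    k1e: 2.8
    literal_infusion: false
  dose_mg: 150.0
  dose_time_h: 2.0
  horizon_h: 12.0
  sample_every_h: 0.5
  session_trials: 3
  equilibrate_s: 600.0
timing:
  dt_mc_ms: 50.0
  n_mc_steps: 100
  dt_stn_ms: 0.02
  n_stn_steps: 2500
  dt_snc_ms: 0.025
  n_snc_steps: 2000
  terminal_every: 10
target:
- 0.3
- 0.35
seed: 0
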