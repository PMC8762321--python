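"""Optional numba-compiled kernels for the two fine-timestep inner loops.

The kernels mirror the reference numpy implementations in
``snc_dopamine.run_snc_window`` and ``basal_ganglia.run_stn_gpe_window``
operation-for-operation; unit tests assert agreement.  When numba is not
importable the callers silently use the numpy path.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally available
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore[misc]
        def deco(fn):
            return fn
        return deco


def snc_param_vector(p) -> np.ndarray:
    """Flatten an SNcParams into the kernel's positional parameter array."""
    return np.array([
        p.C_m, p.g_fast, p.E_fast, p.V1, p.V2, p.g_K, p.E_K, p.V3, p.V4,
        p.phi_w, p.g_L, p.E_L, p.g_CaL, p.E_Ca, p.V_ca_half, p.k_ca_slope,
        p.v_pmca, p.K_pmca, p.v_ncx, p.k_ca_flux, p.k_calb, p.k_cam,
        p.I_nmda_ampa, p.V_synt_max, p.K_synt, p.K_TYR, p.TYR, p.K_i_cda,
        p.K_i_eda, p.V_aadc, p.K_aadc, p.V_vmat, p.K_vmat, p.k_cdeg,
        p.psi, p.n_max, p.K_v, p.K_rel, p.V_DAT, p.K_DAT, p.k_edao,
        p.p_spont, p.k_vleak,
    ])


@njit(cache=True)
def snc_window_kernel(V, w, Ca, LDOPA, DA_c, DA_v, DA_e, alive, het,
                      pv, I_gaba, j_aat, n_steps, dt, terminal_every):
    (C_m, g_fast, E_fast, V1, V2, g_K, E_K, V3, V4, phi_w, g_L, E_L,
     g_CaL, E_Ca, V_ca_half, k_ca_slope, v_pmca, K_pmca, v_ncx, k_ca_flux,
     k_calb, k_cam, I_nmda, V_synt_max, K_synt, K_TYR, TYR, K_i_cda,
     K_i_eda, V_aadc, K_aadc, V_vmat, K_vmat, k_cdeg, psi, n_max, K_v,
     K_rel, V_DAT, K_DAT, k_edao, p_spont, k_vleak) = (
        pv[0], pv[1], pv[2], pv[3], pv[4], pv[5], pv[6], pv[7], pv[8],
        pv[9], pv[10], pv[11], pv[12], pv[13], pv[14], pv[15], pv[16],
        pv[17], pv[18], pv[19], pv[20], pv[21], pv[22], pv[23], pv[24],
        pv[25], pv[26], pv[27], pv[28], pv[29], pv[30], pv[31], pv[32],
        pv[33], pv[34], pv[35], pv[36], pv[37], pv[38], pv[39], pv[40],
        pv[41], pv[42])
    n = V.shape[0]
    dt_term = dt * terminal_every
    J_syn = -(I_gaba + I_nmda)
    da_sum = 0.0
    da_count = 0
    K_rel4 = K_rel**4
    K_synt4 = K_synt**4
    for step in range(n_steps):
        for i in range(n):
            if not alive[i]:
                V[i] = -80.0
                w[i] = 0.0
                Ca[i] = 0.0
                continue
            v = V[i]
            m_inf = 0.5 * (1.0 + np.tanh((v - V1) / V2))
            I_f = g_fast * het[i] * m_inf * (v - E_fast)
            I_K = g_K * w[i] * (v - E_K) + g_L * (v - E_L)
            ca_gate = 1.0 / (1.0 + np.exp(-(v - V_ca_half) / k_ca_slope))
            I_CaL = g_CaL * ca_gate * (v - E_Ca)
            I_pmca = v_pmca * Ca[i] / (Ca[i] + K_pmca)
            I_ncx = -v_ncx * Ca[i]
            J_Ca_mem = -(I_CaL + 2.0 * I_pmca - 2.0 * I_ncx) / 2.0
            dV = (-I_f + 2.0 * J_Ca_mem - I_K + J_syn) / C_m
            w_inf = 0.5 * (1.0 + np.tanh((v - V3) / V4))
            tau_w = 1.0 / np.cosh((v - V3) / (2.0 * V4))
            dw = phi_w * het[i] * (w_inf - w[i]) / tau_w
            dCa = k_ca_flux * 2.0 * J_Ca_mem - (k_calb + 4.0 * k_cam) * Ca[i]
            V[i] = v + dt * dV
            w[i] = w[i] + dt * dw
            Ca[i] = max(Ca[i] + dt * dCa, 0.0)
        if (step + 1) % terminal_every == 0:
            pooled = 0.0
            for i in range(n):
                if not alive[i]:
                    LDOPA[i] = 0.0
                    DA_c[i] = 0.0
                    DA_v[i] = 0.0
                    DA_e[i] = 0.0
                    continue
                ca4 = Ca[i]**4
                v_synt = V_synt_max * ca4 / (K_synt4 + ca4)
                inhib = 1.0 + (K_TYR / TYR) * (
                    1.0 + DA_c[i] / K_i_cda + DA_e[i] / K_i_eda)
                j_synt = v_synt / inhib
                j_aadc = V_aadc * LDOPA[i] / (K_aadc + LDOPA[i])
                j_vmat = V_vmat * DA_c[i] / (K_vmat + DA_c[i])
                n_rrp = n_max * DA_v[i] / (K_v + DA_v[i])
                p_rel = ca4 / (K_rel4 + ca4) + p_spont
                j_rel = psi * n_rrp * p_rel
                LDOPA[i] = max(LDOPA[i] + dt_term * (j_aat + j_synt - j_aadc), 0.0)
                DA_c[i] = max(DA_c[i] + dt_term * (j_aadc - j_vmat - k_cdeg * DA_c[i]), 0.0)
                DA_v[i] = max(DA_v[i] + dt_term * (j_vmat - j_rel / 1000.0
                                                   - k_vleak * DA_v[i]), 0.0)
                j_dat = V_DAT * DA_e[i] / (K_DAT + DA_e[i])
                DA_e[i] = max(DA_e[i] + dt_term * (j_rel - j_dat - k_edao * DA_e[i]), 0.0)
                pooled += DA_e[i]
            da_sum += pooled / n
            da_count += 1
    return da_sum / max(da_count, 1)


@njit(cache=True)
def stn_gpe_window_kernel(x_g, x_s, u, Lg_scaled, Ls, tau_g, tau_s,
                          eps_s, w_sg, w_gs, lam, dt, n_steps, record_every,
                          records, noise_g, noise_s, noise_every):
    n_rec = 0
    for step in range(n_steps):
        chunk = step // noise_every
        y = np.tanh(lam * x_s)
        dxg = (-x_g + Lg_scaled @ x_g + w_sg * y + u + noise_g[chunk]) / tau_g
        dxs = (-x_s + eps_s * (Ls @ y) - w_gs * x_g + noise_s[chunk]) / tau_s
        for i in range(x_g.shape[0]):
            x_g[i] += dt * dxg[i]
            x_s[i] += dt * dxs[i]
        if record_every > 0 and (step + 1) % record_every == 0:
            for i in range(x_s.shape[0]):
                records[i, n_rec] = np.tanh(lam * x_s[i])
            n_rec += 1
    return n_rec
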