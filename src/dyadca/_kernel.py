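"""Numba-accelerated right-hand side.

This kernel is a line-for-line transcription of the reference path
(:func:`dyadca.transport.compute_currents` + :func:`dyadca.engine._rhs_py`)
operating on a packed parameter vector; the test suite asserts the two
paths agree to machine precision.  When numba is unavailable the engine
falls back to the reference implementation.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn
        if args and callable(args[0]):
            return args[0]
        return deco

from .topology import IDX, N_STATES

# state indices (compile-time constants for numba)
S_V = IDX["v"]
S_M = IDX["m"]; S_H = IDX["h"]; S_J = IDX["j"]
S_D = IDX["d"]; S_F = IDX["f"]; S_FCA_T = IDX["fca_t"]; S_FCA_S = IDX["fca_s"]
S_RTO = IDX["r_to"]; S_STO = IDX["s_to"]; S_RSS = IDX["r_ss"]; S_YF = IDX["y_f"]
S_RYROT = IDX["ryr_o_t"]; S_RYRAT = IDX["ryr_a_t"]
S_RYROS = IDX["ryr_o_s"]; S_RYRAS = IDX["ryr_a_s"]
S_CAC = IDX["ca_c"]; S_CASS = IDX["ca_ss"]; S_CAST = IDX["ca_st"]
S_CADS = IDX["ca_ds"]; S_CADT = IDX["ca_dt"]
S_CANSR = IDX["ca_nsr"]; S_CAJS = IDX["ca_jsr_s"]; S_CAJT = IDX["ca_jsr_t"]
S_CALUM = IDX["ca_lumen"]
S_NAI = IDX["na_i"]; S_KI = IDX["k_i"]
S_BCM_C = IDX["b_cm_c"]; S_BCM_SS = IDX["b_cm_ss"]; S_BCM_ST = IDX["b_cm_st"]
S_BCM_DS = IDX["b_cm_ds"]; S_BCM_DT = IDX["b_cm_dt"]
S_BH = IDX["b_htrpn"]; S_BL = IDX["b_ltrpn"]
S_BCS_S = IDX["b_cs_s"]; S_BCS_T = IDX["b_cs_t"]; S_BTS = IDX["b_ts"]
S_BF_C = IDX["bext_free_c"]; S_BF_SS = IDX["bext_free_ss"]
S_BF_ST = IDX["bext_free_st"]; S_BF_DS = IDX["bext_free_ds"]
S_BF_DT = IDX["bext_free_dt"]
S_BB_C = IDX["bext_ca_c"]; S_BB_SS = IDX["bext_ca_ss"]
S_BB_ST = IDX["bext_ca_st"]; S_BB_DS = IDX["bext_ca_ds"]
S_BB_DT = IDX["bext_ca_dt"]

# packed-parameter layout (built by pack_params; order is load-bearing)
_FIELDS = [
    "cm", "vth", "faraday",
    "v_c", "v_ss", "v_st", "v_ds", "v_dt", "v_nsr", "v_js", "v_jt",
    "v_lum", "v_aq",
    "tau_dt_st", "tau_ds_ss", "tau_st_c", "tau_ss_c", "tau_jt_nsr",
    "tau_js_nsr", "tau_lum_e", "tau_ca_cp",
    "tau_b_dt_st", "tau_b_ds_ss", "tau_b_st_c", "tau_b_ss_c", "tau_b_cp",
    "ca_e", "na_e", "k_e",
    "g_na",
    "p_ca", "km_fca", "tau_fca",
    "k_naca", "km_na", "km_ca", "ksat", "eta",
    "i_pca_max", "km_pca",
    "i_nak_max", "km_nak_na", "km_nak_k",
    "g_k1", "g_kto", "g_kss", "g_f", "g_kb", "g_nab", "g_cab", "cab_frac_t",
    "serca_vmax", "serca_km", "serca_km_sr", "serca_hill", "k_leak",
    "ryr_g", "ryr_km_o", "ryr_h_o", "ryr_tau_o", "ryr_km_a", "ryr_h_a",
    "ryr_tau_a",
    "cmdn_tot", "cmdn_on", "cmdn_off",
    "htrpn_tot", "htrpn_on", "htrpn_off",
    "ltrpn_tot", "ltrpn_on", "ltrpn_off",
    "csqn_tot", "csqn_on", "csqn_off",
    "bts_tot", "bts_on", "bts_off",
    # four-site weights (dt, ds, st, ss) per transporter
    "w_ca_dt", "w_ca_ds", "w_ca_st", "w_ca_ss",
    "w_naca_dt", "w_naca_ds", "w_naca_st", "w_naca_ss",
    "w_pca_dt", "w_pca_ds", "w_pca_st", "w_pca_ss",
    "w_up_dt", "w_up_ds", "w_up_c",
    # exogenous buffer + dialysis
    "buf_enabled", "buf_kon", "buf_koff", "b_free_p", "b_bound_p",
    "ca_p", "dialysis", "has_na_p", "na_p", "has_k_p", "k_p",
    # current enable multipliers (1.0 on, 0.0 disabled)
    "en_na", "en_ca", "en_kto", "en_kss", "en_k1", "en_f", "en_kb",
    "en_nab", "en_cab", "en_naca", "en_nak", "en_pca",
    # gate tables: vh, k, tau_base, tau_amp, tau_vc, tau_kc for the 9
    # voltage gates in engine order (m h j d f r_to s_to r_ss y_f)
]
P = {name: i for i, name in enumerate(_FIELDS)}
N_SCALARS = len(_FIELDS)
N_VGATES = 9
GATE_BLOCK = N_SCALARS  # gate table starts here: 9 * 6 floats
N_PACKED = N_SCALARS + N_VGATES * 6

# gate state indices in engine order
_VGATE_STATES = (S_M, S_H, S_J, S_D, S_F, S_RTO, S_STO, S_RSS, S_YF)

# scalar positions used inside the kernel, bound as module constants
for _n, _i in P.items():
    globals()["P_" + _n.upper()] = _i
_G0 = GATE_BLOCK

_VG = np.array(_VGATE_STATES, dtype=np.int64)


@njit(cache=True)
def rhs_kernel(t, y, pp, stim, v_cmd, use_vcmd):  # noqa: C901
    dy = np.zeros(N_STATES)
    v = v_cmd if use_vcmd else y[S_V]
    F = pp[P_FARADAY]
    vth = pp[P_VTH]

    ca_c = y[S_CAC]; ca_ss = y[S_CASS]; ca_st = y[S_CAST]
    ca_ds = y[S_CADS]; ca_dt = y[S_CADT]
    ca_nsr = y[S_CANSR]; ca_js = y[S_CAJS]; ca_jt = y[S_CAJT]
    ca_lum = y[S_CALUM]
    na_i = max(y[S_NAI], 1e-6)
    k_i = max(y[S_KI], 1e-6)
    ca_e = pp[P_CA_E]; na_e = pp[P_NA_E]; k_e = pp[P_K_E]

    e_na = vth * math.log(na_e / na_i)
    e_k = vth * math.log(k_e / k_i)

    # --- currents ---------------------------------------------------------
    i_na = pp[P_EN_NA] * pp[P_G_NA] * y[S_M] ** 3 * y[S_H] * y[S_J] * (v - e_na)

    # L-type Ca (GHK driving)
    x2 = 2.0 * v / vth
    if abs(x2) < 1e-6:
        ghk_dt = ca_dt - ca_lum + 0.25 * x2 * (ca_dt + ca_lum)
        ghk_ds = ca_ds - ca_e + 0.25 * x2 * (ca_ds + ca_e)
        ghk_st = ca_st - ca_lum + 0.25 * x2 * (ca_st + ca_lum)
        ghk_ss = ca_ss - ca_e + 0.25 * x2 * (ca_ss + ca_e)
    else:
        ex2 = math.exp(x2)
        den = ex2 - 1.0
        ghk_dt = x2 * (ca_dt * ex2 - ca_lum) / den
        ghk_ds = x2 * (ca_ds * ex2 - ca_e) / den
        ghk_st = x2 * (ca_st * ex2 - ca_lum) / den
        ghk_ss = x2 * (ca_ss * ex2 - ca_e) / den
    gate_ca = pp[P_EN_CA] * pp[P_P_CA] * y[S_D] * y[S_F]
    i_ca_dt = gate_ca * pp[P_W_CA_DT] * y[S_FCA_T] * ghk_dt
    i_ca_ds = gate_ca * pp[P_W_CA_DS] * y[S_FCA_S] * ghk_ds
    i_ca_st = gate_ca * pp[P_W_CA_ST] * y[S_FCA_T] * ghk_st
    i_ca_ss = gate_ca * pp[P_W_CA_SS] * y[S_FCA_S] * ghk_ss

    i_kto = pp[P_EN_KTO] * pp[P_G_KTO] * y[S_RTO] * y[S_STO] * (v - e_k)
    i_kss = pp[P_EN_KSS] * pp[P_G_KSS] * y[S_RSS] * (v - e_k)
    rect = 1.0 / (1.0 + math.exp(0.07 * (v - e_k - 10.0)))
    i_k1 = pp[P_EN_K1] * pp[P_G_K1] * (k_e / (k_e + 0.21)) * rect * (v - e_k)
    i_f = pp[P_EN_F] * pp[P_G_F] * y[S_YF] * (v + 20.0)
    i_kb = pp[P_EN_KB] * pp[P_G_KB] * (v - e_k)
    i_nab = pp[P_EN_NAB] * pp[P_G_NAB] * (v - e_na)

    g_cab = pp[P_EN_CAB] * pp[P_G_CAB]
    frac_t = pp[P_CAB_FRAC_T]
    e_ca_t = 0.5 * vth * math.log(max(ca_lum, 1e-9) / max(ca_st, 1e-9))
    e_ca_s = 0.5 * vth * math.log(ca_e / max(ca_ss, 1e-9))
    i_cab_st = g_cab * frac_t * (v - e_ca_t)
    i_cab_ss = g_cab * (1.0 - frac_t) * (v - e_ca_s)

    # NCX per site
    k_naca = pp[P_EN_NACA] * pp[P_K_NACA]
    km_na = pp[P_KM_NA]; km_ca = pp[P_KM_CA]
    ksat = pp[P_KSAT]; eta = pp[P_ETA]
    x1 = v / vth
    ef = math.exp(eta * x1)
    er = math.exp((eta - 1.0) * x1)
    na_i3 = na_i ** 3
    na_e3 = na_e ** 3
    den_base = (km_na ** 3 + na_e3) * (1.0 + ksat * er)
    den_lum = den_base * (km_ca + ca_lum)
    den_e = den_base * (km_ca + ca_e)
    i_naca_dt = k_naca * pp[P_W_NACA_DT] * (na_i3 * ca_lum * ef - na_e3 * ca_dt * er) / den_lum
    i_naca_st = k_naca * pp[P_W_NACA_ST] * (na_i3 * ca_lum * ef - na_e3 * ca_st * er) / den_lum
    i_naca_ds = k_naca * pp[P_W_NACA_DS] * (na_i3 * ca_e * ef - na_e3 * ca_ds * er) / den_e
    i_naca_ss = k_naca * pp[P_W_NACA_SS] * (na_i3 * ca_e * ef - na_e3 * ca_ss * er) / den_e

    sigma = (math.exp(na_e / 67.3) - 1.0) / 7.0
    fv = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * x1) + 0.0365 * sigma * math.exp(-x1))
    i_nak = pp[P_EN_NAK] * pp[P_I_NAK_MAX] * fv * (k_e / (k_e + pp[P_KM_NAK_K])) \
        * na_i ** 1.5 / (na_i ** 1.5 + pp[P_KM_NAK_NA] ** 1.5)

    ipmax = pp[P_EN_PCA] * pp[P_I_PCA_MAX]
    km_p = pp[P_KM_PCA]
    i_pca_dt = ipmax * pp[P_W_PCA_DT] * ca_dt / (ca_dt + km_p)
    i_pca_ds = ipmax * pp[P_W_PCA_DS] * ca_ds / (ca_ds + km_p)
    i_pca_st = ipmax * pp[P_W_PCA_ST] * ca_st / (ca_st + km_p)
    i_pca_ss = ipmax * pp[P_W_PCA_SS] * ca_ss / (ca_ss + km_p)

    # SR fluxes
    vmax = pp[P_SERCA_VMAX]; km_up = pp[P_SERCA_KM]; hill = pp[P_SERCA_HILL]
    rb = (ca_nsr / pp[P_SERCA_KM_SR]) ** hill
    fb = (ca_c / km_up) ** hill
    j_up_c = vmax * pp[P_W_UP_C] * (fb - rb) / (1.0 + fb + rb)
    fb = (ca_dt / km_up) ** hill
    j_up_dt = vmax * pp[P_W_UP_DT] * (fb - rb) / (1.0 + fb + rb)
    fb = (ca_ds / km_up) ** hill
    j_up_ds = vmax * pp[P_W_UP_DS] * (fb - rb) / (1.0 + fb + rb)
    j_leak = pp[P_K_LEAK] * (ca_nsr - ca_c)
    j_rel_t = max(0.0, pp[P_RYR_G] * y[S_RYROT] * y[S_RYRAT] * (ca_jt - ca_dt))
    j_rel_s = max(0.0, pp[P_RYR_G] * y[S_RYROS] * y[S_RYRAS] * (ca_js - ca_ds))

    i_membrane = (i_na + i_ca_dt + i_ca_ds + i_ca_st + i_ca_ss + i_kto
                  + i_kss + i_k1 + i_f + i_kb + i_nab + i_cab_st + i_cab_ss
                  + i_naca_dt + i_naca_ds + i_naca_st + i_naca_ss
                  + i_nak + i_pca_dt + i_pca_ds + i_pca_st + i_pca_ss)

    if not use_vcmd:
        dy[S_V] = -(i_membrane + stim) / pp[P_CM]

    # --- gates ------------------------------------------------------------
    for gi in range(N_VGATES):
        base = _G0 + gi * 6
        inf = 1.0 / (1.0 + math.exp(-(v - pp[base]) / pp[base + 1]))
        tau = pp[base + 2] + pp[base + 3] / math.cosh((v - pp[base + 4]) / pp[base + 5])
        si = _VG[gi]
        dy[si] = (inf - y[si]) / tau

    km_fca = pp[P_KM_FCA]; tau_fca = pp[P_TAU_FCA]
    dy[S_FCA_T] = (km_fca / (km_fca + max(ca_dt, 0.0)) - y[S_FCA_T]) / tau_fca
    dy[S_FCA_S] = (km_fca / (km_fca + max(ca_ds, 0.0)) - y[S_FCA_S]) / tau_fca
    km_o = pp[P_RYR_KM_O]; h_o = pp[P_RYR_H_O]; tau_o = pp[P_RYR_TAU_O]
    km_a = pp[P_RYR_KM_A]; h_a = pp[P_RYR_H_A]; tau_a = pp[P_RYR_TAU_A]
    r = (max(ca_dt, 1e-12) / km_o) ** h_o
    dy[S_RYROT] = (r / (1.0 + r) - y[S_RYROT]) / tau_o
    dy[S_RYRAT] = (1.0 / (1.0 + (max(ca_dt, 0.0) / km_a) ** h_a) - y[S_RYRAT]) / tau_a
    r = (max(ca_ds, 1e-12) / km_o) ** h_o
    dy[S_RYROS] = (r / (1.0 + r) - y[S_RYROS]) / tau_o
    dy[S_RYRAS] = (1.0 / (1.0 + (max(ca_ds, 0.0) / km_a) ** h_a) - y[S_RYRAS]) / tau_a

    # --- Ca balances ------------------------------------------------------
    v_c = pp[P_V_C]; v_ss = pp[P_V_SS]; v_st = pp[P_V_ST]
    v_ds = pp[P_V_DS]; v_dt = pp[P_V_DT]; v_nsr = pp[P_V_NSR]
    v_js = pp[P_V_JS]; v_jt = pp[P_V_JT]; v_lum = pp[P_V_LUM]

    two_f = 2.0 * F
    d_dt = -(i_ca_dt + i_pca_dt) / (two_f * v_dt) + i_naca_dt / (F * v_dt)
    d_ds = -(i_ca_ds + i_pca_ds) / (two_f * v_ds) + i_naca_ds / (F * v_ds)
    d_st = -(i_ca_st + i_pca_st + i_cab_st) / (two_f * v_st) \
        + i_naca_st / (F * v_st)
    d_ss = -(i_ca_ss + i_pca_ss + i_cab_ss) / (two_f * v_ss) \
        + i_naca_ss / (F * v_ss)
    d_lum = (i_ca_dt + i_ca_st + i_cab_st + i_pca_dt + i_pca_st) / (two_f * v_lum) \
        - (i_naca_dt + i_naca_st) / (F * v_lum)

    d_c = -j_up_c + j_leak
    d_dt += -j_up_dt * (v_c / v_dt)
    d_ds += -j_up_ds * (v_c / v_ds)
    d_nsr = (j_up_c + j_up_dt + j_up_ds - j_leak) * (v_c / v_nsr)
    d_jt = -j_rel_t
    d_dt += j_rel_t * (v_jt / v_dt)
    d_js = -j_rel_s
    d_ds += j_rel_s * (v_js / v_ds)

    g = (ca_dt - ca_st) / pp[P_TAU_DT_ST]
    d_dt -= g; d_st += g * (v_dt / v_st)
    g = (ca_ds - ca_ss) / pp[P_TAU_DS_SS]
    d_ds -= g; d_ss += g * (v_ds / v_ss)
    g = (ca_st - ca_c) / pp[P_TAU_ST_C]
    d_st -= g; d_c += g * (v_st / v_c)
    g = (ca_ss - ca_c) / pp[P_TAU_SS_C]
    d_ss -= g; d_c += g * (v_ss / v_c)
    g = (ca_jt - ca_nsr) / pp[P_TAU_JT_NSR]
    d_jt -= g; d_nsr += g * (v_jt / v_nsr)
    g = (ca_js - ca_nsr) / pp[P_TAU_JS_NSR]
    d_js -= g; d_nsr += g * (v_js / v_nsr)
    d_lum -= (ca_lum - ca_e) / pp[P_TAU_LUM_E]
    if pp[P_DIALYSIS] > 0.5:
        d_c += (pp[P_CA_P] - ca_c) / pp[P_TAU_CA_CP]

    # endogenous buffers
    tot = pp[P_CMDN_TOT]; kon = pp[P_CMDN_ON]; koff = pp[P_CMDN_OFF]
    rate = kon * ca_c * (tot - y[S_BCM_C]) - koff * y[S_BCM_C]
    dy[S_BCM_C] = rate; d_c -= rate
    rate = kon * ca_ss * (tot - y[S_BCM_SS]) - koff * y[S_BCM_SS]
    dy[S_BCM_SS] = rate; d_ss -= rate
    rate = kon * ca_st * (tot - y[S_BCM_ST]) - koff * y[S_BCM_ST]
    dy[S_BCM_ST] = rate; d_st -= rate
    rate = kon * ca_ds * (tot - y[S_BCM_DS]) - koff * y[S_BCM_DS]
    dy[S_BCM_DS] = rate; d_ds -= rate
    rate = kon * ca_dt * (tot - y[S_BCM_DT]) - koff * y[S_BCM_DT]
    dy[S_BCM_DT] = rate; d_dt -= rate
    rate = pp[P_HTRPN_ON] * ca_c * (pp[P_HTRPN_TOT] - y[S_BH]) \
        - pp[P_HTRPN_OFF] * y[S_BH]
    dy[S_BH] = rate; d_c -= rate
    rate = pp[P_LTRPN_ON] * ca_c * (pp[P_LTRPN_TOT] - y[S_BL]) \
        - pp[P_LTRPN_OFF] * y[S_BL]
    dy[S_BL] = rate; d_c -= rate
    rate = pp[P_CSQN_ON] * ca_js * (pp[P_CSQN_TOT] - y[S_BCS_S]) \
        - pp[P_CSQN_OFF] * y[S_BCS_S]
    dy[S_BCS_S] = rate; d_js -= rate
    rate = pp[P_CSQN_ON] * ca_jt * (pp[P_CSQN_TOT] - y[S_BCS_T]) \
        - pp[P_CSQN_OFF] * y[S_BCS_T]
    dy[S_BCS_T] = rate; d_jt -= rate
    rate = pp[P_BTS_ON] * ca_lum * (pp[P_BTS_TOT] - y[S_BTS]) \
        - pp[P_BTS_OFF] * y[S_BTS]
    dy[S_BTS] = rate; d_lum -= rate

    # exogenous buffer
    if pp[P_BUF_ENABLED] > 0.5:
        kon = pp[P_BUF_KON]; koff = pp[P_BUF_KOFF]
        r_c = kon * ca_c * y[S_BF_C] - koff * y[S_BB_C]
        r_ss = kon * ca_ss * y[S_BF_SS] - koff * y[S_BB_SS]
        r_st = kon * ca_st * y[S_BF_ST] - koff * y[S_BB_ST]
        r_ds = kon * ca_ds * y[S_BF_DS] - koff * y[S_BB_DS]
        r_dt = kon * ca_dt * y[S_BF_DT] - koff * y[S_BB_DT]
        d_c -= r_c; d_ss -= r_ss; d_st -= r_st; d_ds -= r_ds; d_dt -= r_dt
        df_c = -r_c; df_ss = -r_ss; df_st = -r_st; df_ds = -r_ds; df_dt = -r_dt
        db_c = r_c; db_ss = r_ss; db_st = r_st; db_ds = r_ds; db_dt = r_dt
        # free species diffusion
        g = (y[S_BF_DT] - y[S_BF_ST]) / pp[P_TAU_B_DT_ST]
        df_dt -= g; df_st += g * (v_dt / v_st)
        g = (y[S_BF_DS] - y[S_BF_SS]) / pp[P_TAU_B_DS_SS]
        df_ds -= g; df_ss += g * (v_ds / v_ss)
        g = (y[S_BF_ST] - y[S_BF_C]) / pp[P_TAU_B_ST_C]
        df_st -= g; df_c += g * (v_st / v_c)
        g = (y[S_BF_SS] - y[S_BF_C]) / pp[P_TAU_B_SS_C]
        df_ss -= g; df_c += g * (v_ss / v_c)
        # bound species diffusion
        g = (y[S_BB_DT] - y[S_BB_ST]) / pp[P_TAU_B_DT_ST]
        db_dt -= g; db_st += g * (v_dt / v_st)
        g = (y[S_BB_DS] - y[S_BB_SS]) / pp[P_TAU_B_DS_SS]
        db_ds -= g; db_ss += g * (v_ds / v_ss)
        g = (y[S_BB_ST] - y[S_BB_C]) / pp[P_TAU_B_ST_C]
        db_st -= g; db_c += g * (v_st / v_c)
        g = (y[S_BB_SS] - y[S_BB_C]) / pp[P_TAU_B_SS_C]
        db_ss -= g; db_c += g * (v_ss / v_c)
        if pp[P_DIALYSIS] > 0.5:
            df_c += (pp[P_B_FREE_P] - y[S_BF_C]) / pp[P_TAU_B_CP]
            db_c += (pp[P_B_BOUND_P] - y[S_BB_C]) / pp[P_TAU_B_CP]
        dy[S_BF_C] = df_c; dy[S_BF_SS] = df_ss; dy[S_BF_ST] = df_st
        dy[S_BF_DS] = df_ds; dy[S_BF_DT] = df_dt
        dy[S_BB_C] = db_c; dy[S_BB_SS] = db_ss; dy[S_BB_ST] = db_st
        dy[S_BB_DS] = db_ds; dy[S_BB_DT] = db_dt

    # monovalent ions
    i_naca = i_naca_dt + i_naca_ds + i_naca_st + i_naca_ss
    dna = -(i_na + i_nab + 3.0 * i_nak + 0.5 * i_f + 3.0 * i_naca) \
        / (F * pp[P_V_AQ])
    dk = -(i_kto + i_kss + i_k1 + i_kb + 0.5 * i_f - 2.0 * i_nak + stim) \
        / (F * pp[P_V_AQ])
    if pp[P_DIALYSIS] > 0.5 and pp[P_HAS_NA_P] > 0.5:
        dna += (pp[P_NA_P] - na_i) / pp[P_TAU_CA_CP]
    if pp[P_DIALYSIS] > 0.5 and pp[P_HAS_K_P] > 0.5:
        dk += (pp[P_K_P] - k_i) / pp[P_TAU_CA_CP]
    dy[S_NAI] = dna
    dy[S_KI] = dk

    dy[S_CAC] = d_c
    dy[S_CASS] = d_ss
    dy[S_CAST] = d_st
    dy[S_CADS] = d_ds
    dy[S_CADT] = d_dt
    dy[S_CANSR] = d_nsr
    dy[S_CAJS] = d_js
    dy[S_CAJT] = d_jt
    dy[S_CALUM] = d_lum
    return dy


def pack_params(ctx) -> np.ndarray:
    """Flatten a run context (:class:`dyadca.engine._Ctx`) into the packed
    vector consumed by :func:`rhs_kernel`."""
    from .constants import FARADAY, vt
    from .transport import _GATE_INF, _GATE_TAU

    p = ctx.params
    cur = p.data["currents"]
    ion = dict(p.data["ionic"])
    if ctx.ionic:
        ion.update(ctx.ionic)
    dis = ctx.disabled

    def en(label):
        return 0.0 if label in dis else 1.0

    pp = np.zeros(N_PACKED)

    def put(name, value):
        pp[P[name]] = float(value)

    put("cm", p.cm)
    put("vth", vt(p.temperature))
    put("faraday", FARADAY)
    for nm, attr in (("v_c", "v_c"), ("v_ss", "v_ss"), ("v_st", "v_st"),
                     ("v_ds", "v_ds"), ("v_dt", "v_dt"), ("v_nsr", "v_nsr"),
                     ("v_js", "v_js"), ("v_jt", "v_jt"), ("v_lum", "v_lum"),
                     ("v_aq", "v_aq")):
        put(nm, getattr(ctx, attr))
    for nm in ("tau_dt_st", "tau_ds_ss", "tau_st_c", "tau_ss_c",
               "tau_jt_nsr", "tau_js_nsr", "tau_lum_e", "tau_ca_cp",
               "tau_b_dt_st", "tau_b_ds_ss", "tau_b_st_c", "tau_b_ss_c",
               "tau_b_cp"):
        put(nm, getattr(ctx, nm))
    put("ca_e", ion["ca_e"]); put("na_e", ion["na_e"]); put("k_e", ion["k_e"])
    put("g_na", cur["na"]["g"])
    put("p_ca", cur["ca"]["p"])
    put("km_fca", cur["ca"]["km_fca"])
    put("tau_fca", cur["ca"]["tau_fca"])
    put("k_naca", cur["naca"]["k"]); put("km_na", cur["naca"]["km_na"])
    put("km_ca", cur["naca"]["km_ca"]); put("ksat", cur["naca"]["ksat"])
    put("eta", cur["naca"]["eta"])
    put("i_pca_max", cur["pca"]["imax"]); put("km_pca", cur["pca"]["km"])
    put("i_nak_max", cur["nak"]["imax"])
    put("km_nak_na", cur["nak"]["km_na"]); put("km_nak_k", cur["nak"]["km_k"])
    put("g_k1", cur["k1"]["g"]); put("g_kto", cur["kto"]["g"])
    put("g_kss", cur["kss"]["g"]); put("g_f", cur["f"]["g"])
    put("g_kb", cur["kb"]["g"]); put("g_nab", cur["nab"]["g"])
    put("g_cab", cur["cab"]["g"]); put("cab_frac_t", cur["cab"]["frac_t"])
    put("serca_vmax", p.get("serca.vmax")); put("serca_km", p.get("serca.km"))
    put("serca_km_sr", p.get("serca.km_sr"))
    put("serca_hill", p.get("serca.hill")); put("k_leak", p.get("serca.k_leak"))
    for nm in ("g", "km_o", "h_o", "tau_o", "km_a", "h_a", "tau_a"):
        put(f"ryr_{nm}", p.get(f"ryr.{nm}"))
    for buf, (tot, kon, koff) in (("cmdn", ctx.cmdn), ("htrpn", ctx.htrpn),
                                  ("ltrpn", ctx.ltrpn), ("csqn", ctx.csqn),
                                  ("bts", ctx.bts)):
        put(f"{buf}_tot", tot); put(f"{buf}_on", kon); put(f"{buf}_off", koff)
    for tr in ("ca", "naca", "pca"):
        w_dt, w_ds, w_st, w_ss = ctx.sites[tr]
        put(f"w_{tr}_dt", w_dt); put(f"w_{tr}_ds", w_ds)
        put(f"w_{tr}_st", w_st); put(f"w_{tr}_ss", w_ss)
    f_dt, f_ds, f_bulk = ctx.dist.serca_sites()
    put("w_up_dt", f_dt); put("w_up_ds", f_ds); put("w_up_c", f_bulk)
    put("buf_enabled", 1.0 if ctx.buffer.enabled else 0.0)
    put("buf_kon", ctx.buffer.k_on); put("buf_koff", ctx.buffer.k_off)
    put("b_free_p", ctx.b_free_p); put("b_bound_p", ctx.b_bound_p)
    put("ca_p", ctx.ca_p)
    put("dialysis", 1.0 if ctx.dialysis else 0.0)
    put("has_na_p", 0.0 if ctx.na_p is None else 1.0)
    put("na_p", 0.0 if ctx.na_p is None else float(ctx.na_p))
    put("has_k_p", 0.0 if ctx.k_p is None else 1.0)
    put("k_p", 0.0 if ctx.k_p is None else float(ctx.k_p))
    for label in ("na", "ca", "kto", "kss", "k1", "f", "kb", "nab", "cab",
                  "naca", "nak", "pca"):
        put(f"en_{label}", en(label))
    gates = ("m", "h", "j", "d", "f", "r_to", "s_to", "r_ss", "y_f")
    for gi, gname in enumerate(gates):
        vh, k = _GATE_INF[gname]
        base, amp, vc, kc = _GATE_TAU[gname]
        off = GATE_BLOCK + gi * 6
        pp[off:off + 6] = (vh, k, base, amp, vc, kc)
    return pp
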