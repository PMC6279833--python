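"""Paci et al. 2013 ventricular-like hiPSC-CM action potential model.

Hand transcription of the published ventricular variant (18 state variables,
SI units internally: volts, seconds, mM).  Every scalable current or flux is
multiplied by a named scale factor so the right-hand side has the form
``v' = -sum_i q_i I_i(v, s)``; with all factors at one the model reproduces
the published equations.

The immature cell is spontaneously active; under 1 Hz field pacing it
produces a long action potential (APD80 on the order of 400 ms) and a slow
calcium transient, both characteristic of immature myocytes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NAME = "paci2013_ventricular"

# Order matches the printed immature maturation-map diagonal (after the
# leading geometry factor): Na, CaL, to, Ks, Kr, K1, NaCa, NaK, pCa, f,
# bNa, bCa, leak, up, rel.
PARAM_NAMES = (
    "I_Na", "I_CaL", "I_to", "I_Ks", "I_Kr", "I_K1",
    "I_NaCa", "I_NaK", "I_pCa", "I_f", "I_bNa", "I_bCa",
    "J_leak", "J_up", "J_rel",
)

STATE_NAMES = (
    "Vm", "m", "h", "j", "d", "f1", "f2", "fCa",
    "Xr1", "Xr2", "Xs", "Xf", "q", "r", "Nai", "g", "Cai", "Ca_SR",
)

#: published maximal conductances / rates, (value, units)
BASE_CONDUCTANCES = {
    "I_Na": (3671.2302, "S/F"),
    "I_CaL": (8.635702e-5, "m^3/(F*s)"),
    "I_to": (29.9038, "S/F"),
    "I_Ks": (2.041, "S/F"),
    "I_Kr": (29.8667, "S/F"),
    "I_K1": (28.1492, "S/F"),
    "I_NaCa": (4900.0, "A/F"),
    "I_NaK": (1.841424, "A/F"),
    "I_pCa": (0.4125, "A/F"),
    "I_f": (30.10312, "S/F"),
    "I_bNa": (0.9, "S/F"),
    "I_bCa": (0.69264, "S/F"),
    "J_leak": (4.4444e-4, "1/s"),
    "J_up": (0.56064, "mM/s"),
    "J_rel": (1.0, "relative"),
}

GEOMETRY = {
    "Cm_F": 9.87109e-11,      # membrane capacitance
    "Vc_um3": 8800.0,         # cytosolic volume
    "V_SR_um3": 583.73,       # sarcoplasmic-reticulum volume
}

# published initial state (quasi-steady spontaneous activity)
Y0 = np.array([
    -0.0743340057623841,      # Vm (V)
    0.102953468725004,        # m
    0.786926637881461,        # h
    0.253943221774722,        # j
    8.96088425225182e-5,      # d
    0.970411811263976,        # f1
    0.999965815466749,        # f2
    0.998925296531804,        # fCa
    0.00778547011240132,      # Xr1
    0.432162576531617,        # Xr2
    0.0322944866983666,       # Xs
    0.100615100568753,        # Xf
    0.839295925773219,        # q
    0.00573289893326379,      # r
    10.9248496211574,         # Nai (mM)
    0.999999981028517,        # g (RyR inactivation)
    1.80773974140477e-5,      # Cai (mM)
    0.273423475193100,        # Ca_SR (mM)
])

# physical constants
_F = 96485.3415
_R = 8.314472
_T = 310.0

# native time unit is seconds, voltage in volts
T_NATIVE_PER_MS = 1e-3
V_TO_MV = 1000.0
V_INDEX = 0
CAI_INDEX = 16


@njit(cache=False, fastmath=False)
def _core(t, y, s, geom, istim):
    """Derivatives and scaled current values.

    ``s`` holds the 15 scale factors in PARAM_NAMES order, ``geom`` the
    geometry factor multiplying the membrane-current contribution to the
    intracellular concentration balances, ``istim`` a depolarizing stimulus
    in A/F.  Returns (dy, currents) with transmembrane currents in A/F and
    SR fluxes in mM/s.
    """
    Vm = y[0]
    m = y[1]
    h = y[2]
    j = y[3]
    d = y[4]
    f1 = y[5]
    f2 = y[6]
    fCa = y[7]
    Xr1 = y[8]
    Xr2 = y[9]
    Xs = y[10]
    Xf = y[11]
    q = y[12]
    r = y[13]
    Nai = y[14]
    g = y[15]
    Cai = y[16]
    Ca_SR = y[17]

    Cm = 9.87109e-11
    Vc = 8800.0
    V_SR = 583.73
    F = _F
    RT_F = _R * _T / _F        # volts

    Nao = 151.0
    Ko = 5.4
    Cao = 1.8
    Ki = 150.0

    if Cai < 1e-12:
        Cai = 1e-12
    if Ca_SR < 1e-12:
        Ca_SR = 1e-12

    E_Na = RT_F * np.log(Nao / Nai)
    E_K = RT_F * np.log(Ko / Ki)
    E_Ks = RT_F * np.log((Ko + 0.03 * Nao) / (Ki + 0.03 * Nai))
    E_Ca = 0.5 * RT_F * np.log(Cao / Cai)
    E_f = -0.017

    Vmv = Vm * 1000.0          # mV, used by the gate formulations

    # ---- fast sodium current -------------------------------------------
    i_Na = s[0] * 3671.2302 * m ** 3 * h * j * (Vm - E_Na)

    m_inf = (1.0 / (1.0 + np.exp((-Vmv - 34.1) / 5.9))) ** (1.0 / 3.0)
    alpha_m = 1.0 / (1.0 + np.exp((-Vmv - 60.0) / 5.0))
    beta_m = 0.1 / (1.0 + np.exp((Vmv + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((Vmv - 50.0) / 200.0))
    tau_m = alpha_m * beta_m / 1000.0

    h_inf = 1.0 / np.sqrt(1.0 + np.exp((Vmv + 72.1) / 5.7))
    if Vm < -0.0385:
        alpha_h = 0.057 * np.exp(-(Vmv + 80.0) / 6.8)
        beta_h = 2.7 * np.exp(0.079 * Vmv) + 3.1e5 * np.exp(0.3485 * Vmv)
        tau_h = 1.5 / ((alpha_h + beta_h) * 1000.0)
    else:
        tau_h = 1.5 * 1.6947 / 1000.0

    j_inf = h_inf
    if Vm < -0.04:
        alpha_j = ((-25428.0 * np.exp(0.2444 * Vmv) - 6.948e-6 * np.exp(-0.04391 * Vmv))
                   * (Vmv + 37.78) / (1.0 + np.exp(0.311 * (Vmv + 79.23))))
        beta_j = 0.02424 * np.exp(-0.01052 * Vmv) / (1.0 + np.exp(-0.1378 * (Vmv + 40.14)))
    else:
        alpha_j = 0.0
        beta_j = 0.6 * np.exp(0.057 * Vmv) / (1.0 + np.exp(-0.1 * (Vmv + 32.0)))
    tau_j = 7.0 / ((alpha_j + beta_j) * 1000.0)

    # ---- L-type calcium current ----------------------------------------
    Veff = Vm
    if np.abs(Veff) < 1e-9:
        Veff = 1e-9
    efac = np.exp(2.0 * Veff * F / (_R * _T))
    i_CaL = (s[1] * 8.635702e-5 * 4.0 * Veff * F * F / (_R * _T)
             * (Cai * efac - 0.341 * Cao) / (efac - 1.0) * d * f1 * f2 * fCa)

    d_inf = 1.0 / (1.0 + np.exp(-(Vmv + 9.1) / 7.0))
    alpha_d = 0.25 + 1.4 / (1.0 + np.exp((-Vmv - 35.0) / 13.0))
    beta_d = 1.4 / (1.0 + np.exp((Vmv + 5.0) / 5.0))
    gamma_d = 1.0 / (1.0 + np.exp((-Vmv + 50.0) / 20.0))
    tau_d = (alpha_d * beta_d + gamma_d) / 1000.0

    f1_inf = 1.0 / (1.0 + np.exp((Vmv + 26.0) / 3.0))
    tau_f1 = (20.0
              + 1102.5 * np.exp(-(((Vmv + 27.0) ** 2 / 15.0) ** 2))
              + 200.0 / (1.0 + np.exp((13.0 - Vmv) / 10.0))
              + 180.0 / (1.0 + np.exp((30.0 + Vmv) / 10.0))) / 1000.0
    if f1_inf - f1 > 0.0:
        tau_f1 = tau_f1 * (1.0 + 1433.0 * (Cai - 50.0e-6))

    f2_inf = 0.33 + 0.67 / (1.0 + np.exp((Vmv + 35.0) / 4.0))
    tau_f2 = (600.0 * np.exp(-((Vmv + 25.0) ** 2) / 170.0)
              + 31.0 / (1.0 + np.exp((25.0 - Vmv) / 10.0))
              + 16.0 / (1.0 + np.exp((30.0 + Vmv) / 10.0))) / 1000.0

    alpha_fCa = 1.0 / (1.0 + (Cai / 0.0006) ** 8)
    beta_fCa = 0.1 / (1.0 + np.exp((Cai - 0.0009) / 0.0002))
    gamma_fCa = 0.3 / (1.0 + np.exp((Cai - 0.00075) / 0.0008))
    fCa_inf = (alpha_fCa + beta_fCa + gamma_fCa) / 1.3156
    if Vm > -0.06 and fCa_inf > fCa:
        const_fCa = 0.0
    else:
        const_fCa = 1.0
    tau_fCa = 0.002

    # ---- transient outward current -------------------------------------
    i_to = s[2] * 29.9038 * (Vm - E_K) * q * r
    q_inf = 1.0 / (1.0 + np.exp((Vmv + 53.0) / 13.0))
    tau_q = (6.06 + 39.102 / (0.57 * np.exp(-0.08 * (Vmv + 44.0))
                              + 0.065 * np.exp(0.1 * (Vmv + 45.93)))) / 1000.0
    r_inf = 1.0 / (1.0 + np.exp(-(Vmv - 22.3) / 18.75))
    tau_r = (2.75352 + 14.40516 / (1.037 * np.exp(0.09 * (Vmv + 30.61))
                                   + 0.369 * np.exp(-0.12 * (Vmv + 23.84)))) / 1000.0

    # ---- slow delayed rectifier ----------------------------------------
    i_Ks = (s[3] * 2.041 * (Vm - E_Ks) * Xs ** 2
            * (1.0 + 0.6 / (1.0 + (3.8e-5 / Cai) ** 1.4)))
    Xs_inf = 1.0 / (1.0 + np.exp((-Vmv - 20.0) / 16.0))
    alpha_Xs = 1100.0 / np.sqrt(1.0 + np.exp((-10.0 - Vmv) / 6.0))
    beta_Xs = 1.0 / (1.0 + np.exp((-60.0 + Vmv) / 20.0))
    tau_Xs = alpha_Xs * beta_Xs / 1000.0

    # ---- rapid delayed rectifier ---------------------------------------
    i_Kr = s[4] * 29.8667 * (Vm - E_K) * Xr1 * Xr2 * np.sqrt(Ko / 5.4)
    V_half = 1000.0 * (-RT_F / 2.3 * np.log10((1.0 + Cao / 2.6) ** 4
                                              / (1.0 + Cao / 0.58) ** 4) - 0.019)
    Xr1_inf = 1.0 / (1.0 + np.exp((V_half - Vmv) / 4.9))
    alpha_Xr1 = 450.0 / (1.0 + np.exp((-45.0 - Vmv) / 10.0))
    beta_Xr1 = 6.0 / (1.0 + np.exp((30.0 + Vmv) / 11.5))
    tau_Xr1 = alpha_Xr1 * beta_Xr1 / 1000.0
    Xr2_inf = 1.0 / (1.0 + np.exp((Vmv + 88.0) / 50.0))
    alpha_Xr2 = 3.0 / (1.0 + np.exp((-60.0 - Vmv) / 20.0))
    beta_Xr2 = 1.12 / (1.0 + np.exp((-60.0 + Vmv) / 20.0))
    tau_Xr2 = alpha_Xr2 * beta_Xr2 / 1000.0

    # ---- inward rectifier ----------------------------------------------
    alpha_K1 = 3.91 / (1.0 + np.exp(0.5942 * (Vmv - E_K * 1000.0 - 200.0)))
    beta_K1 = ((-1.509 * np.exp(0.0002 * (Vmv - E_K * 1000.0 + 100.0))
                + np.exp(0.5886 * (Vmv - E_K * 1000.0 - 10.0)))
               / (1.0 + np.exp(0.4547 * (Vmv - E_K * 1000.0))))
    XK1_inf = alpha_K1 / (alpha_K1 + beta_K1)
    i_K1 = s[5] * 28.1492 * XK1_inf * (Vm - E_K) * np.sqrt(Ko / 5.4)

    # ---- exchangers, pumps, background ---------------------------------
    gam = 0.35
    alpha_ncx = 2.8571432
    Km_Ca = 1.38
    Km_Nai = 87.5
    Ksat = 0.1
    i_NaCa = (s[6] * 4900.0
              * (np.exp(gam * Vm * F / (_R * _T)) * Nai ** 3 * Cao
                 - np.exp((gam - 1.0) * Vm * F / (_R * _T)) * Nao ** 3 * Cai * alpha_ncx)
              / ((Km_Nai ** 3 + Nao ** 3) * (Km_Ca + Cao)
                 * (1.0 + Ksat * np.exp((gam - 1.0) * Vm * F / (_R * _T)))))

    i_NaK = (s[7] * 1.841424 * Ko / (Ko + 1.0) * Nai / (Nai + 40.0)
             / (1.0 + 0.1245 * np.exp(-0.1 * Vm * F / (_R * _T))
                + 0.0353 * np.exp(-Vm * F / (_R * _T))))

    i_PCa = s[8] * 0.4125 * Cai / (Cai + 0.0005)

    i_f = s[9] * 30.10312 * Xf * (Vm - E_f)
    Xf_inf = 1.0 / (1.0 + np.exp((Vmv + 77.85) / 5.0))
    tau_Xf = 1900.0 / (1.0 + np.exp((Vmv + 15.0) / 10.0)) / 1000.0

    i_b_Na = s[10] * 0.9 * (Vm - E_Na)
    i_b_Ca = s[11] * 0.69264 * (Vm - E_Ca)

    # ---- sarcoplasmic reticulum fluxes (mM/s) --------------------------
    j_leak = s[12] * (Ca_SR - Cai) * 4.4444e-4
    j_up = s[13] * 0.56064 / (1.0 + (0.00025 / Cai) ** 2)
    j_rel = s[14] * (8.232 + 16.464 * Ca_SR ** 2 / (0.0625 + Ca_SR ** 2)) * d * g * 0.0411

    if Cai <= 0.00035:
        g_inf = 1.0 / (1.0 + (Cai / 0.00035) ** 6)
    else:
        g_inf = 1.0 / (1.0 + (Cai / 0.00035) ** 16)
    if g_inf > g and Vm > -0.06:
        const_g = 0.0
    else:
        const_g = 1.0
    tau_g = 0.002

    # ---- balances -------------------------------------------------------
    Cai_bufc = 1.0 / (1.0 + 0.25 * 0.001 / (Cai + 0.001) ** 2)
    CaSR_bufSR = 1.0 / (1.0 + 10.0 * 0.3 / (Ca_SR + 0.3) ** 2)

    memb_to_conc = geom * Cm / (2.0 * Vc * 1e-18 * F)  # A/F -> mM/s (divalent)
    memb_to_conc_na = geom * Cm / (Vc * 1e-18 * F)

    dy = np.empty(18)
    dy[0] = -(i_K1 + i_to + i_Kr + i_Ks + i_CaL + i_NaK + i_Na + i_NaCa
              + i_PCa + i_f + i_b_Na + i_b_Ca) + istim
    dy[1] = (m_inf - m) / tau_m
    dy[2] = (h_inf - h) / tau_h
    dy[3] = (j_inf - j) / tau_j
    dy[4] = (d_inf - d) / tau_d
    dy[5] = (f1_inf - f1) / tau_f1
    dy[6] = (f2_inf - f2) / tau_f2
    dy[7] = const_fCa * (fCa_inf - fCa) / tau_fCa
    dy[8] = (Xr1_inf - Xr1) / tau_Xr1
    dy[9] = (Xr2_inf - Xr2) / tau_Xr2
    dy[10] = (Xs_inf - Xs) / tau_Xs
    dy[11] = (Xf_inf - Xf) / tau_Xf
    dy[12] = (q_inf - q) / tau_q
    dy[13] = (r_inf - r) / tau_r
    dy[14] = -memb_to_conc_na * (i_Na + i_b_Na + 3.0 * i_NaK + 3.0 * i_NaCa)
    dy[15] = const_g * (g_inf - g) / tau_g
    dy[16] = Cai_bufc * (j_leak - j_up + j_rel
                         - (i_CaL + i_b_Ca + i_PCa - 2.0 * i_NaCa) * memb_to_conc)
    dy[17] = CaSR_bufSR * Vc / V_SR * (j_up - (j_rel + j_leak))

    cur = np.empty(15)
    cur[0] = i_Na
    cur[1] = i_CaL
    cur[2] = i_to
    cur[3] = i_Ks
    cur[4] = i_Kr
    cur[5] = i_K1
    cur[6] = i_NaCa
    cur[7] = i_NaK
    cur[8] = i_PCa
    cur[9] = i_f
    cur[10] = i_b_Na
    cur[11] = i_b_Ca
    cur[12] = j_leak
    cur[13] = j_up
    cur[14] = j_rel
    return dy, cur


@njit(cache=False)
def rhs(t, y, s, geom, istim):
    dy, _ = _core(t, y, s, geom, istim)
    return dy


@njit(cache=False)
def currents(t, y, s, geom):
    _, cur = _core(t, y, s, geom, 0.0)
    return cur
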