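"""ten Tusscher & Panfilov 2006 human ventricular (epicardial) AP model.

Hand transcription of the published equations (19 state variables, native
units: mV, ms, mM).  As for the immature model, every current or flux carries
a named multiplicative scale factor.  The adult cell is quiescent and is
paced; its action potential is much shorter and its calcium upstroke much
faster than the immature model's.

The model has no funny current; ``I_f`` is exposed as a scalable
zero-conductance entry so that parameter vectors align by key with the
17-entry adult maturation-map diagonal.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NAME = "tentusscher2006_epi"

PARAM_NAMES = (
    "I_Na", "I_CaL", "I_to", "I_Ks", "I_Kr", "I_K1",
    "I_NaCa", "I_NaK", "I_pCa", "I_f", "I_pK", "I_bNa", "I_bCa",
    "J_leak", "J_up", "J_rel",
)

STATE_NAMES = (
    "Vm", "Xr1", "Xr2", "Xs", "m", "h", "j", "d", "f", "f2", "fCass",
    "s", "r", "Cai", "Cass", "Casr", "Nai", "Ki", "Rbar",
)

BASE_CONDUCTANCES = {
    "I_Na": (14.838, "nS/pF"),
    "I_CaL": (3.98e-5, "cm^3/(uF*s)"),
    "I_to": (0.294, "nS/pF"),
    "I_Ks": (0.392, "nS/pF"),
    "I_Kr": (0.153, "nS/pF"),
    "I_K1": (5.405, "nS/pF"),
    "I_NaCa": (1000.0, "pA/pF"),
    "I_NaK": (2.724, "pA/pF"),
    "I_pCa": (0.1238, "pA/pF"),
    "I_f": (0.0, "nS/pF"),
    "I_pK": (0.0146, "nS/pF"),
    "I_bNa": (0.00029, "nS/pF"),
    "I_bCa": (0.000592, "nS/pF"),
    "J_leak": (0.00036, "1/ms"),
    "J_up": (0.006375, "mM/ms"),
    "J_rel": (0.102, "mM/ms"),
}

GEOMETRY = {
    "Cm_uF": 0.185,
    "Vc": 0.016404,
    "Vsr": 0.001094,
    "Vss": 0.00005468,
}

Y0 = np.array([
    -85.23,       # Vm (mV)
    0.00621,      # Xr1
    0.4712,       # Xr2
    0.0095,       # Xs
    0.00172,      # m
    0.7444,       # h
    0.7045,       # j
    3.373e-5,     # d
    0.7888,       # f
    0.9755,       # f2
    0.9953,       # fCass
    0.999998,     # s
    2.42e-8,      # r
    0.000126,     # Cai (mM)
    0.00036,      # Cass (mM)
    3.64,         # Casr (mM)
    8.604,        # Nai (mM)
    136.89,       # Ki (mM)
    0.9073,       # Rbar
])

_F = 96485.3415
_R = 8314.472     # J/(kmol*K) so that R*T/F is in mV
_T = 310.0

T_NATIVE_PER_MS = 1.0
V_TO_MV = 1.0
V_INDEX = 0
CAI_INDEX = 13


@njit(cache=False, fastmath=False)
def _core(t, y, s_, geom, istim):
    Vm = y[0]
    Xr1 = y[1]
    Xr2 = y[2]
    Xs = y[3]
    m = y[4]
    h = y[5]
    j = y[6]
    d = y[7]
    f = y[8]
    f2 = y[9]
    fCass = y[10]
    sgate = y[11]
    r = y[12]
    Cai = y[13]
    Cass = y[14]
    Casr = y[15]
    Nai = y[16]
    Ki = y[17]
    Rbar = y[18]

    Cm = 0.185
    Vc = 0.016404
    Vsr = 0.001094
    Vss = 0.00005468
    F = _F
    RTONF = _R * _T / _F      # mV

    Ko = 5.4
    Nao = 140.0
    Cao = 2.0

    if Cai < 1e-12:
        Cai = 1e-12
    if Cass < 1e-12:
        Cass = 1e-12
    if Casr < 1e-12:
        Casr = 1e-12

    E_Na = RTONF * np.log(Nao / Nai)
    E_K = RTONF * np.log(Ko / Ki)
    E_Ks = RTONF * np.log((Ko + 0.03 * Nao) / (Ki + 0.03 * Nai))
    E_Ca = 0.5 * RTONF * np.log(Cao / Cai)

    # ---- inward rectifier ----------------------------------------------
    alpha_K1 = 0.1 / (1.0 + np.exp(0.06 * (Vm - E_K - 200.0)))
    beta_K1 = ((3.0 * np.exp(0.0002 * (Vm - E_K + 100.0)) + np.exp(0.1 * (Vm - E_K - 10.0)))
               / (1.0 + np.exp(-0.5 * (Vm - E_K))))
    xK1_inf = alpha_K1 / (alpha_K1 + beta_K1)
    i_K1 = s_[5] * 5.405 * xK1_inf * np.sqrt(Ko / 5.4) * (Vm - E_K)

    # ---- rapid delayed rectifier ---------------------------------------
    i_Kr = s_[4] * 0.153 * np.sqrt(Ko / 5.4) * Xr1 * Xr2 * (Vm - E_K)
    Xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - Vm) / 7.0))
    alpha_xr1 = 450.0 / (1.0 + np.exp((-45.0 - Vm) / 10.0))
    beta_xr1 = 6.0 / (1.0 + np.exp((Vm + 30.0) / 11.5))
    tau_xr1 = alpha_xr1 * beta_xr1
    Xr2_inf = 1.0 / (1.0 + np.exp((Vm + 88.0) / 24.0))
    alpha_xr2 = 3.0 / (1.0 + np.exp((-60.0 - Vm) / 20.0))
    beta_xr2 = 1.12 / (1.0 + np.exp((Vm - 60.0) / 20.0))
    tau_xr2 = alpha_xr2 * beta_xr2

    # ---- slow delayed rectifier ----------------------------------------
    i_Ks = s_[3] * 0.392 * Xs * Xs * (Vm - E_Ks)
    Xs_inf = 1.0 / (1.0 + np.exp((-5.0 - Vm) / 14.0))
    alpha_xs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - Vm) / 6.0))
    beta_xs = 1.0 / (1.0 + np.exp((Vm - 35.0) / 15.0))
    tau_xs = alpha_xs * beta_xs + 80.0

    # ---- fast sodium ----------------------------------------------------
    i_Na = s_[0] * 14.838 * m ** 3 * h * j * (Vm - E_Na)
    m_inf = 1.0 / (1.0 + np.exp((-56.86 - Vm) / 9.03)) ** 2
    alpha_m = 1.0 / (1.0 + np.exp((-60.0 - Vm) / 5.0))
    beta_m = 0.1 / (1.0 + np.exp((Vm + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((Vm - 50.0) / 200.0))
    tau_m = alpha_m * beta_m
    h_inf = 1.0 / (1.0 + np.exp((Vm + 71.55) / 7.43)) ** 2
    if Vm >= -40.0:
        alpha_h = 0.0
        beta_h = 0.77 / (0.13 * (1.0 + np.exp(-(Vm + 10.66) / 11.1)))
    else:
        alpha_h = 0.057 * np.exp(-(Vm + 80.0) / 6.8)
        beta_h = 2.7 * np.exp(0.079 * Vm) + 3.1e5 * np.exp(0.3485 * Vm)
    tau_h = 1.0 / (alpha_h + beta_h)
    j_inf = h_inf
    if Vm >= -40.0:
        alpha_j = 0.0
        beta_j = 0.6 * np.exp(0.057 * Vm) / (1.0 + np.exp(-0.1 * (Vm + 32.0)))
    else:
        alpha_j = ((-2.5428e4 * np.exp(0.2444 * Vm) - 6.948e-6 * np.exp(-0.04391 * Vm))
                   * (Vm + 37.78) / (1.0 + np.exp(0.311 * (Vm + 79.23))))
        beta_j = 0.02424 * np.exp(-0.01052 * Vm) / (1.0 + np.exp(-0.1378 * (Vm + 40.14)))
    tau_j = 1.0 / (alpha_j + beta_j)

    # ---- L-type calcium -------------------------------------------------
    Veff = Vm - 15.0
    if np.abs(Veff) < 1e-7:
        Veff = 1e-7
    efac = np.exp(2.0 * Veff * F / (_R * _T))
    i_CaL = (s_[1] * 3.98e-5 * d * f * f2 * fCass * 4.0 * Veff * F * F / (_R * _T)
             * (0.25 * Cass * efac - Cao) / (efac - 1.0))
    d_inf = 1.0 / (1.0 + np.exp((-8.0 - Vm) / 7.5))
    alpha_d = 1.4 / (1.0 + np.exp((-35.0 - Vm) / 13.0)) + 0.25
    beta_d = 1.4 / (1.0 + np.exp((Vm + 5.0) / 5.0))
    gamma_d = 1.0 / (1.0 + np.exp((50.0 - Vm) / 20.0))
    tau_d = alpha_d * beta_d + gamma_d
    f_inf = 1.0 / (1.0 + np.exp((Vm + 20.0) / 7.0))
    tau_f = (1102.5 * np.exp(-((Vm + 27.0) ** 2) / 225.0)
             + 200.0 / (1.0 + np.exp((13.0 - Vm) / 10.0))
             + 180.0 / (1.0 + np.exp((Vm + 30.0) / 10.0)) + 20.0)
    f2_inf = 0.67 / (1.0 + np.exp((Vm + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * np.exp(-((Vm + 27.0) ** 2) / 240.0)
              + 31.0 / (1.0 + np.exp((25.0 - Vm) / 10.0))
              + 80.0 / (1.0 + np.exp((Vm + 30.0) / 10.0)))
    fCass_inf = 0.6 / (1.0 + (Cass / 0.05) ** 2) + 0.4
    tau_fCass = 80.0 / (1.0 + (Cass / 0.05) ** 2) + 2.0

    # ---- transient outward ----------------------------------------------
    i_to = s_[2] * 0.294 * r * sgate * (Vm - E_K)
    r_inf = 1.0 / (1.0 + np.exp((20.0 - Vm) / 6.0))
    tau_r = 9.5 * np.exp(-((Vm + 40.0) ** 2) / 1800.0) + 0.8
    s_inf = 1.0 / (1.0 + np.exp((Vm + 20.0) / 5.0))
    tau_s = (85.0 * np.exp(-((Vm + 45.0) ** 2) / 320.0)
             + 5.0 / (1.0 + np.exp((Vm - 20.0) / 5.0)) + 3.0)

    # ---- exchangers, pumps, background ----------------------------------
    gam = 0.35
    i_NaCa = (s_[6] * 1000.0
              * (np.exp(gam * Vm / RTONF) * Nai ** 3 * Cao
                 - np.exp((gam - 1.0) * Vm / RTONF) * Nao ** 3 * Cai * 2.5)
              / ((87.5 ** 3 + Nao ** 3) * (1.38 + Cao)
                 * (1.0 + 0.1 * np.exp((gam - 1.0) * Vm / RTONF))))
    i_NaK = (s_[7] * 2.724 * Ko * Nai
             / ((Ko + 1.0) * (Nai + 40.0)
                * (1.0 + 0.1245 * np.exp(-0.1 * Vm / RTONF)
                   + 0.0353 * np.exp(-Vm / RTONF))))
    i_pCa = s_[8] * 0.1238 * Cai / (0.0005 + Cai)
    i_f = s_[9] * 0.0 * (Vm + 17.0)      # placeholder current, zero conductance
    i_pK = s_[10] * 0.0146 * (Vm - E_K) / (1.0 + np.exp((25.0 - Vm) / 5.98))
    i_b_Na = s_[11] * 0.00029 * (Vm - E_Na)
    i_b_Ca = s_[12] * 0.000592 * (Vm - E_Ca)

    # ---- SR calcium handling (mM/ms) ------------------------------------
    kCaSR = 2.5 - 1.5 / (1.0 + (1.5 / Casr) ** 2)
    k1 = 0.15 / kCaSR
    k2 = 0.045 * kCaSR
    O = k1 * Cass ** 2 * Rbar / (0.06 + k1 * Cass ** 2)
    j_rel = s_[15] * 0.102 * O * (Casr - Cass)
    j_leak = s_[13] * 0.00036 * (Casr - Cai)
    j_up = s_[14] * 0.006375 / (1.0 + (0.00025 / Cai) ** 2)
    j_xfer = 0.0038 * (Cass - Cai)

    Cai_buf = 1.0 / (1.0 + 0.2 * 0.001 / (Cai + 0.001) ** 2)
    Casr_buf = 1.0 / (1.0 + 10.0 * 0.3 / (Casr + 0.3) ** 2)
    Cass_buf = 1.0 / (1.0 + 0.4 * 0.00025 / (Cass + 0.00025) ** 2)

    memb = geom * Cm / (Vc * F)

    dy = np.empty(19)
    dy[0] = -(i_K1 + i_to + i_Kr + i_Ks + i_CaL + i_NaK + i_Na + i_NaCa
              + i_pCa + i_pK + i_b_Na + i_b_Ca + i_f) + istim
    dy[1] = (Xr1_inf - Xr1) / tau_xr1
    dy[2] = (Xr2_inf - Xr2) / tau_xr2
    dy[3] = (Xs_inf - Xs) / tau_xs
    dy[4] = (m_inf - m) / tau_m
    dy[5] = (h_inf - h) / tau_h
    dy[6] = (j_inf - j) / tau_j
    dy[7] = (d_inf - d) / tau_d
    dy[8] = (f_inf - f) / tau_f
    dy[9] = (f2_inf - f2) / tau_f2
    dy[10] = (fCass_inf - fCass) / tau_fCass
    dy[11] = (s_inf - sgate) / tau_s
    dy[12] = (r_inf - r) / tau_r
    dy[13] = Cai_buf * ((j_leak - j_up) * Vsr / Vc + j_xfer
                        - (i_b_Ca + i_pCa - 2.0 * i_NaCa) * memb / 2.0)
    dy[14] = Cass_buf * (-i_CaL * geom * Cm / (2.0 * Vss * F)
                         + j_rel * Vsr / Vss - j_xfer * Vc / Vss)
    dy[15] = Casr_buf * (j_up - j_rel - j_leak)
    dy[16] = -(i_Na + i_b_Na + 3.0 * i_NaK + 3.0 * i_NaCa) * memb
    dy[17] = -(i_K1 + i_to + i_Kr + i_Ks - 2.0 * i_NaK + i_pK - istim) * memb
    dy[18] = -k2 * Cass * Rbar + 0.005 * (1.0 - Rbar)

    cur = np.empty(16)
    cur[0] = i_Na
    cur[1] = i_CaL
    cur[2] = i_to
    cur[3] = i_Ks
    cur[4] = i_Kr
    cur[5] = i_K1
    cur[6] = i_NaCa
    cur[7] = i_NaK
    cur[8] = i_pCa
    cur[9] = i_f
    cur[10] = i_pK
    cur[11] = i_b_Na
    cur[12] = i_b_Ca
    cur[13] = j_leak
    cur[14] = j_up
    cur[15] = j_rel
    return dy, cur


@njit(cache=False)
def rhs(t, y, s_, geom, istim):
    dy, _ = _core(t, y, s_, geom, istim)
    return dy


@njit(cache=False)
def currents(t, y, s_, geom):
    _, cur = _core(t, y, s_, geom, 0.0)
    return cur
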