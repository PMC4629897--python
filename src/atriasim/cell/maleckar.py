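"""Human atrial myocyte ionic model (Maleckar/Nygren lineage).

The membrane model is the human atrial action-potential model of Maleckar and
co-workers: the Nygren et al. cell architecture (compartmental Na+/K+/Ca2+
handling with a restricted subsarcolemmal space, cleft space, SR uptake and
release compartments) with the Ca2+-independent transient outward current
(I_t) and the ultra-rapid delayed rectifier (I_Kur) refit to human atrial
voltage-clamp data, and an optional ACh-activated K+ current (zero at the
default ACh concentration).

Internal units follow the published formulation: time s, voltage mV,
current pA, conductance nS, concentration mM, volume nL, capacitance pF.
The public API speaks ms.

The complete constant set lives in ``maleckar_constants.json`` next to this
module, which is the versioned reference parameter file; the dictionaries
below are loaded from it at import time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from numba import njit

_CONST_PATH = Path(__file__).with_name("maleckar_constants.json")

with open(_CONST_PATH) as _fh:
    _RAW = json.load(_fh)

#: Baseline model constants (name -> value). See maleckar_constants.json.
CONSTANTS: dict[str, float] = dict(_RAW["constants"])

#: Resting-ish initial state used to seed pacing runs (name -> value).
INITIAL_STATE: dict[str, float] = dict(_RAW["initial_state"])

#: Ordered state-variable names; index into the state vector.
STATE_NAMES: tuple[str, ...] = tuple(INITIAL_STATE.keys())

N_STATES = len(STATE_NAMES)

# Indices used by analysis code.
IDX_V = STATE_NAMES.index("V")
IDX_NA_I = STATE_NAMES.index("Na_i")
IDX_K_I = STATE_NAMES.index("K_i")
IDX_CA_I = STATE_NAMES.index("Ca_i")

_GATES = (
    "m", "h1", "h2", "d_L", "f_L1", "f_L2",
    "r", "s", "a_ur", "i_ur", "n", "pa",
)
GATE_INDICES = tuple(STATE_NAMES.index(g) for g in _GATES)


def initial_state_vector() -> np.ndarray:
    """Return the default initial state as a float64 vector."""
    return np.array([INITIAL_STATE[k] for k in STATE_NAMES], dtype=np.float64)


# Constants are frozen into the jitted kernel as module-level floats: numba
# treats them as compile-time literals, which keeps the per-step cost low.
_c = CONSTANTS
R_GAS = _c["R"]
TEMP = _c["T"]
FARADAY = _c["F"]
CM = _c["Cm"]
VOL_I = _c["Vol_i"]
VOL_D = _c["Vol_d"]
VOL_C = _c["Vol_c"]
VOL_REL = _c["Vol_rel"]
VOL_UP = _c["Vol_up"]
P_NA = _c["P_Na"]
G_CAL = _c["g_CaL"]
E_CA_APP = _c["E_Ca_app"]
K_CA = _c["k_Ca"]
G_T = _c["g_t"]
G_KUR = _c["g_kur"]
G_KS = _c["g_Ks"]
G_KR = _c["g_Kr"]
G_K1 = _c["g_K1"]
G_B_NA = _c["g_B_Na"]
G_B_CA = _c["g_B_Ca"]
I_NAK_MAX = _c["i_NaK_max"]
K_NAK_K = _c["k_NaK_K"]
K_NAK_NA = _c["k_NaK_Na"]
I_CAP_MAX = _c["i_CaP_max"]
K_CAP = _c["k_CaP"]
K_NACA = _c["k_NaCa"]
GAMMA_NA = _c["gamma_Na"]
D_NACA = _c["d_NaCa"]
PHI_NA_EN = _c["phi_Na_en"]
ACH = _c["ACh"]
TAU_NA = _c["tau_Na"]
TAU_K = _c["tau_K"]
TAU_CA = _c["tau_Ca"]
NA_B = _c["Na_b"]
K_B = _c["K_b"]
CA_B = _c["Ca_b"]
TAU_DI = _c["tau_di"]
I_UP_MAX = _c["I_up_max"]
K_CYCA = _c["k_cyca"]
K_SRCA = _c["k_srca"]
K_XCS = _c["k_xcs"]
TAU_TR = _c["tau_tr"]
ALPHA_REL = _c["alpha_rel"]
K_REL_I = _c["k_rel_i"]
K_REL_D = _c["k_rel_d"]
R_RECOV = _c["r_recov"]
MG_I = _c["Mg_i"]

RTF = R_GAS * TEMP / FARADAY


@njit(cache=False, fastmath=False)
def _step(y, dt, sc_gto, sc_gcal, sc_gkr, i_stim_per_cap):
    """Advance one state vector by one time step (forward Euler + Rush-Larsen).

    Parameters: y (float64[29], modified in place), dt in seconds, the three
    regional conductance multipliers, and the stimulus in pA/pF (positive =
    depolarizing).
    """
    V = y[0]
    m = y[1]
    h1 = y[2]
    h2 = y[3]
    d_L = y[4]
    f_L1 = y[5]
    f_L2 = y[6]
    r = y[7]
    s = y[8]
    a_ur = y[9]
    i_ur = y[10]
    n = y[11]
    pa = y[12]
    Na_c = y[13]
    K_c = y[14]
    Ca_c = y[15]
    Na_i = y[16]
    K_i = y[17]
    Ca_i = y[18]
    Ca_d = y[19]
    Ca_up = y[20]
    Ca_rel = y[21]
    O_C = y[22]
    O_TC = y[23]
    O_TMgC = y[24]
    O_TMgMg = y[25]
    O_Calse = y[26]
    F1 = y[27]
    F2 = y[28]

    E_Na = RTF * np.log(Na_c / Na_i)
    E_K = RTF * np.log(K_c / K_i)
    E_Ca = 0.5 * RTF * np.log(Ca_c / Ca_i)

    # --- I_Na (GHK-type driving term) ---
    Vu = V
    if -1e-6 < Vu < 1e-6:
        Vu = 1e-6  # avoid 0/0 in the GHK factor
    expVF = np.exp(Vu / RTF)
    i_Na = (
        P_NA * m * m * m * (0.9 * h1 + 0.1 * h2) * Na_c * Vu
        * (FARADAY / RTF)
        * (np.exp((Vu - E_Na) / RTF) - 1.0) / (expVF - 1.0)
    )

    # --- I_CaL ---
    f_Ca = Ca_d / (Ca_d + K_CA)
    i_CaL = sc_gcal * G_CAL * d_L * (f_Ca * f_L1 + (1.0 - f_Ca) * f_L2) * (V - E_CA_APP)

    # --- K+ currents ---
    i_t = sc_gto * G_T * r * s * (V - E_K)
    i_Kur = G_KUR * a_ur * i_ur * (V - E_K)
    i_Ks = G_KS * n * (V - E_K)
    pip = 1.0 / (1.0 + np.exp((V + 55.0) / 24.0))
    i_Kr = sc_gkr * G_KR * pa * pip * (V - E_K)
    i_K1 = (
        G_K1 * (K_c ** 0.4457) * (V - E_K)
        / (1.0 + np.exp(1.5 * (V - E_K + 3.6) / RTF))
    )
    # ACh-gated K+ current; negligible at the default ACh ~ 0.
    i_KACh = (
        10.0 / (1.0 + 9.13652 / (ACH ** 0.477811))
        * (0.0517 + 0.4516 / (1.0 + np.exp((V + 59.53) / 17.18)))
        * (V - E_K) * CM
    )

    # --- background, pumps, exchanger ---
    i_B_Na = G_B_NA * (V - E_Na)
    i_B_Ca = G_B_CA * (V - E_Ca)
    pow_Na = Na_i ** 1.5
    i_NaK = (
        I_NAK_MAX * (K_c / (K_c + K_NAK_K))
        * (pow_Na / (pow_Na + K_NAK_NA ** 1.5))
        * (V + 150.0) / (V + 200.0)
    )
    i_CaP = I_CAP_MAX * Ca_i / (Ca_i + K_CAP)
    Na_c3 = Na_c * Na_c * Na_c
    Na_i3 = Na_i * Na_i * Na_i
    i_NaCa = (
        K_NACA
        * (Na_i3 * Ca_c * np.exp(GAMMA_NA * V / RTF)
           - Na_c3 * Ca_i * np.exp((GAMMA_NA - 1.0) * V / RTF))
        / (1.0 + D_NACA * (Na_c3 * Ca_i + Na_i3 * Ca_c))
    )

    # --- SR fluxes ---
    i_up = (
        I_UP_MAX * (Ca_i / K_CYCA - K_XCS * K_XCS * Ca_up / K_SRCA)
        / ((Ca_i + K_CYCA) / K_CYCA + K_XCS * (Ca_up + K_SRCA) / K_SRCA)
    )
    i_tr = (Ca_up - Ca_rel) * 2.0 * FARADAY * VOL_REL / TAU_TR
    f2frac = F2 / (F2 + 0.25)
    i_rel = ALPHA_REL * f2frac * f2frac * (Ca_rel - Ca_i)
    i_di = (Ca_d - Ca_i) * 2.0 * FARADAY * VOL_D / TAU_DI

    i_stim = -i_stim_per_cap * CM  # outward-positive convention

    i_ion = (
        i_Na + i_CaL + i_t + i_Kur + i_K1 + i_Kr + i_Ks
        + i_B_Na + i_B_Ca + i_NaK + i_CaP + i_NaCa + i_KACh
    )

    # --- gate kinetics (Rush-Larsen) ---
    m_inf = 1.0 / (1.0 + np.exp(-(V + 27.12) / 8.21))
    e = (V + 25.57) / 28.8
    tau_m = 4.2e-5 * np.exp(-e * e) + 2.4e-5
    h_inf = 1.0 / (1.0 + np.exp((V + 63.6) / 5.3))
    hden = 1.0 + np.exp((V + 35.1) / 3.2)
    tau_h1 = 0.03 / hden + 3.0e-4
    tau_h2 = 0.12 / hden + 3.0e-3

    d_inf = 1.0 / (1.0 + np.exp(-(V + 9.0) / 5.8))
    e = (V + 35.0) / 30.0
    tau_d = 2.7e-3 * np.exp(-e * e) + 2.0e-3
    f_inf = 1.0 / (1.0 + np.exp((V + 27.4) / 7.1))
    e = (V + 40.0) / 14.4
    tau_f1 = 0.161 * np.exp(-e * e) + 0.01
    e = (V + 40.0) / 14.2
    tau_f2 = 1.3323 * np.exp(-e * e) + 0.0626

    r_inf = 1.0 / (1.0 + np.exp(-(V - 1.0) / 11.0))
    e = V / 30.0
    tau_r = 3.5e-3 * np.exp(-e * e) + 1.5e-3
    s_inf = 1.0 / (1.0 + np.exp((V + 40.5) / 11.5))
    e = (V + 52.45) / 15.8827
    tau_s = 0.025635 * np.exp(-e * e) + 0.01414

    a_ur_inf = 1.0 / (1.0 + np.exp(-(V + 6.0) / 8.6))
    i_ur_inf = 1.0 / (1.0 + np.exp((V + 7.5) / 10.0))
    tau_a_ur = 9.0e-3 / (1.0 + np.exp((V + 5.0) / 12.0)) + 5.0e-4
    tau_i_ur = 0.59 / (1.0 + np.exp((V + 60.0) / 10.0)) + 3.05

    n_inf = 1.0 / (1.0 + np.exp(-(V - 19.9) / 12.7))
    e = (V - 20.0) / 20.0
    tau_n = 0.7 + 0.4 * np.exp(-e * e)
    pa_inf = 1.0 / (1.0 + np.exp(-(V + 15.0) / 6.0))
    e = (V + 20.1376) / 22.1996
    tau_pa = 0.03118 + 0.21718 * np.exp(-e * e)

    y[1] = m_inf + (m - m_inf) * np.exp(-dt / tau_m)
    y[2] = h_inf + (h1 - h_inf) * np.exp(-dt / tau_h1)
    y[3] = h_inf + (h2 - h_inf) * np.exp(-dt / tau_h2)
    y[4] = d_inf + (d_L - d_inf) * np.exp(-dt / tau_d)
    y[5] = f_inf + (f_L1 - f_inf) * np.exp(-dt / tau_f1)
    y[6] = f_inf + (f_L2 - f_inf) * np.exp(-dt / tau_f2)
    y[7] = r_inf + (r - r_inf) * np.exp(-dt / tau_r)
    y[8] = s_inf + (s - s_inf) * np.exp(-dt / tau_s)
    y[9] = a_ur_inf + (a_ur - a_ur_inf) * np.exp(-dt / tau_a_ur)
    y[10] = i_ur_inf + (i_ur - i_ur_inf) * np.exp(-dt / tau_i_ur)
    y[11] = n_inf + (n - n_inf) * np.exp(-dt / tau_n)
    y[12] = pa_inf + (pa - pa_inf) * np.exp(-dt / tau_pa)

    # --- buffers ---
    dO_C = 2.0e5 * Ca_i * (1.0 - O_C) - 476.0 * O_C
    dO_TC = 7.84e4 * Ca_i * (1.0 - O_TC) - 392.0 * O_TC
    dO_TMgC = 2.0e5 * Ca_i * (1.0 - O_TMgC - O_TMgMg) - 6.6 * O_TMgC
    dO_TMgMg = 2.0e3 * MG_I * (1.0 - O_TMgC - O_TMgMg) - 666.0 * O_TMgMg
    dO_Calse = 480.0 * Ca_rel * (1.0 - O_Calse) - 400.0 * O_Calse

    # --- concentrations ---
    inv_VcF = 1.0 / (VOL_C * FARADAY)
    na_flux = i_Na + i_B_Na + 3.0 * i_NaK + 3.0 * i_NaCa + PHI_NA_EN
    k_flux = i_t + i_Kur + i_K1 + i_Ks + i_Kr + i_KACh - 2.0 * i_NaK
    ca_flux = i_CaL + i_B_Ca + i_CaP - 2.0 * i_NaCa

    dNa_c = (NA_B - Na_c) / TAU_NA + na_flux * inv_VcF
    dK_c = (K_B - K_c) / TAU_K + k_flux * inv_VcF
    dCa_c = (CA_B - Ca_c) / TAU_CA + ca_flux / (2.0 * VOL_C * FARADAY)

    dNa_i = -na_flux / (VOL_I * FARADAY)
    dK_i = -(k_flux + i_stim) / (VOL_I * FARADAY)
    dCa_i = (
        -(-i_di + i_B_Ca + i_CaP - 2.0 * i_NaCa + i_up - i_rel)
        / (2.0 * VOL_I * FARADAY)
        - (0.045 * dO_C + 0.08 * dO_TC + 0.16 * dO_TMgC)
    )
    dCa_d = -(i_CaL + i_di) / (2.0 * VOL_D * FARADAY)
    dCa_up = (i_up - i_tr) / (2.0 * VOL_UP * FARADAY)
    dCa_rel = (i_tr - i_rel) / (2.0 * VOL_REL * FARADAY) - 31.0 * dO_Calse

    # --- SR release gating ---
    ract_i = Ca_i / (Ca_i + K_REL_I)
    ract_d = Ca_d / (Ca_d + K_REL_D)
    ract_i4 = ract_i ** 4
    r_act = 203.8 * (ract_i4 + ract_d ** 4)
    r_inact = 33.96 + 339.6 * ract_i4
    dF1 = R_RECOV * (1.0 - F1 - F2) - r_act * F1
    dF2 = r_act * F1 - r_inact * F2

    y[0] = V - dt * 1000.0 * (i_ion + i_stim) / CM
    y[13] = Na_c + dt * dNa_c
    y[14] = K_c + dt * dK_c
    y[15] = Ca_c + dt * dCa_c
    y[16] = Na_i + dt * dNa_i
    y[17] = K_i + dt * dK_i
    y[18] = Ca_i + dt * dCa_i
    y[19] = Ca_d + dt * dCa_d
    y[20] = Ca_up + dt * dCa_up
    y[21] = Ca_rel + dt * dCa_rel
    y[22] = O_C + dt * dO_C
    y[23] = O_TC + dt * dO_TC
    y[24] = O_TMgC + dt * dO_TMgC
    y[25] = O_TMgMg + dt * dO_TMgMg
    y[26] = O_Calse + dt * dO_Calse
    y[27] = F1 + dt * dF1
    y[28] = F2 + dt * dF2


@njit(cache=False)
def ionic_current_per_cap(y, sc_gto, sc_gcal, sc_gkr):
    """Total membrane ionic current in pA/pF (outward positive) of state y.

    Used by the tissue solver's reaction step diagnostics; duplicates the
    current algebra of _step without advancing the state.
    """
    V = y[0]
    Na_c = y[13]
    K_c = y[14]
    Ca_c = y[15]
    Na_i = y[16]
    K_i = y[17]
    Ca_i = y[18]
    Ca_d = y[19]

    E_Na = RTF * np.log(Na_c / Na_i)
    E_K = RTF * np.log(K_c / K_i)
    E_Ca = 0.5 * RTF * np.log(Ca_c / Ca_i)
    Vu = V
    if -1e-6 < Vu < 1e-6:
        Vu = 1e-6
    i_Na = (
        P_NA * y[1] ** 3 * (0.9 * y[2] + 0.1 * y[3]) * Na_c * Vu
        * (FARADAY / RTF)
        * (np.exp((Vu - E_Na) / RTF) - 1.0) / (np.exp(Vu / RTF) - 1.0)
    )
    f_Ca = Ca_d / (Ca_d + K_CA)
    i_CaL = sc_gcal * G_CAL * y[4] * (f_Ca * y[5] + (1.0 - f_Ca) * y[6]) * (V - E_CA_APP)
    i_t = sc_gto * G_T * y[7] * y[8] * (V - E_K)
    i_Kur = G_KUR * y[9] * y[10] * (V - E_K)
    i_Ks = G_KS * y[11] * (V - E_K)
    pip = 1.0 / (1.0 + np.exp((V + 55.0) / 24.0))
    i_Kr = sc_gkr * G_KR * y[12] * pip * (V - E_K)
    i_K1 = (
        G_K1 * (K_c ** 0.4457) * (V - E_K)
        / (1.0 + np.exp(1.5 * (V - E_K + 3.6) / RTF))
    )
    i_B_Na = G_B_NA * (V - E_Na)
    i_B_Ca = G_B_CA * (V - E_Ca)
    pow_Na = Na_i ** 1.5
    i_NaK = (
        I_NAK_MAX * (K_c / (K_c + K_NAK_K))
        * (pow_Na / (pow_Na + K_NAK_NA ** 1.5))
        * (V + 150.0) / (V + 200.0)
    )
    i_CaP = I_CAP_MAX * Ca_i / (Ca_i + K_CAP)
    Na_c3 = Na_c ** 3
    Na_i3 = Na_i ** 3
    i_NaCa = (
        K_NACA
        * (Na_i3 * Ca_c * np.exp(GAMMA_NA * V / RTF)
           - Na_c3 * Ca_i * np.exp((GAMMA_NA - 1.0) * V / RTF))
        / (1.0 + D_NACA * (Na_c3 * Ca_i + Na_i3 * Ca_c))
    )
    total = (
        i_Na + i_CaL + i_t + i_Kur + i_K1 + i_Kr + i_Ks
        + i_B_Na + i_B_Ca + i_NaK + i_CaP + i_NaCa
    )
    return total / CM
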