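"""Numba kernels: TP06 right-hand side, currents, and the time stepper.

The full model algebra lives in a single jitted routine (:func:`_eval`)
that fills, for one state vector, the state derivative, all sarcolemmal
currents and SR fluxes, and the (steady-state, time-constant) pairs of the
thirteen gating-type variables.  Everything else in the package  --  the
public ``rhs``/``compute_currents`` API, the Rush-Larsen stepper, reduced
(slow-fast) systems  --  is a thin view on this one routine, so there is
exactly one transcription of the model equations in the code base.

Integration uses the hybrid Rush-Larsen scheme that is standard for
cardiac ionic models: gating variables are advanced exactly on their
linear relaxation equations (y -> y_inf + (y - y_inf) exp(-dt/tau)), the
membrane potential and ion concentrations by forward Euler.  Frozen
states (clamped V_m, fixed K_i/Na_i, slow-fast frozen variables) are
marked in a mask and simply not advanced.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .constants import (
    ALPHA_NCX, BUF_C, BUF_SR, BUF_SS, CM, EC_SR, FARADAY, GAMMA_NCX,
    K1_REL, K2_REL, K3_REL, K4_REL, K_BUF_C, K_BUF_SR, K_BUF_SS, K_MCA,
    K_MK, K_MNA, K_MNAI, K_PCA, K_SAT, K_UP, MAX_SR, MIN_SR, P_KNA,
    RTONF, V_C, V_SR, V_SS,
)

__all__ = ["_eval", "rl_step", "run_interval", "rhs_into"]


@njit(cache=True, fastmath=True)
def _eval(y, p, stim, dy, cur, inf, tau):
    """Evaluate the TP06 M-cell model at one state.

    Fills ``dy`` (state derivative, per ms), ``cur`` (currents in pA/pF and
    SR fluxes in mM/ms) and, for the 13 gating-type states, ``inf``/``tau``
    (steady state and time constant in ms; tau[i] == 0 marks a non-gating
    state).  ``stim`` is the applied depolarizing current in pA/pF.
    """
    V = y[0]
    m = y[1]
    h = y[2]
    j = y[3]
    d = y[4]
    f = y[5]
    f2 = y[6]
    fCass = y[7]
    r = y[8]
    s = y[9]
    xr1 = y[10]
    xr2 = y[11]
    xs = y[12]
    Rbar = y[13]
    Cai = y[14]
    Cass = y[15]
    CaSR = y[16]
    Nai = y[17]
    Ki = y[18]

    gNa = p[0]
    gCaL = p[1]
    gKr = p[2]
    gKs = p[3]
    gto = p[4]
    gK1 = p[5]
    gpK = p[6]
    gbNa = p[7]
    gbCa = p[8]
    gpCa = p[9]
    PNaK = p[10]
    kNaCa = p[11]
    Pup = p[12]
    Vrel = p[13]
    Vleak = p[14]
    Vxfer = p[15]
    Ko = p[16]
    Nao = p[17]
    Cao = p[18]
    tauf_scale = p[19]
    tauf2_scale = p[20]

    # reversal potentials
    E_Na = RTONF * math.log(Nao / Nai)
    E_K = RTONF * math.log(Ko / Ki)
    E_Ks = RTONF * math.log((Ko + P_KNA * Nao) / (Ki + P_KNA * Nai))
    E_Ca = 0.5 * RTONF * math.log(Cao / Cai)

    # ---- I_Na gates -------------------------------------------------------
    m_inf = 1.0 / (1.0 + math.exp((-56.86 - V) / 9.03)) ** 2
    a_m = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    b_m = 0.1 / (1.0 + math.exp((V + 35.0) / 5.0)) \
        + 0.1 / (1.0 + math.exp((V - 50.0) / 200.0))
    tau_m = a_m * b_m

    h_inf = 1.0 / (1.0 + math.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        a_h = 0.0
        b_h = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
    else:
        a_h = 0.057 * math.exp(-(V + 80.0) / 6.8)
        b_h = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
    tau_h = 1.0 / (a_h + b_h)

    j_inf = h_inf
    if V >= -40.0:
        a_j = 0.0
        b_j = 0.6 * math.exp(0.057 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        a_j = ((-2.5428e4 * math.exp(0.2444 * V)
                - 6.948e-6 * math.exp(-0.04391 * V)) * (V + 37.78)
               / (1.0 + math.exp(0.311 * (V + 79.23))))
        b_j = (0.02424 * math.exp(-0.01052 * V)
               / (1.0 + math.exp(-0.1378 * (V + 40.14))))
    tau_j = 1.0 / (a_j + b_j)

    I_Na = gNa * m * m * m * h * j * (V - E_Na)

    # ---- I_CaL ------------------------------------------------------------
    d_inf = 1.0 / (1.0 + math.exp((-8.0 - V) / 7.5))
    a_d = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
    b_d = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    g_d = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
    tau_d = a_d * b_d + g_d

    f_inf = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
    tau_f = (1102.5 * math.exp(-((V + 27.0) ** 2) / 225.0)
             + 200.0 / (1.0 + math.exp((13.0 - V) / 10.0))
             + 180.0 / (1.0 + math.exp((V + 30.0) / 10.0))
             + 20.0) * tauf_scale

    f2_inf = 0.67 / (1.0 + math.exp((V + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * math.exp(-((V + 27.0) ** 2) / 240.0)
              + 31.0 / (1.0 + math.exp((25.0 - V) / 10.0))
              + 80.0 / (1.0 + math.exp((V + 30.0) / 10.0))) * tauf2_scale

    fCass_inf = 0.6 / (1.0 + (Cass / 0.05) ** 2) + 0.4
    tau_fCass = 80.0 / (1.0 + (Cass / 0.05) ** 2) + 2.0

    # GHK-type driving force; I_CaL = gCaL*gates*2F*z*(0.25*Cass*e^z - Cao)/(e^z - 1)
    z = 2.0 * (V - 15.0) / RTONF
    if abs(z) < 1e-6:
        # removable singularity at V = 15 mV: z/(e^z-1) ~ 1 - z/2
        drive = (0.25 * Cass - Cao) * (1.0 - 0.5 * z) + 0.25 * Cass * z
    else:
        ez = math.exp(z)
        drive = z * (0.25 * Cass * ez - Cao) / (ez - 1.0)
    I_CaL = gCaL * d * f * f2 * fCass * 2.0 * FARADAY * drive

    # ---- I_to (M cell uses the epicardial s-gate formulation) -------------
    r_inf = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * math.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
    s_inf = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
    tau_s = (85.0 * math.exp(-((V + 45.0) ** 2) / 320.0)
             + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0)) + 3.0)
    I_to = gto * r * s * (V - E_K)

    # ---- I_Kr -------------------------------------------------------------
    xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
    a_xr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    b_xr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
    tau_xr1 = a_xr1 * b_xr1
    xr2_inf = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
    a_xr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    b_xr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
    tau_xr2 = a_xr2 * b_xr2
    I_Kr = gKr * math.sqrt(Ko / 5.4) * xr1 * xr2 * (V - E_K)

    # ---- I_Ks -------------------------------------------------------------
    xs_inf = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
    a_xs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - V) / 6.0))
    b_xs = 1.0 / (1.0 + math.exp((V - 35.0) / 15.0))
    tau_xs = a_xs * b_xs + 80.0
    I_Ks = gKs * xs * xs * (V - E_Ks)

    # ---- I_K1 -------------------------------------------------------------
    a_K1 = 0.1 / (1.0 + math.exp(0.06 * (V - E_K - 200.0)))
    b_K1 = ((3.0 * math.exp(0.0002 * (V - E_K + 100.0))
             + math.exp(0.1 * (V - E_K - 10.0)))
            / (1.0 + math.exp(-0.5 * (V - E_K))))
    xK1_inf = a_K1 / (a_K1 + b_K1)
    I_K1 = gK1 * math.sqrt(Ko / 5.4) * xK1_inf * (V - E_K)

    # ---- pumps / exchangers / background ----------------------------------
    evf = math.exp(GAMMA_NCX * V / RTONF)
    evf1 = math.exp((GAMMA_NCX - 1.0) * V / RTONF)
    I_NCX = (kNaCa
             * (evf * Nai ** 3 * Cao - evf1 * Nao ** 3 * Cai * ALPHA_NCX)
             / ((K_MNAI ** 3 + Nao ** 3) * (K_MCA + Cao)
                * (1.0 + K_SAT * evf1)))

    I_NaK = (PNaK * Ko * Nai
             / ((Ko + K_MK) * (Nai + K_MNA))
             / (1.0 + 0.1245 * math.exp(-0.1 * V / RTONF)
                + 0.0353 * math.exp(-V / RTONF)))

    I_pCa = gpCa * Cai / (Cai + K_PCA)
    I_pK = gpK * (V - E_K) / (1.0 + math.exp((25.0 - V) / 5.98))
    I_bNa = gbNa * (V - E_Na)
    I_bCa = gbCa * (V - E_Ca)

    # ---- SR Ca2+ fluxes ---------------------------------------------------
    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / CaSR) ** 2)
    k1 = K1_REL / kcasr
    k2 = K2_REL * kcasr
    O_rel = k1 * Cass * Cass * Rbar / (K3_REL + k1 * Cass * Cass)
    J_rel = Vrel * O_rel * (CaSR - Cass)
    J_up = Pup / (1.0 + (K_UP / Cai) ** 2)
    J_leak = Vleak * (CaSR - Cai)
    J_xfer = Vxfer * (Cass - Cai)

    dRbar = -k2 * Cass * Rbar + K4_REL * (1.0 - Rbar)
    # linear-relaxation form for the Rush-Larsen update of Rbar
    Rbar_rate = k2 * Cass + K4_REL
    Rbar_inf = K4_REL / Rbar_rate

    # ---- material balances ------------------------------------------------
    bufc = 1.0 / (1.0 + BUF_C * K_BUF_C / ((Cai + K_BUF_C) ** 2))
    dCai = bufc * ((J_leak - J_up) * V_SR / V_C + J_xfer
                   - (I_bCa + I_pCa - 2.0 * I_NCX) * CM
                   / (2.0 * V_C * FARADAY))
    bufsr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / ((CaSR + K_BUF_SR) ** 2))
    dCaSR = bufsr * (J_up - J_rel - J_leak)
    bufss = 1.0 / (1.0 + BUF_SS * K_BUF_SS / ((Cass + K_BUF_SS) ** 2))
    dCass = bufss * (-I_CaL * CM / (2.0 * V_SS * FARADAY)
                     + J_rel * V_SR / V_SS - J_xfer * V_C / V_SS)

    dNai = -(I_Na + I_bNa + 3.0 * I_NaK + 3.0 * I_NCX) * CM / (V_C * FARADAY)
    dKi = -(I_K1 + I_to + I_Kr + I_Ks + I_pK - stim - 2.0 * I_NaK) \
        * CM / (V_C * FARADAY)

    I_sum = (I_Na + I_CaL + I_Kr + I_Ks + I_to + I_K1 + I_NCX + I_NaK
             + I_pCa + I_pK + I_bNa + I_bCa)
    dV = stim - I_sum

    dy[0] = dV
    dy[1] = (m_inf - m) / tau_m
    dy[2] = (h_inf - h) / tau_h
    dy[3] = (j_inf - j) / tau_j
    dy[4] = (d_inf - d) / tau_d
    dy[5] = (f_inf - f) / tau_f
    dy[6] = (f2_inf - f2) / tau_f2
    dy[7] = (fCass_inf - fCass) / tau_fCass
    dy[8] = (r_inf - r) / tau_r
    dy[9] = (s_inf - s) / tau_s
    dy[10] = (xr1_inf - xr1) / tau_xr1
    dy[11] = (xr2_inf - xr2) / tau_xr2
    dy[12] = (xs_inf - xs) / tau_xs
    dy[13] = dRbar
    dy[14] = dCai
    dy[15] = dCass
    dy[16] = dCaSR
    dy[17] = dNai
    dy[18] = dKi

    inf[1] = m_inf
    inf[2] = h_inf
    inf[3] = j_inf
    inf[4] = d_inf
    inf[5] = f_inf
    inf[6] = f2_inf
    inf[7] = fCass_inf
    inf[8] = r_inf
    inf[9] = s_inf
    inf[10] = xr1_inf
    inf[11] = xr2_inf
    inf[12] = xs_inf
    inf[13] = Rbar_inf
    tau[1] = tau_m
    tau[2] = tau_h
    tau[3] = tau_j
    tau[4] = tau_d
    tau[5] = tau_f
    tau[6] = tau_f2
    tau[7] = tau_fCass
    tau[8] = tau_r
    tau[9] = tau_s
    tau[10] = tau_xr1
    tau[11] = tau_xr2
    tau[12] = tau_xs
    tau[13] = 1.0 / Rbar_rate

    cur[0] = I_Na
    cur[1] = I_CaL
    cur[2] = I_Kr
    cur[3] = I_Ks
    cur[4] = I_to
    cur[5] = I_K1
    cur[6] = I_NCX
    cur[7] = I_NaK
    cur[8] = I_pCa
    cur[9] = I_pK
    cur[10] = I_bNa
    cur[11] = I_bCa
    cur[12] = J_up
    cur[13] = J_rel
    cur[14] = J_leak
    cur[15] = J_xfer


@njit(cache=True)
def rhs_into(y, p, mask, stim, dy, cur):
    """Full RHS with frozen-state entries zeroed (mask[i] != 0 => frozen)."""
    inf = np.empty(19)
    tau = np.zeros(19)
    _eval(y, p, stim, dy, cur, inf, tau)
    for i in range(19):
        if mask[i] != 0.0:
            dy[i] = 0.0


@njit(cache=True, fastmath=True)
def rl_step(y, p, mask, dt, stim, dy, cur, inf, tau):
    """One hybrid Rush-Larsen / forward-Euler step, in place."""
    _eval(y, p, stim, dy, cur, inf, tau)
    for i in range(19):
        if mask[i] != 0.0:
            continue
        if tau[i] > 0.0:
            y[i] = inf[i] + (y[i] - inf[i]) * math.exp(-dt / tau[i])
        else:
            y[i] = y[i] + dt * dy[i]


@njit(cache=True, fastmath=True)
def run_interval(y, p, mask, dt, duration, stim, out_stride, y_out):
    """Integrate ``duration`` ms at constant applied current ``stim``.

    ``y`` is advanced in place.  Every ``out_stride``-th step the full state
    is written to ``y_out`` (shape (n_out, 19)); y_out[0] is the state at
    entry.  Returns the number of samples written.
    """
    n_steps = int(round(duration / dt))
    dy = np.empty(19)
    cur = np.empty(16)
    inf = np.empty(19)
    tau = np.zeros(19)
    k = 0
    for i in range(19):
        y_out[0, i] = y[i]
    k = 1
    for step in range(1, n_steps + 1):
        rl_step(y, p, mask, dt, stim, dy, cur, inf, tau)
        if step % out_stride == 0:
            for i in range(19):
                y_out[k, i] = y[i]
            k += 1
    return k


@njit(cache=True, fastmath=True)
def run_no_output(y, p, mask, dt, duration, stim):
    """Integrate without recording (fast path for pre-pacing)."""
    n_steps = int(round(duration / dt))
    dy = np.empty(19)
    cur = np.empty(16)
    inf = np.empty(19)
    tau = np.zeros(19)
    for _ in range(n_steps):
        rl_step(y, p, mask, dt, stim, dy, cur, inf, tau)
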