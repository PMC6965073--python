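"""Baseline constants of the ten Tusscher-Panfilov 2006 (TP06) M-cell model.

All values follow the original TP06 publication and its public CellML
encoding.  Units: time ms, voltage mV, concentration mM, current pA/pF.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# state vector layout (19 variables)
# ---------------------------------------------------------------------------
STATE_NAMES = (
    "V",       # 0  membrane potential (mV)
    "m",       # 1  I_Na activation
    "h",       # 2  I_Na fast inactivation
    "j",       # 3  I_Na slow inactivation
    "d",       # 4  I_CaL activation
    "f",       # 5  I_CaL voltage-dependent inactivation (fast)
    "f2",      # 6  I_CaL voltage-dependent inactivation (slow)
    "fCass",   # 7  I_CaL Ca2+-dependent inactivation
    "r",       # 8  I_to activation
    "s",       # 9  I_to inactivation
    "xr1",     # 10 I_Kr activation
    "xr2",     # 11 I_Kr inactivation
    "xs",      # 12 I_Ks activation
    "Rbar",    # 13 fraction of closed SR release channels
    "Cai",     # 14 myoplasmic Ca2+ (mM)
    "Cass",    # 15 subspace Ca2+ (mM)
    "CaSR",    # 16 SR Ca2+ (mM)
    "Nai",     # 17 myoplasmic Na+ (mM)
    "Ki",      # 18 myoplasmic K+ (mM)
)
N_STATE = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}

# indices of gating variables integrated with the Rush-Larsen scheme
GATE_INDICES = tuple(range(1, 14))

CURRENT_NAMES = (
    "I_Na", "I_CaL", "I_Kr", "I_Ks", "I_to", "I_K1",
    "I_NCX", "I_NaK", "I_pCa", "I_pK", "I_bNa", "I_bCa",
    "J_up", "J_rel", "J_leak", "J_xfer",
)
CURRENT_IDX = {name: i for i, name in enumerate(CURRENT_NAMES)}
N_CURRENT = len(CURRENT_NAMES)

# ---------------------------------------------------------------------------
# physical constants
# ---------------------------------------------------------------------------
R_GAS = 8314.472        # J/(kmol K)
TEMP = 310.0            # K
FARADAY = 96485.3415    # C/mol
RTONF = R_GAS * TEMP / FARADAY  # mV

CM = 0.185              # membrane capacitance (uF)
V_C = 0.016404          # cytoplasmic volume (um^3, model units)
V_SR = 0.001094         # SR volume
V_SS = 0.00005468       # subspace volume

# ---------------------------------------------------------------------------
# maximal conductances / transport rates (M cell)
# ---------------------------------------------------------------------------
G_NA = 14.838           # nS/pF
G_CAL = 3.98e-5         # cm^3 uF^-1 ms^-1
G_KR = 0.153            # nS/pF
G_KS_M = 0.098          # nS/pF (M cell; epi/endo use 0.392/0.392)
G_TO_M = 0.294          # nS/pF (M cell, epicardial formulation of s gate)
G_K1 = 5.405            # nS/pF
G_PK = 0.0146
G_BNA = 0.00029
G_BCA = 0.000592
G_PCA = 0.1238
K_PCA = 0.0005

P_NAK = 2.724
K_MK = 1.0
K_MNA = 40.0

K_NACA = 1000.0
GAMMA_NCX = 0.35
K_MCA = 1.38
K_MNAI = 87.5
K_SAT = 0.1
ALPHA_NCX = 2.5

P_KNA = 0.03

# SR Ca2+ handling
VMAX_UP = 0.006375      # mM/ms (P_up)
K_UP = 0.00025
V_REL = 0.102           # mM/ms
K1_REL = 0.15
K2_REL = 0.045
K3_REL = 0.060
K4_REL = 0.005
EC_SR = 1.5
MAX_SR = 2.5
MIN_SR = 1.0
V_LEAK = 0.00036
V_XFER = 0.0038

# Ca2+ buffering
BUF_C = 0.2
K_BUF_C = 0.001
BUF_SR = 10.0
K_BUF_SR = 0.3
BUF_SS = 0.4
K_BUF_SS = 0.00025

# external ion concentrations (mM)
K_O = 5.4
NA_O = 140.0
CA_O = 2.0

# ---------------------------------------------------------------------------
# default initial state (1-Hz paced steady state of the original model,
# from the public CellML encoding)
# ---------------------------------------------------------------------------
DEFAULT_INITIAL_STATE = np.array([
    -85.23,     # V
    0.00172,    # m
    0.7444,     # h
    0.7045,     # j
    3.373e-5,   # d
    0.7888,     # f
    0.9755,     # f2
    0.9953,     # fCass
    2.42e-8,    # r
    0.999998,   # s
    0.00621,    # xr1
    0.4712,     # xr2
    0.0095,     # xs
    0.9073,     # Rbar
    0.000126,   # Cai
    0.00036,    # Cass
    3.64,       # CaSR
    8.604,      # Nai
    136.89,     # Ki
])

# ---------------------------------------------------------------------------
# kernel parameter-vector layout (effective values, scalings applied)
# ---------------------------------------------------------------------------
P_NAMES = (
    "gNa", "gCaL", "gKr", "gKs", "gto", "gK1", "gpK", "gbNa", "gbCa",
    "gpCa", "PNaK", "kNaCa", "Pup", "Vrel", "Vleak", "Vxfer",
    "Ko", "Nao", "Cao", "tauf_scale", "tauf2_scale",
)
P_IDX = {name: i for i, name in enumerate(P_NAMES)}
N_P = len(P_NAMES)

BASELINE_P = np.array([
    G_NA, G_CAL, G_KR, G_KS_M, G_TO_M, G_K1, G_PK, G_BNA, G_BCA,
    G_PCA, P_NAK, K_NACA, VMAX_UP, V_REL, V_LEAK, V_XFER,
    K_O, NA_O, CA_O, 1.0, 1.0,
])
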