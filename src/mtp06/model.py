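"""Public model surface: right-hand side, currents, steady-state initials."""

from __future__ import annotations

import numpy as np

from . import _kernel
from .constants import (
    CURRENT_IDX, CURRENT_NAMES, DEFAULT_INITIAL_STATE, IDX, N_CURRENT,
    N_STATE, STATE_NAMES,
)
from .params import ParameterSet


class NumericsError(RuntimeError):
    """Non-finite state handed to the model equations."""


def _check_state(state: np.ndarray) -> np.ndarray:
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATE,):
        raise ValueError(f"state must have length {N_STATE}, got {y.shape}")
    if not np.all(np.isfinite(y)):
        bad = STATE_NAMES[int(np.flatnonzero(~np.isfinite(y))[0])]
        raise NumericsError(f"non-finite state variable {bad!r}")
    return y


def rhs(t: float, state: np.ndarray, params: ParameterSet,
        stim: float = 0.0) -> np.ndarray:
    """Time derivative of the 19-variable state (per ms).

    ``stim`` is the applied depolarizing current in pA/pF (enters dV/dt
    with positive sign).  Entries for clamped/fixed variables are 0.
    The system is autonomous; ``t`` is accepted for solver interfaces.
    """
    y = _check_state(state)
    dy = np.empty(N_STATE)
    cur = np.empty(N_CURRENT)
    _kernel.rhs_into(y, params.kernel_p(), params.kernel_mask(),
                     float(stim), dy, cur)
    return dy


def compute_currents(state: np.ndarray, params: ParameterSet) -> dict:
    """All sarcolemmal currents (pA/pF) and SR fluxes (mM/ms) at a state."""
    y = _check_state(state)
    dy = np.empty(N_STATE)
    cur = np.empty(N_CURRENT)
    _kernel.rhs_into(y, params.kernel_p(), np.zeros(N_STATE), 0.0, dy, cur)
    return {name: cur[CURRENT_IDX[name]] for name in CURRENT_NAMES}


def gate_steady_state(V: float, params: ParameterSet,
                      Cass: float = 0.00036) -> np.ndarray:
    """Voltage-dependent steady-state values of the 13 gating variables."""
    y = DEFAULT_INITIAL_STATE.copy()
    y[IDX["V"]] = V
    y[IDX["Cass"]] = Cass
    dy = np.empty(N_STATE)
    cur = np.empty(N_CURRENT)
    inf = np.empty(N_STATE)
    tau = np.zeros(N_STATE)
    _kernel._eval(y, params.kernel_p(), 0.0, dy, cur, inf, tau)
    return inf[1:14].copy()


def steady_state_initials(V_rest: float, params: ParameterSet,
                          concentrations: dict | None = None) -> np.ndarray:
    """Initial state with gates at their steady-state values at ``V_rest``.

    Concentrations default to the model's standard resting values and can
    be overridden per variable (e.g. ``{"Nai": 6.0}``).  Clamped/fixed
    variables are set to their configured values.
    """
    if not -100.0 <= V_rest <= -60.0:
        raise ValueError("V_rest outside physiological range (-100..-60 mV)")
    y = DEFAULT_INITIAL_STATE.copy()
    y[IDX["V"]] = V_rest
    y[1:14] = gate_steady_state(V_rest, params, Cass=y[IDX["Cass"]])
    if concentrations:
        for name, value in concentrations.items():
            y[IDX[name]] = value
    return params.apply_clamps(y)
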