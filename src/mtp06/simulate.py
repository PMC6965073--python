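"""Time integration: traces, constant-current runs, and paced AP simulation.

The workhorse integrator is the jitted hybrid Rush-Larsen stepper
(:mod:`._kernel`) at a fixed 0.02-ms step, the standard resolution for
this model family; an LSODA path (rtol 1e-8) is available for
cross-checks and for relaxation/shooting computations that need error
control.  Paced runs proceed beat by beat and stop either after a fixed
number of beats or when the beat-to-beat relative changes of V_min,
V_max and APD90 all fall below 1e-3 (with a hard wall-time cap in
simulated minutes).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _kernel
from ._apmetrics import APFeatures, beat_features, relative_change
from .constants import IDX, N_CURRENT, N_STATE, STATE_NAMES
from .model import steady_state_initials
from .params import ParameterSet
from .protocols import PacingProtocol

DT_DEFAULT = 0.02       # ms, fixed integration step
OUT_STEP_DEFAULT = 0.5  # ms, output sampling step
CONVERGENCE_TOL = 1e-3
MAX_PACED_MS = 1.8e6    # 30 simulated minutes


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last valid state."""

    def __init__(self, msg, last_state=None):
        super().__init__(msg)
        self.last_state = last_state


@dataclass
class Trace:
    """Sampled trajectory with provenance.

    ``y`` has one row per sample and one column per state variable.
    For paced runs only the last ``keep_beats`` beats carry samples;
    ``features`` covers every beat from the start of the run.
    """

    t: np.ndarray
    y: np.ndarray
    params: ParameterSet
    protocol: object | None = None
    stim_times: np.ndarray | None = None
    features: list = field(default_factory=list)
    converged: bool | None = None
    n_beats: int = 0
    first_kept_beat: int = 0

    def __getitem__(self, name: str) -> np.ndarray:
        return self.y[:, IDX[name]]

    @property
    def V(self) -> np.ndarray:
        return self.y[:, 0]

    def to_frame(self, columns=("V", "Cai", "Cass", "CaSR", "Nai", "Ki")):
        data = {"t": self.t}
        for c in columns:
            data[c] = self[c]
        return pd.DataFrame(data)

    def to_csv(self, path, columns=("V", "Cai", "Cass", "CaSR", "Nai", "Ki")):
        self.to_frame(columns).to_csv(path, index=False)

    def features_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.features:
            rows.append({
                "beat": f.beat, "t_stim": f.t_stim, "V_min": f.V_min,
                "V_max": f.V_max, "V_peak": f.V_peak, "APD90": f.APD90,
                "n_eads": f.n_eads,
            })
        return pd.DataFrame(rows)


def _check_finite(y, context):
    if not np.all(np.isfinite(y)):
        raise IntegrationError(f"non-finite state during {context}",
                               last_state=np.array(y))


def integrate(params: ParameterSet, y0: np.ndarray, duration: float,
              stim: float = 0.0, dt: float = DT_DEFAULT,
              out_step: float = OUT_STEP_DEFAULT, t0: float = 0.0) -> Trace:
    """Integrate at constant applied current and return a sampled Trace."""
    y = params.apply_clamps(y0)
    p = params.kernel_p()
    mask = params.kernel_mask()
    stride = max(1, int(round(out_step / dt)))
    n_steps = int(round(duration / dt))
    n_out = n_steps // stride + 1
    buf = np.empty((n_out, N_STATE))
    k = _kernel.run_interval(y, p, mask, dt, duration, stim, stride, buf)
    _check_finite(y, "constant-current run")
    t = t0 + dt * stride * np.arange(k)
    return Trace(t=t, y=buf[:k].copy(), params=params)


def integrate_lsoda(params: ParameterSet, y0: np.ndarray, duration: float,
                    stim: float = 0.0, rtol: float = 1e-8,
                    t_eval: np.ndarray | None = None) -> Trace:
    """Adaptive-step reference integration (LSODA, relative tol 1e-8)."""
    y = params.apply_clamps(y0)
    p = params.kernel_p()
    mask = params.kernel_mask()
    dy = np.empty(N_STATE)
    cur = np.empty(N_CURRENT)

    def f(t, yy):
        _kernel.rhs_into(yy, p, mask, stim, dy, cur)
        return dy.copy()

    atol = np.full(N_STATE, 1e-10)
    atol[IDX["V"]] = 1e-8
    atol[IDX["Nai"]] = 1e-8
    atol[IDX["Ki"]] = 1e-8
    sol = solve_ivp(f, (0.0, duration), y, method="LSODA", rtol=rtol,
                    atol=atol, t_eval=t_eval, dense_output=False)
    if not sol.success:
        raise IntegrationError(f"LSODA failed: {sol.message}",
                               last_state=sol.y[:, -1] if sol.y.size else y)
    return Trace(t=sol.t, y=sol.y.T.copy(), params=params)


def default_initial_state(params: ParameterSet) -> np.ndarray:
    """Steady-state-at-rest initial values (gates relaxed at -85.4 mV)."""
    return steady_state_initials(-85.4, params)


def simulate_paced(params: ParameterSet, protocol: PacingProtocol,
                   init: np.ndarray | None = None,
                   max_duration: float = MAX_PACED_MS,
                   convergence_tol: float = CONVERGENCE_TOL,
                   dt: float = DT_DEFAULT, out_step: float = OUT_STEP_DEFAULT,
                   keep_beats: int = 12, min_beats: int = 2) -> Trace:
    """Pace the model and collect per-beat AP features.

    Stops after ``protocol.n_beats`` beats when given; otherwise runs to
    the beat-to-beat convergence criterion (relative changes of V_min,
    V_max and APD90 all below ``convergence_tol``) or until
    ``max_duration`` ms of simulated time, whichever comes first.  The
    returned Trace carries samples for the last ``keep_beats`` beats and
    features for every beat; ``converged`` reports the criterion state.
    """
    CL = protocol.CL
    width = protocol.width
    amp = protocol.amplitude
    y = params.apply_clamps(init if init is not None
                            else default_initial_state(params))
    p = params.kernel_p()
    mask = params.kernel_mask()
    stride = max(1, int(round(out_step / dt)))

    if protocol.n_beats is not None:
        n_max = protocol.n_beats
    else:
        n_max = max(min_beats, int(max_duration // CL))

    n1 = int(round(width / dt))
    n2 = int(round((CL - width) / dt))
    buf1 = np.empty((n1 // stride + 1, N_STATE))
    buf2 = np.empty((n2 // stride + 1, N_STATE))

    kept: deque = deque(maxlen=keep_beats)
    features: list[APFeatures] = []
    prev_V_min = float(y[0])
    prev_feat: APFeatures | None = None
    converged = False
    n_done = 0

    for b in range(n_max):
        t0 = b * CL
        k1 = _kernel.run_interval(y, p, mask, dt, width, amp, stride, buf1)
        k2 = _kernel.run_interval(y, p, mask, dt, CL - width, 0.0, stride, buf2)
        _check_finite(y, f"paced beat {b}")
        t1 = t0 + dt * stride * np.arange(k1)
        t2 = t0 + width + dt * stride * np.arange(k2)
        tb = np.concatenate([t1, t2[1:]])
        yb = np.vstack([buf1[:k1], buf2[1:k2]])
        feat = beat_features(tb, yb[:, 0], t0, prev_V_min, beat=b)
        features.append(feat)
        kept.append((tb, yb.copy()))
        n_done = b + 1
        if protocol.n_beats is None and prev_feat is not None and b + 1 >= min_beats:
            ok = (relative_change(feat.V_min, prev_feat.V_min) < convergence_tol
                  and relative_change(feat.V_max, prev_feat.V_max) < convergence_tol
                  and relative_change(feat.APD90, prev_feat.APD90) < convergence_tol)
            if ok:
                converged = True
                break
        prev_V_min = feat.V_min
        prev_feat = feat

    # drop the duplicated entry sample of every beat after the first
    t = np.concatenate([tb if i == 0 else tb[1:]
                        for i, (tb, _) in enumerate(kept)])
    ytr = np.vstack([yb if i == 0 else yb[1:]
                     for i, (_, yb) in enumerate(kept)])
    stim_times = np.arange(n_done) * CL
    return Trace(t=t, y=ytr, params=params, protocol=protocol,
                 stim_times=stim_times, features=features,
                 converged=converged, n_beats=n_done,
                 first_kept_beat=n_done - len(kept))
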