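"""Voltage-clamped intracellular Ca2+ subsystem: pulse trains, spontaneous
SR release detection, and bifurcation structure vs clamped V_m.

With V_m a parameter (and Na_i fixed at 6 mM, K_i at 140 mM), the
remaining states form the Ca2+ subsystem whose steady state loses
stability via supercritical Hopf bifurcations in the plateau V_m range
when the SR Ca2+ uptake rate (P_up) is high; spontaneous Ca2+
oscillations -- abrupt Ca_SR falls with Ca_i/Ca_ss rises and inward
I_NCX surges -- live between the Neimark-Sacker points of the limit
cycle born there.  Voltage gates are kept as (fast, equilibrated) states
rather than analytically eliminated; at an equilibrium this is
equivalent and keeps one transcription of the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bifurcation import (BifurcationPoint, EquilibriumPoint, STATE_SCALE,
                          find_limit_cycle, refine_equilibrium)
from .constants import IDX
from .model import gate_steady_state, steady_state_initials
from .params import ParameterSet
from .protocols import ClampProtocol
from .simulate import Trace, integrate

#: release detection defaults
RELEASE_DROP_FRACTION = 0.05     # Ca_SR fall within the window
RELEASE_WINDOW_MS = 100.0
PULSE_EXCLUSION_MS = 50.0


def clamped_params(params: ParameterSet, Vm: float,
                   Nai: float = 6.0) -> ParameterSet:
    """Clamp V_m and fix Na_i/K_i (the clamp-analysis convention)."""
    return replace(params, clamp_Vm=True, Vm_value=float(Vm),
                   fix_Nai=True, Nai_value=Nai, fix_Ki=True)


def holding_steady_state(params: ParameterSet, V_hold: float = -85.0,
                         relax_ms: float = 60_000.0) -> np.ndarray:
    """State after a long clamp at the holding potential."""
    ps = clamped_params(params, V_hold)
    y0 = steady_state_initials(V_hold, ps)
    return integrate(ps, y0, relax_ms, out_step=relax_ms).y[-1]


def simulate_clamped(params: ParameterSet, protocol: ClampProtocol,
                     init: np.ndarray | None = None,
                     out_step: float = 1.0,
                     dt: float | None = None) -> Trace:
    """Run a voltage-clamp pulse train; V_m follows the schedule exactly.

    Returns a single concatenated Trace; pulse onset times are stored in
    ``stim_times``.
    """
    kw = {} if dt is None else {"dt": dt}
    if init is None:
        init = holding_steady_state(params, protocol.V_hold)
    y = init.copy()
    ts, ys, onsets = [], [], []
    t = 0.0
    for dur, V in protocol.schedule():
        ps = clamped_params(params, V)
        if V == protocol.V_test:
            onsets.append(t)
        tr = integrate(ps, y, dur, out_step=out_step, t0=t, **kw)
        y = tr.y[-1].copy()
        ts.append(tr.t if not ts else tr.t[1:])
        ys.append(tr.y if len(ys) == 0 else tr.y[1:])
        t += dur
    return Trace(t=np.concatenate(ts), y=np.vstack(ys), params=params,
                 protocol=protocol, stim_times=np.array(onsets))


@dataclass
class ReleaseEvent:
    """One spontaneous (or pulse-triggered) SR Ca2+ release."""

    onset: float                 # ms
    casr_drop: float             # mM
    casr_drop_frac: float
    peak_cai: float              # mM within the event window
    peak_cass: float
    pulse_triggered: bool = False


def detect_release_events(trace: Trace,
                          drop_fraction: float = RELEASE_DROP_FRACTION,
                          window_ms: float = RELEASE_WINDOW_MS,
                          pulse_onsets: np.ndarray | None = None,
                          exclusion_ms: float = PULSE_EXCLUSION_MS
                          ) -> list[ReleaseEvent]:
    """SR release events: Ca_SR falls >= ``drop_fraction`` within
    ``window_ms`` with a concurrent Ca_i rise.

    Events starting within ``exclusion_ms`` after a pulse onset are
    flagged pulse-triggered (and excluded from spontaneous counts by the
    callers).
    """
    t = trace.t
    casr = trace["CaSR"]
    cai = trace["Cai"]
    cass = trace["Cass"]
    if pulse_onsets is None:
        pulse_onsets = trace.stim_times if trace.stim_times is not None \
            else np.array([])
    step = float(np.median(np.diff(t)))
    w = max(2, int(round(window_ms / step)))
    events: list[ReleaseEvent] = []
    i = 0
    n = len(t)
    while i < n - w:
        j = min(i + w, n - 1)
        drop = casr[i] - np.min(casr[i:j + 1])
        if casr[i] > 0 and drop / casr[i] >= drop_fraction \
                and np.max(cai[i:j + 1]) > cai[i]:
            # onset = first *abrupt* decline inside the triggering window
            # (3x the mean rate implied by the detection threshold), so a
            # window that merely straddles an upcoming steep fall does
            # not acquire a spuriously early onset
            rate_thresh = 3.0 * drop_fraction / window_ms * step
            i0 = i
            while i0 < j and (casr[i0] - casr[i0 + 1]) \
                    < rate_thresh * casr[i0]:
                i0 += 1
            if i0 == j:
                i += 1
                continue
            i = i0
            # extend to the local Ca_SR minimum
            k = i + int(np.argmin(casr[i:j + 1]))
            while k + 1 < n and casr[k + 1] < casr[k]:
                k += 1
            onset = float(t[i])
            trig = bool(np.any((onset - pulse_onsets >= 0)
                               & (onset - pulse_onsets < exclusion_ms)))
            events.append(ReleaseEvent(
                onset=onset,
                casr_drop=float(casr[i] - casr[k]),
                casr_drop_frac=float((casr[i] - casr[k]) / casr[i]),
                peak_cai=float(np.max(cai[i:k + 1])),
                peak_cass=float(np.max(cass[i:k + 1])),
                pulse_triggered=trig))
            i = k + 1
        else:
            i += 1
    return events


def spontaneous_events(events: list[ReleaseEvent]) -> list[ReleaseEvent]:
    return [e for e in events if not e.pulse_triggered]


# ---------------------------------------------------------------------------
# bifurcation structure of the clamped Ca2+ subsystem
# ---------------------------------------------------------------------------

def clamped_equilibrium(params: ParameterSet, Vm: float,
                        relax_ms: float = 60_000.0,
                        warm: np.ndarray | None = None
                        ) -> EquilibriumPoint | None:
    """Steady state of the clamped cell at ``Vm`` with stability."""
    ps = clamped_params(params, Vm)
    guesses = []
    if warm is not None:
        y = warm.copy()
        y[IDX["V"]] = Vm
        y[1:14] = gate_steady_state(Vm, ps, Cass=y[IDX["Cass"]])
        guesses.append(y)
    y0 = steady_state_initials(max(-100, min(-60, Vm)), ps) \
        if -100 <= Vm <= -60 else steady_state_initials(-85.0, ps)
    y0[IDX["V"]] = Vm
    y0[1:14] = gate_steady_state(Vm, ps, Cass=y0[IDX["Cass"]])
    tr = integrate(ps, y0, relax_ms, out_step=relax_ms)
    # average over the tail in case the subsystem oscillates
    guesses.append(tr.y[-1])
    for g in guesses:
        ep = refine_equilibrium(g, ps)
        if ep is not None:
            ep.branch = "Ca_EP"
            return ep
    return None


@dataclass
class CaBifurcationDiagram:
    """Clamped-V_m bifurcation diagram of the Ca2+ subsystem."""

    V_values: np.ndarray
    eps: list                              # EquilibriumPoint | None per V
    hopf_points: list = field(default_factory=list)   # BifurcationPoint
    orbits: list = field(default_factory=list)        # (V, PeriodicOrbit)
    oscillations: list = field(default_factory=list)  # (V, dict) from sim

    def unstable_interval(self, include_missing: bool = True
                          ) -> tuple[float, float] | None:
        """V_m interval without a stable equilibrium.

        Grid points where no equilibrium was found count as not-stable
        when ``include_missing`` (the EP branch can fold away entirely
        inside the oscillatory window at high P_up); edges are placed
        midway between the boundary grid points.
        """
        flags = []
        for v, ep in zip(self.V_values, self.eps):
            if ep is None:
                flags.append(include_missing)
            else:
                flags.append(not ep.is_stable)
        idx = np.flatnonzero(flags)
        if idx.size == 0:
            return None
        V = np.asarray(self.V_values, dtype=float)
        i0, i1 = idx[0], idx[-1]
        lo = 0.5 * (V[i0 - 1] + V[i0]) if i0 > 0 else V[i0]
        hi = 0.5 * (V[i1] + V[i1 + 1]) if i1 + 1 < len(V) else V[i1]
        return (float(lo), float(hi))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, ep in zip(self.V_values, self.eps):
            if ep is None:
                continue
            rows.append({"Vm": v, "Cai": ep.state[IDX["Cai"]],
                         "Cass": ep.state[IDX["Cass"]],
                         "CaSR": ep.state[IDX["CaSR"]],
                         "stable": ep.is_stable, "max_re": ep.max_re})
        return pd.DataFrame(rows)


def ca_bifurcation_vs_vm(params: ParameterSet, V_values: np.ndarray,
                         relax_ms: float = 60_000.0, hb_tol: float = 0.25,
                         with_orbits: bool = False,
                         osc_sim_ms: float = 120_000.0
                         ) -> CaBifurcationDiagram:
    """EP branch and Hopf points of the Ca2+ subsystem vs clamped V_m.

    H_1/H_2 are refined by bisection on the EP stability; optionally the
    limit cycle near each Hopf point is shot and sampled spontaneous
    Ca_i oscillations are measured from long simulations at unstable V_m.
    """
    V_values = np.asarray(V_values, dtype=float)
    eps = []
    warm = None
    for V in V_values:
        ep = clamped_equilibrium(params, V, relax_ms=relax_ms, warm=warm)
        eps.append(ep)
        if ep is not None:
            warm = ep.state
    diagram = CaBifurcationDiagram(V_values=V_values, eps=eps)
    for i in range(1, len(V_values)):
        e0, e1 = eps[i - 1], eps[i]
        if e0 is None or e1 is None or e0.is_stable == e1.is_stable:
            continue
        lo, hi = V_values[i - 1], V_values[i]
        st = e0.state
        while abs(hi - lo) > hb_tol:
            mid = 0.5 * (lo + hi)
            em = clamped_equilibrium(params, mid, relax_ms=relax_ms / 4,
                                     warm=st)
            if em is None:
                break
            st = em.state
            if em.is_stable == e0.is_stable:
                lo = mid
            else:
                hi = mid
        diagram.hopf_points.append(
            BifurcationPoint("HB", 0.5 * (lo + hi), st,
                             detail="supercritical" if e0.is_stable
                             else "stability regained"))
    if with_orbits:
        _sample_oscillations(diagram, params, osc_sim_ms)
    return diagram


def _sample_oscillations(diagram, params, osc_sim_ms):
    for V, ep in zip(diagram.V_values, diagram.eps):
        if ep is None or ep.is_stable:
            continue
        ps = clamped_params(params, V)
        y = ep.state.copy()
        y[IDX["Cass"]] *= 1.05
        tr = integrate(ps, y, osc_sim_ms, out_step=5.0)
        sel = tr.t >= tr.t[-1] - osc_sim_ms / 2
        cai = tr["Cai"][sel]
        t = tr.t[sel]
        amp = float(cai.max() - cai.min())
        from scipy.signal import find_peaks
        pk, _ = find_peaks(cai, prominence=0.25 * amp if amp > 0 else None)
        period = float(np.mean(np.diff(t[pk]))) if len(pk) >= 3 else math.nan
        diagram.oscillations.append(
            (float(V), {"CaO_min": float(cai.min()),
                        "CaO_max": float(cai.max()),
                        "period": period}))
        lead = ep.eigenvalues[np.argmax(ep.eigenvalues.real)]
        if abs(lead.imag) > 1e-9:
            orb = find_limit_cycle(ps, tr.y[-1],
                                   2 * math.pi / abs(lead.imag))
            if orb is not None:
                diagram.orbits.append((float(V), orb))


def hb_locus(params: ParameterSet, axis: str, values: np.ndarray,
             V_bracket: tuple[float, float] = (-85.0, 40.0),
             coarse_n: int = 26, relax_ms: float = 40_000.0,
             hb_tol: float = 0.5) -> pd.DataFrame:
    """Unstable clamped-V_m interval (H_1, H_2) per value of ``axis``.

    Returns a frame with columns (value, V_low, V_high); rows without an
    instability carry NaN bounds.
    """
    rows = []
    for v in np.asarray(values, dtype=float):
        ps = params.with_scales(**{axis: float(v)})
        grid = np.linspace(V_bracket[0], V_bracket[1], coarse_n)
        diag = ca_bifurcation_vs_vm(ps, grid, relax_ms=relax_ms,
                                    hb_tol=hb_tol)
        iv = diag.unstable_interval()
        if iv is None:
            rows.append({"value": v, "V_low": math.nan, "V_high": math.nan})
        else:
            rows.append({"value": v, "V_low": iv[0], "V_high": iv[1]})
    return pd.DataFrame(rows)
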