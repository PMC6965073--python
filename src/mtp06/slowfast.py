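"""Slow-fast decomposition analyses.

Two decompositions explain EAD initiation and termination:

* **xs2-parameterized fast subsystem** -- the I_Ks activation gate xs is
  the slow variable terminating EADs.  The fast subsystem comprises all
  states except xs, Na_i and Ca_SR; bifurcation diagrams of its
  quasi-equilibria (qV_E1-3) and quasi-limit cycles are drawn against
  the channel open probability xs^2 (with Na_i = 6 mM and Ca_SR frozen).
  EADs correspond to transient trapping of the full-system trajectory in
  the basin of a stable depolarized qEP (spiral sink) until the
  trajectory crosses the steady-state xs^2 curve.

* **Ca_SR-parameterized voltage-clamped fast subsystem** -- for
  spontaneous SR Ca2+ release the slow variable is the SR content.  The
  fast subsystem holds the voltage-independent states (fCass, Rbar,
  Ca_ss, Ca_i) with V_m clamped; spontaneous release occurs when the
  full (clamped) trajectory crosses the Hopf value of Ca_SR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bifurcation import (BifurcationPoint, EquilibriumPoint, STATE_SCALE,
                          find_limit_cycle, refine_equilibrium)
from .constants import IDX, N_STATE
from .model import gate_steady_state, rhs, steady_state_initials
from .params import ConfigurationError, ParameterSet
from .simulate import Trace, integrate

XS_FAST_FROZEN = ("xs", "Nai", "CaSR", "Ki")
CASR_FAST_FREE = ("fCass", "Rbar", "Cass", "Cai")


@dataclass(frozen=True)
class FastSubsystemSpec:
    """Definition of a fast subsystem: which slow variables are frozen.

    ``axis`` is the bifurcation parameter: ``"xs2"`` (I_Ks open
    probability; internally xs = sqrt(axis)) or ``"CaSR"`` (mM, with V_m
    clamped at ``Vm``).
    """

    axis: str                       # "xs2" | "CaSR"
    Nai: float = 6.0
    CaSR: float | None = None       # frozen value (xs2 axis only)
    Vm: float | None = None         # clamp value (CaSR axis only)
    Ki: float = 140.0

    def __post_init__(self):
        if self.axis not in ("xs2", "CaSR"):
            raise ConfigurationError("axis must be 'xs2' or 'CaSR'")
        if self.axis == "xs2" and self.CaSR is None:
            raise ConfigurationError("xs2 decomposition needs a frozen CaSR")
        if self.axis == "CaSR" and self.Vm is None:
            raise ConfigurationError("CaSR decomposition needs a clamped Vm")


def build_fast_subsystem(spec: FastSubsystemSpec,
                         params: ParameterSet) -> ParameterSet:
    """Parameter set whose mask freezes the spec's slow variables.

    The reduced right-hand side is the full TP06 RHS restricted to the
    free variables with frozen values substituted (one transcription of
    the model; the mask does the freezing).
    """
    if params.clamp_Vm and spec.axis == "CaSR" \
            and spec.Vm is not None and params.Vm_value != spec.Vm:
        raise ConfigurationError(
            "protocol clamps V_m at a different value than the spec")
    if spec.axis == "xs2":
        return replace(params, fix_Ki=True, Ki_value=spec.Ki,
                       fix_Nai=True, Nai_value=spec.Nai,
                       frozen_extra=("xs", "CaSR"))
    frozen = tuple(n for n in ("V", "m", "h", "j", "d", "f", "f2", "r", "s",
                               "xr1", "xr2", "xs", "CaSR")
                   if n != "V")  # V handled by clamp flag
    return replace(params, fix_Ki=True, Ki_value=spec.Ki,
                   fix_Nai=True, Nai_value=spec.Nai,
                   clamp_Vm=True, Vm_value=float(spec.Vm),
                   frozen_extra=frozen)


def full_system_params(spec: FastSubsystemSpec,
                       params: ParameterSet) -> ParameterSet:
    """Parameters for the *full-system* overlay trajectory: only the
    non-axis slow variables are frozen (for the xs2 decomposition that is
    Na_i, Ca_SR and K_i -- xs itself stays free so the trajectory moves
    across the diagram)."""
    if spec.axis != "xs2":
        raise ConfigurationError(
            "overlay trajectories with a free axis exist only for the "
            "xs2 decomposition; the CaSR decomposition overlays clamped "
            "full-system traces")
    return replace(params, fix_Ki=True, Ki_value=spec.Ki,
                   fix_Nai=True, Nai_value=spec.Nai,
                   frozen_extra=("CaSR",))


def _fast_state(spec: FastSubsystemSpec, params: ParameterSet,
                axis_value: float, template: np.ndarray) -> np.ndarray:
    """Insert the frozen slow-variable values into a state vector."""
    y = np.array(template, dtype=float, copy=True)
    y[IDX["Nai"]] = spec.Nai
    y[IDX["Ki"]] = spec.Ki
    if spec.axis == "xs2":
        y[IDX["xs"]] = math.sqrt(max(0.0, axis_value))
        y[IDX["CaSR"]] = spec.CaSR
    else:
        y[IDX["CaSR"]] = axis_value
        y[IDX["V"]] = spec.Vm
        # voltage gates sit at their clamped-V steady state
        y[1:14] = gate_steady_state(spec.Vm, params, Cass=y[IDX["Cass"]])
    return y


@dataclass
class QuasiBranch:
    """One-parameter bifurcation structure of a fast subsystem."""

    spec: FastSubsystemSpec
    values: np.ndarray
    points: list                                 # per value: list of qEPs
    bifurcations: list = field(default_factory=list)
    orbits: list = field(default_factory=list)   # per value: list of qLCs

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, eps in zip(self.values, self.points):
            for ep in eps:
                rows.append({
                    "axis_value": v, "branch": ep.branch, "V": ep.V,
                    "Cass": ep.state[IDX["Cass"]],
                    "stability": ep.stability, "spiral": ep.spiral,
                    "max_re": ep.max_re,
                })
        return pd.DataFrame(rows)

    def stable_segment(self, branch: str = "V_E3"):
        """(axis value, qEP) pairs where the labeled branch is stable."""
        out = []
        for v, eps in zip(self.values, self.points):
            for ep in eps:
                if ep.branch == branch and ep.is_stable:
                    out.append((v, ep))
        return out


def steady_state_xs2_curve(params: ParameterSet,
                           V_grid: np.ndarray) -> pd.DataFrame:
    """The steady-state open probability xs_inf(V)^2 over a V_m grid."""
    xs2 = [gate_steady_state(V, params)[IDX["xs"] - 1] ** 2 for V in V_grid]
    return pd.DataFrame({"V": V_grid, "xs2": xs2})


def _find_fast_equilibria(spec, ps_fast, params, axis_value,
                          relax_ms, warm_states):
    """Equilibria of the reduced system (seed ladder fits the free set)."""
    found: list[EquilibriumPoint] = []

    def absorb(guess):
        ep = refine_equilibrium(guess, ps_fast)
        if ep is None:
            return
        for other in found:
            if np.max(np.abs((ep.state - other.state) / STATE_SCALE)) < 1e-5:
                return
        found.append(ep)

    for g in warm_states or []:
        absorb(_fast_state(spec, params, axis_value, g))

    max_eps = 3 if spec.axis == "xs2" else 1
    if len(found) < max_eps:
        if spec.axis == "xs2":
            seeds_v = (-90.0, -75.0, -60.0, -40.0, -25.0, -10.0, 0.0, 15.0)
            for V in seeds_v:
                y = steady_state_initials(-85.0, params)
                y[IDX["V"]] = V
                y[1:14] = gate_steady_state(V, params, Cass=y[IDX["Cass"]])
                y = _fast_state(spec, params, axis_value, y)
                ps_rel = replace(ps_fast, clamp_Vm=True, Vm_value=V)
                tr = integrate(ps_rel, y, relax_ms, out_step=relax_ms)
                y_rel = tr.y[-1].copy()
                y_rel[IDX["V"]] = V
                absorb(y_rel)
        else:
            for cass0 in (1e-4, 1e-3):
                y = steady_state_initials(-85.0, params)
                y[IDX["Cass"]] = cass0
                y = _fast_state(spec, params, axis_value, y)
                tr = integrate(ps_fast, y, relax_ms, out_step=relax_ms)
                absorb(tr.y[-1])
    found.sort(key=lambda e: e.V if spec.axis == "xs2"
               else e.state[IDX["Cass"]])
    for i, ep in enumerate(found[:3]):
        ep.branch = f"V_E{i + 1}" if spec.axis == "xs2" else "Ca_EP"
    return found[:3]


def quasi_branch(spec: FastSubsystemSpec, params: ParameterSet,
                 axis_values: np.ndarray, relax_ms: float = 20_000.0,
                 hb_tol: float | None = None,
                 with_orbits: bool = False) -> QuasiBranch:
    """Continue the fast subsystem's equilibria along the axis.

    Tracks stability/spiral character, refines Hopf points of the
    depolarized branch by bisection, and (optionally) shoots for the
    limit cycles born there.
    """
    axis_values = np.asarray(axis_values, dtype=float)
    ps_fast = build_fast_subsystem(spec, params)
    if hb_tol is None:
        hb_tol = max(1e-4, 0.002 * abs(axis_values[-1] - axis_values[0]))
    points, bifs, orbits = [], [], []
    warm: list[np.ndarray] = []
    track = "V_E3" if spec.axis == "xs2" else "Ca_EP"
    for i, v in enumerate(axis_values):
        eps = _find_fast_equilibria(spec, ps_fast, params, v, relax_ms, warm)
        points.append(eps)
        orbits.append([])
        warm = [ep.state for ep in eps]
        if i == 0:
            continue
        e0 = next((e for e in points[-2] if e.branch == track), None)
        e1 = next((e for e in eps if e.branch == track), None)
        if e0 is None or e1 is None or e0.is_stable == e1.is_stable:
            continue
        lo, hi = axis_values[i - 1], v
        st = e0.state
        while abs(hi - lo) > hb_tol:
            mid = 0.5 * (lo + hi)
            em = _find_fast_equilibria(spec, ps_fast, params, mid,
                                       relax_ms, [st])
            em = next((e for e in em if e.branch == track), None)
            if em is None:
                break
            st = em.state
            if em.is_stable == e0.is_stable:
                lo = mid
            else:
                hi = mid
        spiral = e0.spiral or e1.spiral
        bifs.append(BifurcationPoint("HB" if spiral else "SNB_EP",
                                     0.5 * (lo + hi), st, detail=track))
    qb = QuasiBranch(spec=spec, values=axis_values, points=points,
                     bifurcations=bifs, orbits=orbits)
    if with_orbits:
        _attach_orbits(qb, params, ps_fast)
    return qb


def _attach_orbits(qb: QuasiBranch, params: ParameterSet,
                   ps_fast: ParameterSet) -> None:
    """Seed quasi-LCs from simulation near unstable spiral qEPs."""
    for i, (v, eps) in enumerate(zip(qb.values, qb.points)):
        for ep in eps:
            if ep.is_stable or not ep.spiral:
                continue
            lead = ep.eigenvalues[np.argmax(ep.eigenvalues.real)]
            if abs(lead.imag) < 1e-6:
                continue
            T_guess = 2.0 * math.pi / abs(lead.imag)
            y = ep.state.copy()
            y[IDX["Cass"]] *= 1.05
            tr = integrate(ps_fast, y, min(20 * T_guess, 60_000.0),
                           out_step=1.0)
            orb = find_limit_cycle(ps_fast, tr.y[-1], T_guess)
            if orb is not None:
                qb.orbits[i].append(orb)
            break


@dataclass
class OverlayReport:
    """Projection of a full-system trajectory onto a quasi-branch diagram."""

    projection: pd.DataFrame
    trapped: bool
    dwell_ms: float
    crossed_hb: bool | None = None   # CaSR decomposition only
    crossing_time: float | None = None


def overlay_trajectory(trace: Trace, qb: QuasiBranch, params: ParameterSet,
                       trap_radius_mv: float = 2.0,
                       dwell_threshold_ms: float = 100.0) -> OverlayReport:
    """Project a full-system trace onto the decomposition plane.

    For the xs2 decomposition the projection is (xs^2, V_m) and the
    report measures the dwell time within ``trap_radius_mv`` of the
    stable depolarized qEP segment before the trajectory crosses the
    steady-state xs^2 curve.  For the Ca_SR decomposition the projection
    is (Ca_SR, Ca_ss) and the report states whether the trajectory
    crossed the Hopf value of Ca_SR.
    """
    spec = qb.spec
    if spec.axis == "xs2":
        x = trace["xs"] ** 2
        yv = trace.V
        proj = pd.DataFrame({"xs2": x, "V": yv, "t": trace.t})
        # trapping ends when the trajectory crosses the steady-state
        # xs^2 curve (xs stops growing; repolarization proceeds)
        xs2_inf = np.array([gate_steady_state(V, params)[IDX["xs"] - 1] ** 2
                            for V in yv])
        below = x < xs2_inf
        n_end = len(x)
        if np.any(below):
            first_below = int(np.argmax(below))
            crossed = np.flatnonzero(~below[first_below:])
            if crossed.size:
                n_end = first_below + int(crossed[0])
        seg = qb.stable_segment("V_E3")
        dwell = 0.0
        if seg and n_end > 1:
            xs_vals = np.array([s[0] for s in seg])
            v_vals = np.array([s[1].V for s in seg])
            xw = x[:n_end]
            vw = yv[:n_end]
            inside = (xw >= xs_vals.min() - 1e-9) \
                & (xw <= xs_vals.max() + 1e-9)
            if np.any(inside):
                v_near = np.interp(xw[inside], xs_vals, v_vals)
                near = np.abs(vw[inside] - v_near) <= trap_radius_mv
                dwell = float(np.sum(near) * np.median(np.diff(trace.t)))
        return OverlayReport(projection=proj,
                             trapped=dwell >= dwell_threshold_ms,
                             dwell_ms=dwell)
    # CaSR decomposition
    proj = pd.DataFrame({"CaSR": trace["CaSR"], "Cass": trace["Cass"],
                         "t": trace.t})
    hb = next((b for b in qb.bifurcations if b.kind == "HB"), None)
    crossed_hb = None
    t_cross = None
    if hb is not None:
        above = trace["CaSR"] >= hb.value
        crossed_hb = bool(np.any(above))
        if crossed_hb:
            t_cross = float(trace.t[np.argmax(above)])
    return OverlayReport(projection=proj, trapped=False, dwell_ms=0.0,
                         crossed_hb=crossed_hb, crossing_time=t_cross)
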