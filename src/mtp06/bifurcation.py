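"""Equilibria, limit cycles, and bifurcations of the non-paced cell.

The autonomous analyses fix K_i (140 mM) to remove the conservation
degeneracy of the free-K_i system; Na_i stays free unless the protocol
fixes it.  Equilibria are located by damped root finding from a ladder
of membrane-potential seeds whose concentration variables are first
relaxed under a V_m clamp; stability comes from eigenvalues of a central
finite-difference Jacobian.  Limit cycles are found by single shooting
(period as unknown, one state component anchored) and their Floquet
multipliers from a finite-difference monodromy matrix.

Branch continuation is natural-parameter stepping with warm starts and
bisection refinement of bifurcation points -- adequate because the
underlying study scans branches on fine parameter grids; folds are
handled by bidirectional scanning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root

from . import _kernel
from .constants import IDX, N_CURRENT, N_STATE
from .model import steady_state_initials
from .params import ParameterSet
from .simulate import integrate, integrate_lsoda

#: per-variable magnitude scales used for residual/step normalization
STATE_SCALE = np.ones(N_STATE)
STATE_SCALE[IDX["V"]] = 100.0
STATE_SCALE[IDX["Cai"]] = 1e-3
STATE_SCALE[IDX["Cass"]] = 1e-3
STATE_SCALE[IDX["CaSR"]] = 1.0
STATE_SCALE[IDX["Nai"]] = 10.0
STATE_SCALE[IDX["Ki"]] = 140.0

EP_RESIDUAL_TOL = 1e-10
TRIVIAL_MULTIPLIER_TOL = 1e-3


#: residual rate scales for the non-gating states (per-ms change that
#: counts as O(1) for the Newton solver); gating states use their
#: fixed-point form y - y_inf instead, which removes the 1/tau stiffness
RES_SCALE = np.ones(N_STATE)
RES_SCALE[IDX["V"]] = 1.0        # mV/ms
RES_SCALE[IDX["Cai"]] = 1e-6     # mM/ms
RES_SCALE[IDX["Cass"]] = 1e-5
RES_SCALE[IDX["CaSR"]] = 1e-3
RES_SCALE[IDX["Nai"]] = 1e-5
RES_SCALE[IDX["Ki"]] = 1e-5

_GATES = np.arange(1, 14)


def _free_rhs_factory(params: ParameterSet):
    """Well-conditioned residual function on the free coordinates.

    Works in z-space (z = y/scale) so the solver sees O(1) variables.
    Gating equations are posed as y - y_inf(V, Ca_ss) = 0 (equivalent
    roots, unit condition number); the remaining balances are scaled by
    characteristic rates.  States outside the admissible region get a
    distance-from-feasible penalty instead of a model call.
    """
    p = params.kernel_p()
    mask = params.kernel_mask()
    free = np.flatnonzero(mask == 0.0)
    conc = np.array([IDX["Cai"], IDX["Cass"], IDX["CaSR"], IDX["Nai"],
                     IDX["Ki"]])
    gate_pos = np.isin(free, _GATES)
    dy = np.empty(N_STATE)
    cur = np.empty(N_CURRENT)
    inf = np.empty(N_STATE)
    tau = np.zeros(N_STATE)

    def f_scaled(z, template):
        y = template.copy()
        y[free] = z * STATE_SCALE[free]
        bad = 0.0
        for i in conc:
            if y[i] <= 0.0:
                bad += 1.0 - y[i] / STATE_SCALE[i]
        if abs(y[IDX["V"]]) > 500.0:
            bad += abs(y[IDX["V"]]) / 500.0
        if bad > 0.0:
            return np.full(len(free), 10.0 + bad)
        _kernel._eval(y, p, 0.0, dy, cur, inf, tau)
        r = dy[free] / RES_SCALE[free]
        r[gate_pos] = (y[free] - inf[free])[gate_pos]
        return r

    return f_scaled, free


def _raw_residual(y: np.ndarray, params: ParameterSet) -> float:
    """max |dy_i| / state scale over the free coordinates."""
    dy = np.empty(N_STATE)
    cur = np.empty(N_CURRENT)
    free = np.flatnonzero(params.kernel_mask() == 0.0)
    _kernel.rhs_into(y, params.kernel_p(), params.kernel_mask(), 0.0,
                     dy, cur)
    return float(np.max(np.abs(dy[free] / STATE_SCALE[free])))


@dataclass
class EquilibriumPoint:
    """Steady state of the autonomous (or clamped) system."""

    state: np.ndarray
    params: ParameterSet
    eigenvalues: np.ndarray | None = None
    residual: float = np.nan
    branch: str | None = None     # V_E1 / V_E2 / V_E3 by V_m ordering

    @property
    def V(self) -> float:
        return float(self.state[IDX["V"]])

    @property
    def max_re(self) -> float:
        return float(np.max(self.eigenvalues.real))

    @property
    def stability(self) -> str:
        if self.eigenvalues is None:
            return "indeterminate"
        re = self.eigenvalues.real
        if not np.all(np.isfinite(re)):
            return "indeterminate"
        if np.max(re) < 0.0:
            return "stable"
        if np.min(re) < 0.0 < np.max(re):
            return "saddle"
        return "unstable"

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"

    @property
    def spiral(self) -> bool:
        """Leading (largest real part) eigenvalue belongs to a complex pair."""
        if self.eigenvalues is None:
            return False
        lead = self.eigenvalues[np.argmax(self.eigenvalues.real)]
        return abs(lead.imag) > 1e-12

    @property
    def leading_complex(self) -> complex | None:
        """Complex-pair eigenvalue with the largest real part (the mode
        that makes the approach/escape oscillatory)."""
        if self.eigenvalues is None:
            return None
        cplx = self.eigenvalues[np.abs(self.eigenvalues.imag) > 1e-9]
        if cplx.size == 0:
            return None
        return complex(cplx[np.argmax(cplx.real)])

    @property
    def spiral_character(self) -> str | None:
        """'sink' or 'source' by the sign of the leading complex pair's
        real part (the convention behind spiral-sink/source labels)."""
        lead = self.leading_complex
        if lead is None:
            return None
        return "sink" if lead.real < 0 else "source"


def jacobian(state: np.ndarray, params: ParameterSet,
             rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the true RHS on the free
    state dimensions, in similarity-scaled coordinates (eigenvalues are
    unchanged by the diagonal scaling)."""
    p = params.kernel_p()
    mask = params.kernel_mask()
    free = np.flatnonzero(mask == 0.0)
    y = params.apply_clamps(state)
    dy = np.empty(N_STATE)
    cur = np.empty(N_CURRENT)

    def g(yy):
        _kernel.rhs_into(yy, p, mask, 0.0, dy, cur)
        return dy[free] / STATE_SCALE[free]

    n = len(free)
    J = np.empty((n, n))
    for k in range(n):
        h = rel_step * STATE_SCALE[free[k]]
        yp = y.copy(); yp[free[k]] += h
        ym = y.copy(); ym[free[k]] -= h
        J[:, k] = (g(yp) - g(ym)) * (STATE_SCALE[free[k]] / (2.0 * h))
    return J


def refine_equilibrium(y_guess: np.ndarray, params: ParameterSet
                       ) -> EquilibriumPoint | None:
    """Newton-polish an equilibrium guess; None if no convergence."""
    f, free = _free_rhs_factory(params)
    y = params.apply_clamps(y_guess)
    sol = root(lambda z: f(z, y), y[free] / STATE_SCALE[free], method="hybr",
               options={"xtol": 1e-13, "maxfev": 4000})
    if not sol.success:
        return None
    y_ep = y.copy()
    y_ep[free] = sol.x * STATE_SCALE[free]
    gates = y_ep[1:14]
    if np.any(gates < -1e-6) or np.any(gates > 1.0 + 1e-6):
        return None
    if np.any(y_ep[[IDX["Cai"], IDX["Cass"], IDX["CaSR"], IDX["Nai"]]] <= 0):
        return None
    res = _raw_residual(y_ep, params)
    if res > EP_RESIDUAL_TOL:
        return None
    ep = EquilibriumPoint(state=y_ep, params=params, residual=res)
    ep.eigenvalues = np.linalg.eigvals(jacobian(y_ep, params))
    return ep


def _refine_via_nai_secant(y_guess: np.ndarray, params: ParameterSet,
                           max_outer: int = 40) -> EquilibriumPoint | None:
    """Robust equilibrium refinement across the slow Na_i manifold.

    Na_i equilibrates orders of magnitude more slowly than the rest of
    the state, which defeats a plain Newton solve from distant seeds.
    Here Na_i is treated as the outer unknown: for fixed Na_i the fast
    remainder is solved by Newton, and the Na_i balance (dNa_i/dt at
    that fast equilibrium) is driven to zero by a secant iteration.
    """
    from dataclasses import replace as _replace

    if params.fix_Nai:
        return None
    i_na = IDX["Nai"]
    dy = np.empty(N_STATE)
    cur = np.empty(N_CURRENT)

    state_cache = {"y": np.array(y_guess, dtype=float)}

    def g(nai: float) -> float | None:
        ps_fix = _replace(params, fix_Nai=True, Nai_value=float(nai))
        y0 = state_cache["y"].copy()
        y0[i_na] = nai
        ep = refine_equilibrium(y0, ps_fix)
        if ep is None:
            return None
        state_cache["y"] = ep.state
        _kernel.rhs_into(ep.state, params.kernel_p(),
                         params.kernel_mask(), 0.0, dy, cur)
        return float(dy[i_na])

    n0 = float(np.clip(y_guess[i_na], 0.5, 25.0))
    n1 = n0 * 0.9 if n0 > 1.0 else n0 + 0.5
    g0, g1 = g(n0), g(n1)
    if g0 is None or g1 is None:
        return None
    for _ in range(max_outer):
        if abs(g1) < 1e-13:
            break
        if g1 == g0:
            return None
        n2 = n1 - g1 * (n1 - n0) / (g1 - g0)
        if not np.isfinite(n2) or n2 <= 0.05:
            n2 = 0.5 * (n0 + n1)
        n0, g0 = n1, g1
        n1 = float(np.clip(n2, 0.1, 40.0))
        g1 = g(n1)
        if g1 is None:
            return None
    else:
        return None
    return refine_equilibrium(state_cache["y"], params)


def ep_stability(ep: EquilibriumPoint) -> str:
    """(Re)compute eigenvalues and return the stability class."""
    ep.eigenvalues = np.linalg.eigvals(jacobian(ep.state, ep.params))
    return ep.stability


def find_equilibria(params: ParameterSet, v_seeds: np.ndarray | None = None,
                    relax_ms: float = 30_000.0,
                    warm_states: list | None = None) -> list[EquilibriumPoint]:
    """Locate up to three equilibria of the autonomous system.

    Seeds a ladder of membrane potentials (gates at steady state), relaxes
    the remaining variables under a V_m clamp for ``relax_ms``, then
    releases the clamp and root-finds on the full free system.  Duplicate
    solutions are merged; results sorted by V_m and labeled V_E1..V_E3.
    """
    if v_seeds is None:
        v_seeds = np.array([-90, -85, -80, -75, -70, -60, -50, -40,
                            -30, -20, -10, 0, 10, 20], dtype=float)

    found: list[EquilibriumPoint] = []

    def absorb(guess):
        ep = refine_equilibrium(guess, params)
        if ep is None:
            ep = _refine_via_nai_secant(guess, params)
        if ep is None:
            return
        for other in found:
            if np.max(np.abs((ep.state - other.state) / STATE_SCALE)) < 1e-5:
                return
        found.append(ep)

    # warm starts first; the seed ladder only runs when they do not
    # already account for the full (three-point) equilibrium structure
    for g in warm_states or []:
        absorb(g)
    if len(found) >= 3:
        found.sort(key=lambda e: e.V)
        for i, ep in enumerate(found[:3]):
            ep.branch = f"V_E{i + 1}"
        return found[:3]

    guesses: list[np.ndarray] = []
    from dataclasses import replace
    for V in v_seeds:
        ps_cl = replace(params, clamp_Vm=True, Vm_value=float(V))
        y = steady_state_initials(max(-100.0, min(-60.0, V)), ps_cl) \
            if -100 <= V <= -60 else None
        if y is None:
            y = steady_state_initials(-85.0, params)
            y[IDX["V"]] = V
            from .model import gate_steady_state
            y[1:14] = gate_steady_state(V, params, Cass=y[IDX["Cass"]])
        y = ps_cl.apply_clamps(y)
        tr = integrate(ps_cl, y, relax_ms, out_step=relax_ms)
        guesses.append(tr.y[-1])
    for g in guesses:
        absorb(g)
    found.sort(key=lambda e: e.V)
    for i, ep in enumerate(found[:3]):
        ep.branch = f"V_E{i + 1}"
    return found[:3]


# ---------------------------------------------------------------------------
# periodic orbits
# ---------------------------------------------------------------------------

@dataclass
class PeriodicOrbit:
    """Limit cycle found by single shooting."""

    y0: np.ndarray               # full state on the section
    period: float                # ms
    params: ParameterSet
    multipliers: np.ndarray | None = None
    t: np.ndarray | None = None  # one sampled period
    y: np.ndarray | None = None
    closure_error: float = np.nan

    @property
    def V_extrema(self) -> tuple[float, float]:
        V = self.y[:, IDX["V"]]
        return float(V.min()), float(V.max())

    @property
    def trivial_multiplier(self) -> float:
        return float(np.abs(self.multipliers)[
            np.argmin(np.abs(np.abs(self.multipliers) - 1.0))])

    @property
    def nontrivial_multipliers(self) -> np.ndarray:
        k = np.argmin(np.abs(self.multipliers - 1.0))
        return np.delete(self.multipliers, k)

    @property
    def is_stable(self) -> bool:
        return bool(np.all(np.abs(self.nontrivial_multipliers) < 1.0))


def _flow(params: ParameterSet, y0: np.ndarray, T: float,
          rtol: float = 1e-8) -> np.ndarray:
    tr = integrate_lsoda(params, y0, T, rtol=rtol)
    return tr.y[-1]


def find_limit_cycle(params: ParameterSet, seed_state: np.ndarray,
                     period_guess: float, rtol: float = 1e-8,
                     max_iter: int = 25) -> PeriodicOrbit | None:
    """Single-shooting limit-cycle search.

    ``seed_state`` should lie near the orbit (e.g. from simulation near a
    Hopf point or a spontaneous oscillation); the anchor (Poincare phase
    condition) fixes the state component of largest oscillation at its
    seed value, leaving the period as the extra unknown.
    """
    free = params.free_indices()
    y_base = params.apply_clamps(seed_state)
    # choose anchor: component with the largest scaled derivative
    from .model import rhs
    dy0 = rhs(0.0, y_base, params)
    anchor = free[np.argmax(np.abs(dy0[free] / STATE_SCALE[free]))]
    others = np.array([i for i in free if i != anchor])

    def residual(z):
        y = y_base.copy()
        y[others] = z[:-1] * STATE_SCALE[others]
        T = z[-1] * period_guess
        if T <= 0:
            return np.full(len(free), 1e3)
        yT = _flow(params, y, T, rtol=rtol)
        return (yT - y)[free] / STATE_SCALE[free]

    z0 = np.concatenate([y_base[others] / STATE_SCALE[others], [1.0]])
    sol = root(residual, z0, method="hybr",
               options={"xtol": 1e-10, "maxfev": max_iter * (len(free) + 1)})
    res = np.max(np.abs(residual(sol.x)))
    if res > 1e-6:
        return None
    y0 = y_base.copy()
    y0[others] = sol.x[:-1] * STATE_SCALE[others]
    T = sol.x[-1] * period_guess
    tr = integrate_lsoda(params, y0, T, rtol=rtol,
                         t_eval=np.linspace(0.0, T, 400))
    orbit = PeriodicOrbit(y0=y0, period=T, params=params,
                          t=tr.t, y=tr.y, closure_error=float(res))
    orbit.multipliers = monodromy_multipliers(orbit)
    return orbit


def monodromy_multipliers(orbit: PeriodicOrbit, dt_sub: float = 0.05,
                          rtol: float = 1e-10) -> np.ndarray:
    """Floquet multipliers via the variational equations along the orbit.

    The fundamental matrix is propagated as Phi <- expm(J dt) Phi with
    the Jacobian refreshed every ``dt_sub`` ms on the shot orbit
    (finite-difference perturbation of initial conditions fails here:
    relaxation-type Ca2+ cycles shift their release timing nonlinearly
    under any finite perturbation).  The quality gate is the trivial
    multiplier's distance from 1.
    """
    from scipy.linalg import expm

    params = orbit.params
    free = params.free_indices()
    n = len(free)
    n_steps = max(8, int(math.ceil(orbit.period / dt_sub)))
    h = orbit.period / n_steps
    t_eval = np.linspace(0.0, orbit.period, n_steps + 1)
    tr = integrate_lsoda(params, orbit.y0, orbit.period, rtol=rtol,
                         t_eval=t_eval)
    Phi = np.eye(n)
    for k in range(n_steps):
        # Jacobian at the interval midpoint (midpoint-Magnus propagation)
        y_mid = 0.5 * (tr.y[k] + tr.y[k + 1])
        J = jacobian(y_mid, params)
        # undo the similarity scaling used by jacobian(): multipliers of
        # the scaled system equal those of the original, so propagate in
        # scaled coordinates throughout
        Phi = expm(J * h) @ Phi
    return np.linalg.eigvals(Phi)


# ---------------------------------------------------------------------------
# spontaneous oscillations
# ---------------------------------------------------------------------------

@dataclass
class SOResult:
    """Outcome of a long unstimulated run from a depolarized state."""

    kind: str                    # "SO" | "equilibrium" | "rest"
    V_min: float = np.nan
    V_max: float = np.nan
    period: float = np.nan       # ms (mean cycle over the window)
    final_state: np.ndarray | None = None


def detect_spontaneous_oscillation(params: ParameterSet, init: np.ndarray,
                                   total_ms: float = 300_000.0,
                                   window_ms: float = 60_000.0,
                                   amp_threshold: float = 1.0,
                                   dt: float | None = None) -> SOResult:
    """Classify the asymptotic unstimulated behavior from ``init``.

    ``SO``: sustained V_m oscillation of amplitude >= 1 mV in the last
    window; ``rest``: quiescent below the resting threshold; otherwise
    ``equilibrium`` (arrest at a depolarized stable steady state).
    """
    kw = {} if dt is None else {"dt": dt}
    tr = integrate(params, init, total_ms, out_step=5.0, **kw)
    sel = tr.t >= tr.t[-1] - window_ms
    V = tr.V[sel]
    t = tr.t[sel]
    amp = float(V.max() - V.min())
    if amp >= amp_threshold:
        from scipy.signal import find_peaks
        pk, _ = find_peaks(V, prominence=0.5 * amp_threshold)
        period = float(np.mean(np.diff(t[pk]))) if len(pk) >= 3 else np.nan
        return SOResult("SO", float(V.min()), float(V.max()), period,
                        tr.y[-1])
    if V.max() < -75.0:
        return SOResult("rest", float(V.min()), float(V.max()),
                        final_state=tr.y[-1])
    return SOResult("equilibrium", float(V.min()), float(V.max()),
                    final_state=tr.y[-1])


# ---------------------------------------------------------------------------
# branches
# ---------------------------------------------------------------------------

@dataclass
class BifurcationPoint:
    kind: str                    # HB | SNB_EP | SNB_LC | PDB | NSB | hom
    value: float                 # axis value
    state: np.ndarray | None = None
    detail: str = ""


@dataclass
class Branch:
    """One-parameter continuation result."""

    axis: str
    values: np.ndarray
    points: list            # per value: list of EquilibriumPoint or orbit
    bifurcations: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, eps in zip(self.values, self.points):
            for ep in eps:
                rows.append({
                    "axis_value": v, "branch": ep.branch, "V": ep.V,
                    "stability": ep.stability, "max_re": ep.max_re,
                    "spiral": ep.spiral,
                })
        return pd.DataFrame(rows)


def _match_branches(prev: list, cur: list) -> None:
    """Propagate branch labels by nearest V_m (handles branch count change)."""
    if not prev:
        return
    for ep in cur:
        if ep.branch is None and prev:
            near = min(prev, key=lambda q: abs(q.V - ep.V))
            ep.branch = near.branch


def continue_ep_branch(params: ParameterSet, axis: str,
                       values: np.ndarray, relax_ms: float = 30_000.0,
                       hb_tol: float = 1e-4,
                       v_seeds: np.ndarray | None = None) -> Branch:
    """Natural-parameter continuation of all equilibria along one axis.

    Hopf points are refined by bisection on the sign of the leading
    complex pair's real part of each labeled branch; saddle-node points
    are flagged where a branch appears/disappears or a real eigenvalue
    crosses zero.
    """
    values = np.asarray(values, dtype=float)
    points: list[list[EquilibriumPoint]] = []
    bifs: list[BifurcationPoint] = []
    warm: list[np.ndarray] = []

    def eps_at(x, warm_states):
        ps = params.with_scales(**{axis: float(x)})
        eps = find_equilibria(ps, v_seeds=v_seeds, relax_ms=relax_ms,
                              warm_states=warm_states)
        return eps

    for i, v in enumerate(values):
        eps = eps_at(v, warm)
        if points:
            _match_branches(points[-1], eps)
        points.append(eps)
        warm = [ep.state for ep in eps]
        if i == 0:
            continue
        prev = {ep.branch: ep for ep in points[-2]}
        cur = {ep.branch: ep for ep in eps}
        for name in set(prev) & set(cur):
            e0, e1 = prev[name], cur[name]
            # complex-pair real-part sign change -> HB
            lead0 = e0.eigenvalues[np.argmax(e0.eigenvalues.real)]
            lead1 = e1.eigenvalues[np.argmax(e1.eigenvalues.real)]
            if (abs(lead0.imag) > 1e-9 or abs(lead1.imag) > 1e-9) \
                    and np.sign(lead0.real) != np.sign(lead1.real):
                lo, hi = values[i - 1], v
                st = e0.state
                while abs(hi - lo) > hb_tol:
                    mid = 0.5 * (lo + hi)
                    eps_m = eps_at(mid, [st])
                    _match_branches(points[-2], eps_m)
                    em = next((e for e in eps_m if e.branch == name), None)
                    if em is None:
                        break
                    st = em.state
                    if np.sign(em.max_re) == np.sign(lead0.real):
                        lo = mid
                    else:
                        hi = mid
                bifs.append(BifurcationPoint("HB", 0.5 * (lo + hi), st,
                                             detail=name))
            elif np.sign(lead0.real) != np.sign(lead1.real):
                bifs.append(BifurcationPoint(
                    "SNB_EP", 0.5 * (values[i - 1] + v), e1.state,
                    detail=f"{name} real eigenvalue zero-crossing"))
        for name in set(prev) - set(cur):
            bifs.append(BifurcationPoint(
                "SNB_EP", 0.5 * (values[i - 1] + v), prev[name].state,
                detail=f"{name} branch fold"))
        for name in set(cur) - set(prev):
            bifs.append(BifurcationPoint(
                "SNB_EP", 0.5 * (values[i - 1] + v), cur[name].state,
                detail=f"{name} branch fold"))
    return Branch(axis=axis, values=values, points=points, bifurcations=bifs)


def continue_lc_branch(params: ParameterSet, axis: str, values: np.ndarray,
                       seed_orbit: PeriodicOrbit,
                       period_cap: float = 20_000.0) -> Branch:
    """Continue a limit-cycle branch by warm-started shooting.

    Flags PDB (a real multiplier crossing -1), NSB (a complex pair
    crossing the unit circle), SNB_LC (+1 crossing), and a heuristic
    homoclinic endpoint when the period exceeds ``period_cap``.
    """
    values = np.asarray(values, dtype=float)
    orbits: list[list] = []
    bifs: list[BifurcationPoint] = []
    prev = seed_orbit
    for i, v in enumerate(values):
        ps = params.with_scales(**{axis: float(v)})
        orb = find_limit_cycle(ps, prev.y0, prev.period)
        orbits.append([orb] if orb else [])
        if orb is None:
            if prev is not None and prev.period > 0.5 * period_cap:
                bifs.append(BifurcationPoint("hom", v, prev.y0,
                                             "period blow-up / branch loss"))
            break
        if orb.period > period_cap:
            bifs.append(BifurcationPoint("hom", v, orb.y0, "period cap"))
            break
        if i > 0 and orbits[i - 1]:
            p0, p1 = orbits[i - 1][0], orb
            m0 = p0.nontrivial_multipliers
            m1 = p1.nontrivial_multipliers
            def crossing(sel0, sel1, which):
                if sel0 != sel1:
                    bifs.append(BifurcationPoint(
                        which, 0.5 * (values[i - 1] + v), p1.y0))
            # real negative multiplier magnitude crossing 1 -> PDB
            def worst(ms, pred):
                cand = [abs(mu) for mu in ms if pred(mu)]
                return max(cand) if cand else None
            pd0 = worst(m0, lambda mu: abs(mu.imag) < 1e-6 and mu.real < 0)
            pd1 = worst(m1, lambda mu: abs(mu.imag) < 1e-6 and mu.real < 0)
            if pd0 is not None and pd1 is not None:
                crossing(pd0 > 1, pd1 > 1, "PDB")
            ns0 = worst(m0, lambda mu: abs(mu.imag) >= 1e-6)
            ns1 = worst(m1, lambda mu: abs(mu.imag) >= 1e-6)
            if ns0 is not None and ns1 is not None:
                crossing(ns0 > 1, ns1 > 1, "NSB")
            sn0 = worst(m0, lambda mu: abs(mu.imag) < 1e-6 and mu.real > 0)
            sn1 = worst(m1, lambda mu: abs(mu.imag) < 1e-6 and mu.real > 0)
            if sn0 is not None and sn1 is not None:
                crossing(sn0 > 1, sn1 > 1, "SNB_LC")
        prev = orb
    return Branch(axis=axis, values=values[:len(orbits)], points=orbits,
                  bifurcations=bifs)


def two_parameter_curves(params: ParameterSet, axis1: str,
                         values1: np.ndarray, axis2: str,
                         bracket2: tuple[float, float],
                         so_total_ms: float = 300_000.0,
                         tol2: float = 1e-3,
                         relax_ms: float = 30_000.0) -> dict:
    """Loci of Hopf points and SO onset/offset on a parameter plane.

    For each value of ``axis1``, the Hopf point of the depolarized
    equilibrium (V_E3) along ``axis2`` is found by eigenvalue bisection,
    and the onset (SO_1) / offset (SO_2) of spontaneous oscillations by
    bisection on the long-run classification started near V_E3.
    """
    out = {"HB": [], "SO1": [], "SO2": []}
    for v1 in np.asarray(values1, dtype=float):
        ps1 = params.with_scales(**{axis1: float(v1)})

        def ve3(x):
            ps = ps1.with_scales(**{axis2: float(x)})
            eps = find_equilibria(ps, relax_ms=relax_ms)
            return (eps[-1], ps) if len(eps) == 3 else (None, ps)

        lo, hi = bracket2
        ep_lo, _ = ve3(lo)
        ep_hi, _ = ve3(hi)
        if ep_lo is not None and ep_hi is not None \
                and ep_lo.is_stable != ep_hi.is_stable:
            a, b = lo, hi
            while abs(b - a) > tol2:
                mid = 0.5 * (a + b)
                em, _ = ve3(mid)
                if em is None:
                    break
                if em.is_stable == ep_lo.is_stable:
                    a = mid
                else:
                    b = mid
            out["HB"].append((v1, 0.5 * (a + b)))

        def so_kind(x):
            ps = ps1.with_scales(**{axis2: float(x)})
            eps = find_equilibria(ps, relax_ms=relax_ms)
            if len(eps) < 3:
                return None
            y = eps[-1].state.copy()
            y[IDX["V"]] += 1.0
            return detect_spontaneous_oscillation(
                ps, y, total_ms=so_total_ms).kind

        k_lo, k_hi = so_kind(lo), so_kind(hi)
        if k_lo is not None and k_hi is not None and k_lo != k_hi \
                and "SO" in (k_lo, k_hi):
            a, b = lo, hi
            ref = k_lo
            while abs(b - a) > tol2:
                mid = 0.5 * (a + b)
                km = so_kind(mid)
                if km is None:
                    break
                if km == ref:
                    a = mid
                else:
                    b = mid
            key = "SO1" if k_lo == "SO" else "SO2"
            out[key].append((v1, 0.5 * (a + b)))
    return out
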