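"""Two-parameter phase diagrams of the paced cell, with boundary
refinement and overlay of non-paced bifurcation curves.

Grid sweeps follow the warm-start convention: the first point of every
line is paced to (near-)steady state, subsequent points inherit the
previous point's final state.  Desk-scale defaults use coarse grids with
bisection-refined boundaries instead of exhaustive fine scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import BehaviorLabel, classify_behavior
from .params import ConfigurationError, ParameterSet
from .protocols import PacingProtocol, make_pacing
from .simulate import IntegrationError, simulate_paced


@dataclass
class PhaseDiagram:
    """Grid of behavior labels on a 2-D parameter plane."""

    axis1: str
    axis2: str
    values1: np.ndarray
    values2: np.ndarray
    labels: np.ndarray            # (n1, n2) object array of str
    boundaries: dict = field(default_factory=dict)   # name -> [(a1, a2)]
    overlay: dict = field(default_factory=dict)      # curves from bifurcation
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, v1 in enumerate(self.values1):
            for j, v2 in enumerate(self.values2):
                rows.append({self.axis1: v1, self.axis2: v2,
                             "label": self.labels[i, j]})
        return pd.DataFrame(rows)

    def region_fraction(self, label: str) -> float:
        flat = [x for x in self.labels.ravel() if x != "failed"]
        if not flat:
            return np.nan
        return sum(1 for x in flat if x == label) / len(flat)


def sweep_plane(params: ParameterSet, protocol: PacingProtocol,
                axis1: str, values1: np.ndarray,
                axis2: str, values2: np.ndarray,
                init: np.ndarray | None = None,
                prepace_beats: int = 360, beats_per_point: int = 12,
                refine: bool = True, resolution: float = 0.002,
                dt: float | None = None) -> PhaseDiagram:
    """Classify paced behavior over a 2-D grid of normalized scalings.

    Each line (fixed ``axis1`` value) is traversed along ``axis2`` in the
    given order with chained initial conditions; the first point gets
    ``prepace_beats`` beats, later points ``beats_per_point``.  With
    ``refine``, label transitions along each line are bisected to
    ``resolution``.
    """
    values1 = np.asarray(values1, dtype=float)
    values2 = np.asarray(values2, dtype=float)
    kw = {} if dt is None else {"dt": dt}
    labels = np.empty((len(values1), len(values2)), dtype=object)
    boundaries: dict[str, list] = {}

    def classify_at(ps, state, n_beats):
        prot = make_pacing(protocol.CL, amplitude=protocol.amplitude,
                           width=protocol.width, n_beats=n_beats)
        tr = simulate_paced(ps, prot, init=state, **kw)
        return classify_behavior(ps, prot, tr, dt=dt), tr.y[-1].copy()

    from .simulate import default_initial_state

    for i, v1 in enumerate(values1):
        state = init.copy() if init is not None else None
        line_labels = []
        line_states = []
        for j, v2 in enumerate(values2):
            ps = params.with_scales(**{axis1: float(v1), axis2: float(v2)})
            if state is None:
                state = default_initial_state(ps)
            n = prepace_beats if j == 0 else beats_per_point
            try:
                lab, state = classify_at(ps, state, n)
                labels[i, j] = lab.value
            except IntegrationError:
                labels[i, j] = "failed"
            line_labels.append(labels[i, j])
            line_states.append(None if state is None else state.copy())
        if refine:
            for j in range(1, len(values2)):
                a, b = line_labels[j - 1], line_labels[j]
                if a == b or "failed" in (a, b):
                    continue
                lo, hi = values2[j - 1], values2[j]
                st = line_states[j - 1]
                while abs(hi - lo) > resolution and st is not None:
                    mid = 0.5 * (lo + hi)
                    ps = params.with_scales(**{axis1: float(v1),
                                               axis2: float(mid)})
                    try:
                        lab_m, st = classify_at(ps, st.copy(),
                                                beats_per_point)
                    except IntegrationError:
                        break
                    if lab_m.value == a:
                        lo = mid
                    else:
                        hi = mid
                boundaries.setdefault(f"{a}->{b}", []).append(
                    (float(v1), 0.5 * (lo + hi)))
    return PhaseDiagram(axis1=axis1, axis2=axis2, values1=values1,
                        values2=values2, labels=labels,
                        boundaries=boundaries,
                        provenance={"CL": protocol.CL,
                                    "variant": params.variant,
                                    "prepace_beats": prepace_beats,
                                    "beats_per_point": beats_per_point})


def overlay_bifurcation(diagram: PhaseDiagram, curves: dict,
                        so_region: np.ndarray | None = None) -> PhaseDiagram:
    """Merge non-paced bifurcation curves into a phase diagram.

    ``curves`` maps names (e.g. "HB", "SO1", "SO2") to lists of
    (axis1, axis2) points on the same plane.  When ``so_region`` (boolean
    grid aligned with the diagram) is given, the containment statistic
    ``so_in_RF`` -- the fraction of SO-region grid points labeled RF --
    is stored in the provenance.
    """
    diagram.overlay.update(curves or {})
    if so_region is not None:
        so_region = np.asarray(so_region, dtype=bool)
        if so_region.shape != diagram.labels.shape:
            raise ConfigurationError("so_region grid does not match diagram")
        n_so = int(so_region.sum())
        if n_so:
            n_rf = int(np.sum((diagram.labels == BehaviorLabel.RF.value)
                              & so_region))
            diagram.provenance["so_in_RF"] = n_rf / n_so
    return diagram


def hysteresis_scan(params: ParameterSet, protocol: PacingProtocol,
                    axis: str, values: np.ndarray,
                    prepace_beats: int = 360, beats_per_point: int = 12,
                    dt: float | None = None) -> pd.DataFrame:
    """Label a 1-D scan in both traversal directions; disagreeing points
    are flagged bistable rather than hidden."""
    res = {}
    for direction in ("ascending", "descending"):
        vals = np.sort(np.asarray(values, dtype=float))
        if direction == "descending":
            vals = vals[::-1]
        diag = sweep_plane(params, protocol, axis, np.array([1.0]),
                           axis, vals, prepace_beats=prepace_beats,
                           beats_per_point=beats_per_point, refine=False,
                           dt=dt)
        res[direction] = dict(zip(vals, diag.labels[0]))
    rows = []
    for v in np.sort(np.asarray(values, dtype=float)):
        up, dn = res["ascending"][v], res["descending"][v]
        rows.append({"value": v, "ascending": up, "descending": dn,
                     "bistable": up != dn})
    return pd.DataFrame(rows)
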