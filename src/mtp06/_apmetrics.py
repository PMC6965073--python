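"""Low-level per-beat action-potential metrics on sampled V_m arrays.

Kept free of any simulation imports so both the simulator (for its
beat-to-beat convergence criterion) and the feature-extraction API can
use the same measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

#: V_m below which the cell counts as repolarized to rest (mV)
V_REST_THRESHOLD = -75.0
#: minimum prominence of a plateau oscillation extremum to count as EAD (mV)
EAD_PROMINENCE = 1.0
#: EADs are only counted this long after the AP peak (ms)
EAD_WINDOW_START = 200.0
#: the AP peak is searched within this window after stimulus onset (ms)
PEAK_SEARCH = 50.0


@dataclass
class APFeatures:
    """Per-beat AP features (times in ms relative to the trace clock)."""

    beat: int
    t_stim: float
    V_min: float            # phase-4 minimum preceding the upstroke
    V_peak: float
    t_peak: float
    V_max: float            # early phase-2 (dome) maximum before any EAD
    APD90: float            # nan if repolarization not reached in window
    ead_min: list = field(default_factory=list)
    ead_max: list = field(default_factory=list)
    regular: bool = True

    @property
    def n_eads(self) -> int:
        return len(self.ead_max)

    @property
    def has_ead(self) -> bool:
        return self.n_eads > 0


def _interp_crossing(t, V, i, level):
    """Linear-interpolated time where V crosses ``level`` between i and i+1."""
    dv = V[i + 1] - V[i]
    if dv == 0.0:
        return t[i]
    return t[i] + (level - V[i]) / dv * (t[i + 1] - t[i])


def beat_features(t: np.ndarray, V: np.ndarray, t_stim: float,
                  prev_V_min: float, beat: int = 0,
                  ead_prominence: float = EAD_PROMINENCE,
                  rest_threshold: float = V_REST_THRESHOLD) -> APFeatures:
    """Measure one beat given samples covering [t_stim, next stimulus).

    ``prev_V_min`` is the phase-4 minimum preceding this upstroke (the
    amplitude baseline for APD90).  APD90 is nan when 90% repolarization
    is not reached within the supplied window.
    """
    t = np.asarray(t)
    V = np.asarray(V)
    i0 = int(np.searchsorted(t, t_stim))
    tb = t[i0:]
    Vb = V[i0:]
    if len(tb) < 8:
        raise ValueError("beat window too short")

    in_peak = tb <= t_stim + PEAK_SEARCH
    k_peak = int(np.argmax(Vb[in_peak]))
    V_peak = float(Vb[k_peak])
    t_peak = float(tb[k_peak])

    # upstroke time: maximum dV/dt within 10 ms of the stimulus (the
    # conventional AP-duration start marker)
    in_up = tb <= t_stim + 10.0
    if np.count_nonzero(in_up) >= 3:
        dV = np.gradient(Vb[in_up], tb[in_up])
        t_up = float(tb[in_up][int(np.argmax(dV))])
    else:
        t_up = t_stim

    amp = V_peak - prev_V_min
    V90 = V_peak - 0.9 * amp
    APD90 = math.nan
    below = np.flatnonzero(Vb[k_peak:] < V90)
    if below.size:
        i = k_peak + int(below[0]) - 1
        if i >= k_peak:
            t90 = _interp_crossing(tb, Vb, i, V90)
        else:
            t90 = tb[k_peak]
        APD90 = t90 - t_up

    # EAD extrema: plateau oscillations from t_peak + 200 ms until
    # repolarization to rest (or the end of the window)
    ead_min: list = []
    ead_max: list = []
    w0 = t_peak + EAD_WINDOW_START
    sel = tb >= w0
    if np.count_nonzero(sel) >= 5:
        tw = tb[sel]
        Vw = Vb[sel]
        rep = np.flatnonzero(Vw < rest_threshold)
        if rep.size:
            tw = tw[: rep[0] + 1]
            Vw = Vw[: rep[0] + 1]
        if len(Vw) >= 5:
            pk, _ = find_peaks(Vw, prominence=ead_prominence)
            tr, _ = find_peaks(-Vw, prominence=ead_prominence)
            ead_max = [float(Vw[i]) for i in pk]
            ead_min = [float(Vw[i]) for i in tr]

    # phase-4 minimum of this cycle: minimum after the peak
    V_min = float(np.min(Vb[k_peak:]))

    # early phase-2 (dome) maximum: after the spike/notch, before the EAD
    # window opens
    dome = (tb >= t_peak + 25.0) & (tb <= t_peak + EAD_WINDOW_START)
    V_max = float(np.max(Vb[dome])) if np.count_nonzero(dome) else V_peak

    return APFeatures(beat=beat, t_stim=float(t_stim), V_min=V_min,
                      V_peak=V_peak, t_peak=t_peak, V_max=V_max,
                      APD90=float(APD90), ead_min=ead_min, ead_max=ead_max)


def relative_change(new: float, old: float) -> float:
    """|new - old| / |old| with nan-propagation (nan => not converged)."""
    if math.isnan(new) or math.isnan(old):
        return math.inf
    if old == 0.0:
        return abs(new - old)
    return abs(new - old) / abs(old)
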