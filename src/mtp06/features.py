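"""AP feature extraction, EAD detection, behavior classification, and
critical-parameter searches for the paced cell.

Behavior classes
----------------
``no_EAD``
    Regular APs with monotone plateau repolarization.
``fR`` (fast repolarization)
    APs with EADs whose APD90 stays <= 5 s, repolarizing to rest before
    (or promptly after) the next stimulus.
``RF`` (repolarization failure)
    APs with EADs that do not repolarize within 5 s; discriminated from
    fR by the response to an extra stimulus after the last test stimulus
    (an RF-type AP fails to return to the resting potential within 5 s).
``local_response``
    Arrest at a depolarized stable equilibrium: between stimuli V_m
    never falls below -40 mV and, outside the stimulus deflection and
    its settling window, stays within a 2-mV band (a quiet level rather
    than EAD oscillations).
"""

from __future__ import annotations

import math
from enum import Enum

import numpy as np

from ._apmetrics import (APFeatures, EAD_PROMINENCE, V_REST_THRESHOLD,
                         beat_features)
from .params import ParameterSet
from .protocols import PacingProtocol, make_pacing
from .simulate import Trace, integrate, simulate_paced

#: fR/RF discrimination threshold on APD90 (ms)
FR_APD_LIMIT = 5000.0
#: local-response thresholds: inter-stimulus V_m floor (mV), width of the
#: "quiet" band outside stimulus deflections (mV), and the post-stimulus
#: settling window excluded from the quiet check (ms)
LOCAL_DIASTOLIC_FLOOR = -40.0
LOCAL_QUIET_BAND_MV = 2.0
LOCAL_SETTLE_MS = 500.0


class BehaviorLabel(str, Enum):
    no_EAD = "no_EAD"
    fR = "fR"
    RF = "RF"
    local_response = "local_response"


def extract_ap_features(trace: Trace, protocol: PacingProtocol | None = None,
                        ead_prominence: float = EAD_PROMINENCE) -> list[APFeatures]:
    """Per-stimulus AP features for the sampled beats of a paced trace.

    Features are recomputed from the stored samples (the simulator's own
    per-beat features cover the full run; this covers the kept window and
    honors a custom EAD prominence).
    """
    protocol = protocol or trace.protocol
    if protocol is None or trace.stim_times is None:
        raise ValueError("trace carries no pacing protocol")
    CL = protocol.CL
    t0_first = trace.t[0]
    out = []
    prev_V_min = float(trace.V[0])
    for ts in trace.stim_times:
        if ts < t0_first or ts + CL > trace.t[-1] + 1e-9:
            continue
        sel = (trace.t >= ts) & (trace.t < ts + CL)
        if np.count_nonzero(sel) < 8:
            continue
        beat = int(round(ts / CL))
        f = beat_features(trace.t[sel], trace.V[sel], ts, prev_V_min,
                          beat=beat, ead_prominence=ead_prominence)
        prev_V_min = f.V_min
        out.append(f)
    if not out:
        raise ValueError("trace too short: no complete beat window sampled")
    return out


def _is_local_response(trace: Trace, protocol: PacingProtocol) -> bool:
    """Arrest at the depolarized stable equilibrium: V_m never returns
    toward rest between stimuli and, apart from the stimulus artifact,
    sits quietly (no EAD-scale oscillation) near one level."""
    n_last = min(10, trace.n_beats)
    t_start = trace.stim_times[trace.n_beats - n_last]
    sel = trace.t >= t_start
    t = trace.t[sel]
    V = trace.V[sel]
    if V.min() <= LOCAL_DIASTOLIC_FLOOR:
        return False
    # mask out the stimulus deflection and its relaxation
    quiet = np.ones(len(t), dtype=bool)
    for ts in trace.stim_times[trace.n_beats - n_last:]:
        quiet &= ~((t >= ts) & (t < ts + LOCAL_SETTLE_MS))
    if quiet.sum() < 10:
        return False
    return float(V[quiet].max() - V[quiet].min()) < LOCAL_QUIET_BAND_MV


def _extra_stimulus_repolarizes(params: ParameterSet, protocol: PacingProtocol,
                                state: np.ndarray, within_ms: float = 5000.0,
                                dt: float | None = None) -> bool:
    """Apply one extra stimulus and test repolarization to rest within 5 s."""
    kw = {} if dt is None else {"dt": dt}
    tr1 = integrate(params, state, protocol.width, stim=protocol.amplitude, **kw)
    tr2 = integrate(params, tr1.y[-1], within_ms, stim=0.0, **kw)
    return bool(np.any(tr2.V < V_REST_THRESHOLD))


def classify_behavior(params: ParameterSet, protocol: PacingProtocol,
                      trace: Trace, dt: float | None = None) -> BehaviorLabel:
    """Classify the steady paced behavior of a completed run.

    Uses the features of the last 10 stimuli.  The fR/RF split follows
    the extra-stimulus test: when the final AP has not repolarized
    (APD90 > 5 s or unresolved), one extra stimulus is delivered from the
    end state; repolarization to the resting potential within 5 s means
    fR, otherwise RF.
    """
    if _is_local_response(trace, protocol):
        return BehaviorLabel.local_response
    feats = trace.features[-10:]
    last = feats[-1]
    # did the final AP reach the resting potential before the next
    # stimulus was due?
    t_tail = trace.stim_times[-1] + 0.05 * protocol.CL
    rested = bool(np.any(trace.V[trace.t >= t_tail] < V_REST_THRESHOLD))
    if not any(f.has_ead for f in feats):
        if math.isnan(last.APD90) or last.APD90 > FR_APD_LIMIT \
                or not rested:
            if not _extra_stimulus_repolarizes(params, protocol,
                                               trace.y[-1], dt=dt):
                return BehaviorLabel.RF
        return BehaviorLabel.no_EAD
    # fR requires BOTH a short AP duration and repolarization to rest;
    # an AP that is only terminated by the next stimulus (APD90
    # unresolved within its cycle) is repolarization failure
    if not math.isnan(last.APD90) and last.APD90 <= FR_APD_LIMIT and rested:
        return BehaviorLabel.fR
    if not math.isnan(last.APD90) and last.APD90 <= FR_APD_LIMIT \
            and _extra_stimulus_repolarizes(params, protocol, trace.y[-1],
                                            dt=dt):
        return BehaviorLabel.fR
    return BehaviorLabel.RF


def paced_behavior(params: ParameterSet, protocol: PacingProtocol,
                   init: np.ndarray | None = None,
                   n_beats: int | None = None,
                   dt: float | None = None) -> tuple[BehaviorLabel, Trace]:
    """Simulate and classify in one step; returns (label, trace)."""
    prot = protocol if n_beats is None else make_pacing(
        protocol.CL, amplitude=protocol.amplitude, width=protocol.width,
        n_beats=n_beats)
    kw = {} if dt is None else {"dt": dt}
    tr = simulate_paced(params, prot, init=init, **kw)
    return classify_behavior(params, prot, tr, dt=dt), tr


def find_critical_parameter(params: ParameterSet, protocol: PacingProtocol,
                            axis: str, bracket: tuple[float, float],
                            resolution: float = 0.001,
                            beats_per_point: int = 12,
                            prepace_beats: int = 360,
                            predicate=None,
                            init: np.ndarray | None = None,
                            dt: float | None = None,
                            return_states: bool = False):
    """Bisect the critical normalized value of ``axis`` where the paced
    behavior switches (by default: EAD emergence).

    Mirrors the scan protocol of the source analyses: the cell is paced
    to (near-)steady state at the bracket's first endpoint, then each
    bisection point is evaluated with ``beats_per_point`` warm-started
    beats and classified on its last 10 stimuli.  Warm starts inherit
    the last state computed on the bracket-*start* side, mirroring the
    direction of the underlying parameter sweeps (results can be
    direction-dependent; scan the other way to probe hysteresis).
    ``predicate`` maps a Trace to bool (default: any EAD among the last
    10 beats); bracket endpoints must disagree.
    """
    if predicate is None:
        def predicate(tr):
            return any(f.has_ead for f in tr.features[-10:])

    a, b = bracket
    kw = {} if dt is None else {"dt": dt}

    ps_a = params.with_scales(**{axis: a})
    if init is None:
        from .constants import DEFAULT_INITIAL_STATE
        rest = integrate(ps_a, DEFAULT_INITIAL_STATE, 120_000.0,
                         out_step=100.0, **kw)
        init = rest.y[-1]
    prot_pre = make_pacing(protocol.CL, amplitude=protocol.amplitude,
                           width=protocol.width, n_beats=prepace_beats)
    tr_a = simulate_paced(ps_a, prot_pre, init=init, **kw)
    state_a = tr_a.y[-1].copy()

    prot_pt = make_pacing(protocol.CL, amplitude=protocol.amplitude,
                          width=protocol.width, n_beats=beats_per_point)

    def evaluate(x, warm_state):
        ps_x = params.with_scales(**{axis: x})
        tr = simulate_paced(ps_x, prot_pt, init=warm_state.copy(), **kw)
        return predicate(tr), tr.y[-1].copy()

    flag_a, state_a = predicate(tr_a), state_a
    flag_b, state_b = evaluate(b, state_a)
    if flag_a == flag_b:
        raise ValueError(
            f"bracket endpoints classify identically ({axis}: {a} and {b})")

    lo, hi = a, b
    state_lo, state_hi = state_a, state_b
    while abs(hi - lo) > resolution:
        mid = 0.5 * (lo + hi)
        # inherit the state from the bracket-start side (scan direction)
        warm = state_lo
        flag_mid, state_mid = evaluate(mid, warm)
        if flag_mid == flag_a:
            lo, state_lo = mid, state_mid
        else:
            hi, state_hi = mid, state_mid
    critical = 0.5 * (lo + hi)
    if return_states:
        return critical, {"lo": (lo, state_lo), "hi": (hi, state_hi)}
    return critical


def first_ead_stimulus_index(params: ParameterSet, CL_pre: float,
                             CL_post: float,
                             init: np.ndarray | None = None,
                             prepace_beats: int | None = None,
                             max_stimuli: int = 600,
                             dt: float | None = None) -> int | None:
    """Index (1-based) of the first post-switch stimulus whose AP carries
    an EAD after an abrupt pacing cycle-length change.

    The cell is paced at ``CL_pre`` for ``prepace_beats`` beats (default:
    30 simulated minutes) starting from ``init`` (default: the model's
    resting state), then the cycle length switches to ``CL_post``.
    Returns None when no EAD occurs within ``max_stimuli`` stimuli.
    """
    kw = {} if dt is None else {"dt": dt}
    if prepace_beats is None:
        prepace_beats = int(1.8e6 // CL_pre)
    tr_pre = simulate_paced(params, make_pacing(CL_pre, n_beats=prepace_beats),
                            init=init, **kw)
    if CL_post == CL_pre:
        return None
    tr = simulate_paced(params, make_pacing(CL_post, n_beats=max_stimuli),
                        init=tr_pre.y[-1], **kw)
    for f in tr.features:
        if f.has_ead:
            return f.beat + 1
    return None
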