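"""Voltage clamp: schedule exactness and SR-release event detection."""

import numpy as np
import pytest

import mtp06 as m
from mtp06.simulate import Trace
from mtp06.vclamp import (clamped_params, detect_release_events,
                          holding_steady_state, simulate_clamped,
                          spontaneous_events)
from tests.conftest import DT_TEST


@pytest.fixture(scope="module")
def short_train():
    ps = m.build_parameters("mTP06b")
    prot = m.make_clamp(train_ms=20_000.0)
    tr = simulate_clamped(ps, prot, dt=DT_TEST,
                          init=holding_steady_state(ps, relax_ms=20_000.0))
    return ps, prot, tr


def test_clamped_vm_follows_schedule_exactly(short_train):
    ps, prot, tr = short_train
    # V_m equals the protocol value at every sample, bit-exactly
    for onset in tr.stim_times:
        during = (tr.t > onset) & (tr.t < onset + prot.pulse_ms)
        assert np.all(tr.V[during] == prot.V_test)
        after = (tr.t > onset + prot.pulse_ms) & (tr.t < onset + prot.period_ms)
        assert np.all(tr.V[after] == prot.V_hold)
    assert len(tr.stim_times) == prot.n_pulses()


def test_pulses_load_the_sr(short_train):
    ps, prot, tr = short_train
    assert tr["CaSR"][-1] > tr["CaSR"][0]
    assert tr["Cass"].max() > 10 * tr["Cass"].min()


def _synthetic_casr_trace(drops):
    """Constant Ca_SR = 3 mM with injected linear drops; Ca_i mirrors."""
    t = np.arange(0.0, 60_000.0, 5.0)
    casr = np.full_like(t, 3.0)
    cai = np.full_like(t, 1e-4)
    for onset, frac, dur in drops:
        sel = (t >= onset) & (t < onset + dur)
        ramp = np.linspace(0.0, frac * 3.0, sel.sum())
        casr[sel] -= ramp
        casr[t >= onset + dur] -= frac * 3.0
        cai[sel] += np.linspace(0.0, 5e-4, sel.sum())
    y = np.zeros((len(t), m.N_STATE))
    y[:, m.IDX["CaSR"]] = casr
    y[:, m.IDX["Cai"]] = cai
    y[:, m.IDX["Cass"]] = cai
    return Trace(t=t, y=y, params=m.build_parameters("mTP06b"),
                 stim_times=np.array([]))


def test_single_injected_drop_detected_once():
    tr = _synthetic_casr_trace([(20_000.0, 0.10, 50.0)])
    ev = detect_release_events(tr)
    assert len(ev) == 1
    assert ev[0].onset == pytest.approx(20_000.0, abs=200.0)
    assert ev[0].casr_drop_frac == pytest.approx(0.10, abs=0.02)
    assert not ev[0].pulse_triggered


def test_constant_casr_yields_no_events():
    tr = _synthetic_casr_trace([])
    assert detect_release_events(tr) == []


def test_slow_drop_below_rate_threshold_ignored():
    # 4% drop over 100 ms stays under the 5%-per-window default
    tr = _synthetic_casr_trace([(20_000.0, 0.04, 100.0)])
    assert detect_release_events(tr) == []


def test_pulse_coincident_events_flagged():
    tr = _synthetic_casr_trace([(20_010.0, 0.10, 50.0)])
    tr.stim_times = np.array([20_000.0])
    ev = detect_release_events(tr)
    assert len(ev) == 1 and ev[0].pulse_triggered
    assert spontaneous_events(ev) == []


def test_hb_locus_interval_widens_with_pup():
    """The unstable clamped-V_m interval of the Ca subsystem widens as
    P_up increases (coarse scan)."""
    from mtp06.vclamp import hb_locus
    ps = m.build_parameters("mTP06b")
    df = hb_locus(ps, "scale_Pup", np.array([1.0, 2.0]),
                  V_bracket=(-60.0, 10.0), coarse_n=15, relax_ms=20_000.0,
                  hb_tol=2.0)
    w = (df["V_high"] - df["V_low"]).to_numpy()
    assert np.all(np.isfinite(w)), f"missing instability interval: {df}"
    assert w[1] > w[0], f"interval must widen with P_up: {df}"


def test_pup_zero_depletes_sr_without_release(ps_b):
    ps = m.build_parameters("mTP06b").with_scales(scale_Pup=0.0)
    prot = m.make_clamp(train_ms=10_000.0)
    y0 = holding_steady_state(m.build_parameters("mTP06b"),
                              relax_ms=10_000.0)
    tr = simulate_clamped(ps, prot, init=y0, dt=DT_TEST)
    casr = tr["CaSR"]
    assert np.all(np.diff(casr) <= 1e-12)
    assert spontaneous_events(detect_release_events(tr)) == []
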