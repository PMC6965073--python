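"""Integration layer: traces, pacing, convergence, clamp exactness."""

import numpy as np
import pytest
from dataclasses import replace

import mtp06 as m
from tests.conftest import DT_TEST


def test_trace_time_strictly_increasing(paced_beat_b):
    assert np.all(np.diff(paced_beat_b.t) > 0)
    # output step resolves 1-ms stimuli
    assert np.max(np.diff(paced_beat_b.t)) <= 0.5 + 1e-9


def test_zero_amplitude_pacing_is_quiescent(ps_b, rest_state_b):
    prot = m.make_pacing(2000.0, amplitude=0.0, n_beats=3)
    tr = m.simulate_paced(ps_b, prot, init=rest_state_b, dt=DT_TEST)
    assert np.max(np.abs(tr.V - tr.V[0])) < 1.0


def test_paced_run_reports_features_per_beat(paced_beat_b):
    assert paced_beat_b.n_beats == 5
    assert len(paced_beat_b.features) == 5
    f = paced_beat_b.features[-1]
    assert f.V_peak > 0 > f.V_min
    assert 200 < f.APD90 < 600
    assert f.V_max > f.V_min


def test_convergence_criterion_idempotent(ps_b, rest_state_b):
    """Re-running from a converged state must re-report convergence
    within a couple of beats."""
    tr1 = m.simulate_paced(ps_b, m.make_pacing(1000.0), init=rest_state_b,
                           max_duration=120_000.0, dt=DT_TEST)
    tr2 = m.simulate_paced(ps_b, m.make_pacing(1000.0), init=tr1.y[-1],
                           max_duration=60_000.0, dt=DT_TEST)
    assert tr2.converged
    assert tr2.n_beats <= 3


def test_rush_larsen_agrees_with_lsoda_reference(ps_b, rest_state_b):
    """One paced beat: fixed-step hybrid integration tracks the adaptive
    LSODA reference (rtol 1e-8) to sub-millivolt accuracy away from the
    upstroke."""
    prot = m.make_pacing(1000.0, n_beats=1)
    tr = m.simulate_paced(ps_b, prot, init=rest_state_b, dt=0.01)
    t_eval = np.arange(1.0, 999.0, 1.0)   # absolute time since stimulus on
    ref1 = m.integrate_lsoda(ps_b, rest_state_b, 1.0, stim=60.0)
    ref = m.integrate_lsoda(ps_b, ref1.y[-1], 998.0)
    V_rl = np.interp(t_eval, tr.t, tr.V)
    V_ref = np.interp(t_eval, ref.t + 1.0, ref.y[:, 0])
    sel = t_eval > 10.0   # skip the upstroke's steep phase
    assert np.max(np.abs(V_rl[sel] - V_ref[sel])) < 1.0


def test_halving_dt_changes_apd_below_half_ms(ps_b, rest_state_b):
    apd = {}
    for dt in (0.02, 0.01):
        tr = m.simulate_paced(ps_b, m.make_pacing(1000.0, n_beats=3),
                              init=rest_state_b, dt=dt)
        apd[dt] = tr.features[-1].APD90
    assert abs(apd[0.02] - apd[0.01]) < 0.5


def test_trace_frame_and_csv_roundtrip(tmp_path, paced_beat_b):
    df = paced_beat_b.to_frame()
    assert list(df.columns) == ["t", "V", "Cai", "Cass", "CaSR", "Nai", "Ki"]
    path = tmp_path / "trace.csv"
    paced_beat_b.to_csv(path)
    import pandas as pd
    back = pd.read_csv(path)
    assert np.allclose(back["V"], df["V"])
    ff = paced_beat_b.features_frame()
    assert len(ff) == paced_beat_b.n_beats


def test_integration_error_carries_last_state(ps_b):
    bad = m.DEFAULT_INITIAL_STATE.copy()
    bad[m.IDX["CaSR"]] = -5.0   # unphysical; integration blows up
    with pytest.raises(Exception):
        m.integrate(ps_b, bad, 1000.0, dt=DT_TEST)
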