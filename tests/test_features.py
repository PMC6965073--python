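"""EAD detection and classification on constructed signals and on
short model runs."""

import numpy as np
import pytest

import mtp06 as m
from mtp06._apmetrics import beat_features
from mtp06.features import BehaviorLabel
from tests.conftest import DT_TEST


def _synthetic_ap(t, apd=400.0, v_rest=-85.0, v_peak=40.0, n_osc=0,
                  osc_amp=5.0, osc_t0=250.0, osc_period=120.0):
    """Idealized AP: fast upstroke, plateau with optional superimposed
    damped oscillations, exponential repolarization after ``apd``."""
    V = np.full_like(t, v_rest)
    up = t >= 2.0
    V[up] = v_peak - (v_peak - 0.6 * v_peak) * (1 - np.exp(-(t[up] - 2) / 3))
    plateau = v_peak * 0.6
    rep = t > apd
    V[up & ~rep] = plateau + (v_peak - plateau) * np.exp(-(t[up & ~rep] - 2) / 40.0)
    V[rep] = v_rest + (plateau - v_rest) * np.exp(-(t[rep] - apd) / 25.0)
    if n_osc:
        osc = np.zeros_like(t)
        win = (t >= osc_t0) & (t <= osc_t0 + n_osc * osc_period)
        osc[win] = osc_amp * np.sin(
            2 * np.pi * (t[win] - osc_t0) / osc_period - np.pi / 2) + osc_amp
        V = V + osc
    return V


def test_monotone_repolarization_has_no_ead():
    t = np.arange(0.0, 2000.0, 0.5)
    V = _synthetic_ap(t, apd=400.0)
    f = beat_features(t, V, 0.0, -85.0)
    assert f.ead_max == [] and f.ead_min == []
    # closed form: plateau 24 mV decays to -85 with tau 25 ms from t=400;
    # V90 = 40 - 0.9*(40+85) = -72.5 crossed at 400 + 25*ln(109/12.5)
    t90_expected = 400.0 + 25.0 * np.log((24.0 + 85.0) / (85.0 - 72.5))
    assert f.APD90 == pytest.approx(t90_expected, abs=5.0)


def test_three_plateau_oscillations_detected_as_three_eads():
    """Constructed-signal oracle: a plateau carrying three 5-mV damped
    oscillations at t > 200 ms must yield exactly three EAD maxima."""
    t = np.arange(0.0, 2000.0, 0.5)
    V = _synthetic_ap(t, apd=800.0, n_osc=3, osc_amp=5.0, osc_t0=280.0)
    f = beat_features(t, V, 0.0, -85.0)
    assert len(f.ead_max) == 3


def test_oscillations_before_200ms_window_are_ignored():
    t = np.arange(0.0, 2000.0, 0.5)
    V = _synthetic_ap(t, apd=700.0, n_osc=2, osc_amp=6.0, osc_t0=60.0,
                      osc_period=60.0)
    f = beat_features(t, V, 0.0, -85.0)
    assert len(f.ead_max) == 0


def test_subthreshold_ripple_not_counted():
    t = np.arange(0.0, 2000.0, 0.5)
    V = _synthetic_ap(t, apd=800.0, n_osc=3, osc_amp=0.3, osc_t0=280.0)
    f = beat_features(t, V, 0.0, -85.0)
    assert f.ead_max == []


def test_extract_features_from_model_trace(ead_trace_b):
    ps, prot, tr = ead_trace_b
    feats = m.extract_ap_features(tr, prot)
    assert len(feats) >= 1
    assert any(f.has_ead for f in feats), \
        "g_Kr-reduced mTP06b at 0.2 Hz should exhibit EADs"
    for f in feats:
        assert f.V_peak > f.V_max > f.V_min
        for lo, hi in zip(f.ead_min, f.ead_max):
            assert f.V_min < lo < f.V_peak and f.V_min < hi < f.V_peak


def test_classification_no_ead_for_control(ps_b, rest_state_b):
    label, tr = m.paced_behavior(ps_b, m.make_pacing(2000.0, n_beats=8),
                                 init=rest_state_b, dt=DT_TEST)
    assert label is BehaviorLabel.no_EAD


def test_classification_ead_types(ead_trace_b):
    ps, prot, tr = ead_trace_b
    label = m.classify_behavior(ps, prot, tr, dt=DT_TEST)
    assert label in (BehaviorLabel.fR, BehaviorLabel.RF)
    # fR/RF consistency: fR-labeled runs repolarize within the APD limit
    last = tr.features[-1]
    if label is BehaviorLabel.fR and not np.isnan(last.APD90):
        assert last.APD90 <= 5000.0


def test_critical_parameter_requires_disagreeing_bracket(ps_b, rest_state_b):
    with pytest.raises(ValueError, match="identically"):
        m.find_critical_parameter(
            ps_b, m.make_pacing(5000.0), "scale_gKr", (1.0, 0.95),
            prepace_beats=3, beats_per_point=3, init=rest_state_b,
            dt=DT_TEST)


def test_first_ead_index_none_without_cl_change(ps_b, rest_state_b):
    idx = m.first_ead_stimulus_index(ps_b, 1000.0, 1000.0,
                                     init=rest_state_b, prepace_beats=3,
                                     dt=DT_TEST)
    assert idx is None
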