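"""Parameter sets, variant presets, and normalized-scaling semantics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mtp06 as m
from mtp06.constants import P_IDX
from mtp06.params import VARIANT_PRESETS


def test_variant_presets_match_published_scalings():
    a = m.build_parameters("mTP06a")
    assert (a.scale_gKs, a.scale_gKr, a.scale_Pup) == (0.4, 1.5, 0.6)
    assert a.scale_gCaL == 1.0 and a.scale_tau_fL == 1.0
    b = m.build_parameters("mTP06b")
    assert (b.scale_gKs, b.scale_gKr, b.scale_Pup) == (0.4, 1.5, 0.6)
    assert (b.scale_tau_fL, b.scale_gCaL) == (0.5, 2.0)
    o = m.build_parameters("original")
    assert all(getattr(o, f) == 1.0 for f in
               ("scale_gKs", "scale_gKr", "scale_gCaL", "scale_Pup",
                "scale_NCX", "scale_tau_fL"))


def test_normalized_override_multiplies_variant_preset():
    # a normalized g_Kr of 0.4 in mTP06b means 1.5 * 0.4 in absolute terms
    ps = m.build_parameters("mTP06b", {"scale_gKr": 0.4})
    assert ps.scale_gKr == pytest.approx(1.5 * 0.4)
    assert ps.normalized("scale_gKr") == pytest.approx(0.4)
    # overrides compose multiplicatively via with_scales
    ps2 = ps.with_scales(scale_gKr=0.5)
    assert ps2.scale_gKr == pytest.approx(1.5 * 0.5)


def test_kernel_vector_applies_scalings():
    ps = m.build_parameters("mTP06b", {"scale_gKr": 0.5, "scale_Pup": 2.0})
    p = ps.kernel_p()
    p0 = m.build_parameters("original").kernel_p()
    assert p[P_IDX["gKr"]] == pytest.approx(p0[P_IDX["gKr"]] * 1.5 * 0.5)
    assert p[P_IDX["Pup"]] == pytest.approx(p0[P_IDX["Pup"]] * 0.6 * 2.0)
    assert p[P_IDX["tauf_scale"]] == pytest.approx(0.5)
    assert p[P_IDX["tauf2_scale"]] == pytest.approx(0.5)


def test_unknown_variant_and_override_rejected():
    with pytest.raises(m.ConfigurationError):
        m.build_parameters("TP07")
    with pytest.raises(m.ConfigurationError):
        m.build_parameters("mTP06b", {"scale_gBanana": 2.0})
    with pytest.raises(m.ConfigurationError):
        m.ParameterSet(scale_gKr=-0.5)


def test_clamp_flags_shape_mask_and_state():
    ps = m.ParameterSet(variant="mTP06b", fix_Ki=True, fix_Nai=True,
                        clamp_Vm=True, Vm_value=-40.0,
                        **VARIANT_PRESETS["mTP06b"])
    mask = ps.kernel_mask()
    assert mask[m.IDX["V"]] == 1.0 and mask[m.IDX["Nai"]] == 1.0 \
        and mask[m.IDX["Ki"]] == 1.0
    assert mask.sum() == 3
    y = ps.apply_clamps(m.DEFAULT_INITIAL_STATE)
    assert y[m.IDX["V"]] == -40.0
    assert y[m.IDX["Nai"]] == 6.0 and y[m.IDX["Ki"]] == 140.0
    assert len(ps.free_indices()) == m.N_STATE - 3


def test_yaml_roundtrip(tmp_path):
    ps = m.build_parameters("mTP06b", {"scale_gKr": 0.721}, fix_Ki=True)
    path = tmp_path / "ps.yaml"
    ps.to_yaml(path)
    ps2 = m.ParameterSet.from_yaml(path)
    assert ps2 == ps


@settings(max_examples=25, deadline=None)
@given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
def test_with_scales_composes_with_preset(gkr, gcal):
    ps = m.build_parameters("mTP06b").with_scales(scale_gKr=gkr,
                                                  scale_gCaL=gcal)
    assert ps.scale_gKr == pytest.approx(1.5 * gkr)
    assert ps.scale_gCaL == pytest.approx(2.0 * gcal)
    assert ps.normalized("scale_gKr") == pytest.approx(gkr)
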