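"""Slow-fast decompositions: reduction consistency and spec handling."""

import numpy as np
import pytest
from dataclasses import replace

import mtp06 as m
from mtp06.params import ConfigurationError
from mtp06.slowfast import (FastSubsystemSpec, build_fast_subsystem,
                            _fast_state, steady_state_xs2_curve)


def test_spec_validation():
    with pytest.raises(ConfigurationError):
        FastSubsystemSpec(axis="xs2")            # needs CaSR
    with pytest.raises(ConfigurationError):
        FastSubsystemSpec(axis="CaSR")           # needs Vm
    with pytest.raises(ConfigurationError):
        FastSubsystemSpec(axis="banana", CaSR=1.0)


def test_frozen_and_free_sets_partition_state():
    ps = m.build_parameters("mTP06b")
    spec = FastSubsystemSpec(axis="xs2", CaSR=1.5)
    ps_fast = build_fast_subsystem(spec, ps)
    mask = ps_fast.kernel_mask()
    frozen = {m.STATE_NAMES[i] for i in np.flatnonzero(mask)}
    assert frozen == {"xs", "Nai", "CaSR", "Ki"}
    assert len(ps_fast.free_indices()) + len(frozen) == m.N_STATE


def test_casr_decomposition_frees_only_ca_subsystem():
    ps = m.build_parameters("mTP06b")
    spec = FastSubsystemSpec(axis="CaSR", Vm=-10.0)
    ps_fast = build_fast_subsystem(spec, ps)
    free = {m.STATE_NAMES[i] for i in ps_fast.free_indices()}
    assert free == {"fCass", "Rbar", "Cass", "Cai"}


def test_reduced_rhs_equals_full_rhs_on_free_variables():
    """Consistency oracle: the reduced RHS must equal the full RHS
    restricted to free variables, for many states."""
    ps = m.build_parameters("mTP06b", {"scale_gKr": 0.6})
    spec = FastSubsystemSpec(axis="xs2", CaSR=1.5)
    ps_fast = build_fast_subsystem(spec, ps)
    free = ps_fast.free_indices()
    rng = np.random.default_rng(7)
    base = m.DEFAULT_INITIAL_STATE
    for _ in range(50):
        y = base * rng.uniform(0.8, 1.2, size=base.shape)
        y[0] = rng.uniform(-90.0, 30.0)
        y[1:14] = np.clip(y[1:14], 0.0, 1.0)
        y = _fast_state(spec, ps, axis_value=0.04, template=y)
        full = m.rhs(0.0, y, ps)
        red = m.rhs(0.0, y, ps_fast)
        assert np.allclose(red[free], full[free], rtol=0, atol=1e-12)
        frozen = np.setdiff1d(np.arange(m.N_STATE), free)
        assert np.all(red[frozen] == 0.0)


def test_xs2_zero_silences_iks():
    ps = m.build_parameters("mTP06b")
    spec = FastSubsystemSpec(axis="xs2", CaSR=1.5)
    y = _fast_state(spec, ps, axis_value=0.0,
                    template=m.DEFAULT_INITIAL_STATE)
    assert m.compute_currents(y, ps)["I_Ks"] == 0.0
    y2 = _fast_state(spec, ps, axis_value=0.25,
                     template=m.DEFAULT_INITIAL_STATE)
    assert y2[m.IDX["xs"]] == pytest.approx(0.5)


def test_steady_state_xs2_curve_monotone():
    ps = m.build_parameters("mTP06b")
    df = steady_state_xs2_curve(ps, np.linspace(-80.0, 20.0, 11))
    assert np.all(np.diff(df["xs2"]) > 0)
    assert df["xs2"].iloc[0] < 1e-3


def test_conflicting_clamp_rejected():
    ps = replace(m.build_parameters("mTP06b"), clamp_Vm=True, Vm_value=-20.0)
    spec = FastSubsystemSpec(axis="CaSR", Vm=-10.0)
    with pytest.raises(ConfigurationError):
        build_fast_subsystem(spec, ps)


def test_decomposition_fidelity_at_full_equilibrium():
    """Freezing the slow variables at a full-system EP's values makes the
    reduced system's EP coincide with the full EP on free components."""
    from mtp06 import bifurcation as bif
    ps = m.build_parameters("mTP06b", {"scale_gKr": 0.7}, fix_Ki=True)
    eps = bif.find_equilibria(ps, v_seeds=np.array([-90.0]),
                              relax_ms=10_000.0)
    ep = eps[0]
    spec = FastSubsystemSpec(axis="xs2", Nai=ep.state[m.IDX["Nai"]],
                             CaSR=ep.state[m.IDX["CaSR"]])
    ps_fast = build_fast_subsystem(spec, ps)
    red_ep = bif.refine_equilibrium(ep.state, ps_fast)
    assert red_ep is not None
    free = ps_fast.free_indices()
    assert np.allclose(red_ep.state[free], ep.state[free],
                       rtol=0, atol=1e-8 * bif.STATE_SCALE[free].max())
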