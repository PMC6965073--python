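"""Model equations: current bookkeeping, clamps, steady-state initials,
and trajectory invariants."""

import numpy as np
import pytest
from dataclasses import replace

import mtp06 as m
from mtp06.model import NumericsError
from tests.conftest import DT_TEST


def test_dvdt_equals_stim_minus_current_sum(ps_b, rest_state_b):
    """dV/dt from the RHS must equal stim - sum of the 12 sarcolemmal
    currents computed by compute_currents (same expressions)."""
    for stim in (0.0, 60.0):
        dy = m.rhs(0.0, rest_state_b, ps_b, stim=stim)
        cur = m.compute_currents(rest_state_b, ps_b)
        total = sum(cur[k] for k in ("I_Na", "I_CaL", "I_Kr", "I_Ks", "I_to",
                                     "I_K1", "I_NCX", "I_NaK", "I_pCa",
                                     "I_pK", "I_bNa", "I_bCa"))
        assert dy[m.IDX["V"]] == pytest.approx(stim - total, abs=1e-12)


def test_zero_conductance_kills_current(rest_state_b):
    ps = m.build_parameters("mTP06b").with_scales(scale_gKs=0.0)
    assert m.compute_currents(rest_state_b, ps)["I_Ks"] == 0.0


def test_ncx_reverses_sign_once_on_voltage_sweep(ps_b, rest_state_b):
    """Brute-force V_m sweep at fixed concentrations: I_NCX changes sign
    exactly once (its reversal potential)."""
    signs = []
    for V in np.linspace(-90.0, 60.0, 301):
        y = rest_state_b.copy()
        y[m.IDX["V"]] = V
        signs.append(np.sign(m.compute_currents(y, ps_b)["I_NCX"]))
    flips = np.count_nonzero(np.diff(signs))
    assert flips == 1


def test_rhs_rejects_nonfinite_state(ps_b, rest_state_b):
    y = rest_state_b.copy()
    y[m.IDX["Cai"]] = np.nan
    with pytest.raises(NumericsError, match="Cai"):
        m.rhs(0.0, y, ps_b)


def test_clamped_entries_have_zero_derivative(rest_state_b):
    ps = replace(m.build_parameters("mTP06b"), clamp_Vm=True,
                 Vm_value=-50.0, fix_Ki=True, fix_Nai=True)
    dy = m.rhs(0.0, ps.apply_clamps(rest_state_b), ps, stim=60.0)
    assert dy[m.IDX["V"]] == 0.0
    assert dy[m.IDX["Ki"]] == 0.0
    assert dy[m.IDX["Nai"]] == 0.0


def test_steady_state_initials_gates_bounded_and_quiescent(ps_b):
    y = m.steady_state_initials(-85.0, ps_b)
    assert np.all(y[1:14] >= 0.0) and np.all(y[1:14] <= 1.0)
    # unstimulated integration stays near rest (slow drift only)
    tr = m.integrate(ps_b, y, 60_000.0, out_step=500.0, dt=DT_TEST)
    assert abs(tr.V[-1] - tr.V[0]) < 2.0
    with pytest.raises(ValueError):
        m.steady_state_initials(-40.0, ps_b)


def test_xs_steady_state_is_sigmoid_in_v(ps_b):
    xs = [m.gate_steady_state(V, ps_b)[m.IDX["xs"] - 1]
          for V in (-85.0, -20.0, 40.0)]
    assert xs[0] < xs[1] < xs[2]
    assert xs[0] < 0.01 and xs[2] > 0.9


def test_trajectory_keeps_gates_bounded_and_concentrations_positive(
        paced_beat_b):
    y = paced_beat_b.y
    gates = y[:, 1:14]
    assert gates.min() >= -1e-9 and gates.max() <= 1.0 + 1e-9
    conc = y[:, [m.IDX["Cai"], m.IDX["Cass"], m.IDX["CaSR"],
                 m.IDX["Nai"], m.IDX["Ki"]]]
    assert conc.min() > 0.0


def test_variant_equivalence_mtp06b_reduces_to_mtp06a(rest_state_b):
    """mTP06b with tau_fL and g_CaL overrides reset to the mTP06a values
    reproduces mTP06a trajectories bit-identically."""
    ps_b = replace(m.build_parameters("mTP06b"),
                   scale_tau_fL=1.0, scale_gCaL=1.0)
    ps_a = m.build_parameters("mTP06a")
    assert np.array_equal(ps_b.kernel_p(), ps_a.kernel_p())
    tr_b = m.simulate_paced(ps_b, m.make_pacing(1000.0, n_beats=2),
                            init=rest_state_b, dt=DT_TEST)
    tr_a = m.simulate_paced(ps_a, m.make_pacing(1000.0, n_beats=2),
                            init=rest_state_b, dt=DT_TEST)
    assert np.array_equal(tr_b.y, tr_a.y)


def test_fixed_ki_constant_along_trajectory(rest_state_b):
    ps = replace(m.build_parameters("mTP06b"), fix_Ki=True, fix_Nai=True)
    tr = m.simulate_paced(ps, m.make_pacing(1000.0, n_beats=2),
                          init=rest_state_b, dt=DT_TEST)
    assert np.all(tr["Ki"] == 140.0)
    assert np.all(tr["Nai"] == 6.0)
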