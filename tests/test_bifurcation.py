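"""Equilibria, stability, and the eigenvalue/simulation consistency of
the non-paced (K_i-fixed) cell."""

import numpy as np
import pytest
from dataclasses import replace

import mtp06 as m
from mtp06 import bifurcation as bif
from tests.conftest import DT_TEST

RELAX = 15_000.0   # short seed-relaxation for tests


@pytest.fixture(scope="module")
def eps_b07():
    """Equilibria of mTP06b at normalized g_Kr = 0.7 (K_i fixed)."""
    ps = m.build_parameters("mTP06b", {"scale_gKr": 0.7}, fix_Ki=True)
    return ps, bif.find_equilibria(ps, relax_ms=RELAX)


def test_three_equilibria_with_unstable_ve3(eps_b07):
    ps, eps = eps_b07
    assert len(eps) == 3
    assert [e.branch for e in eps] == ["V_E1", "V_E2", "V_E3"]
    assert eps[0].V < eps[1].V < eps[2].V
    assert eps[0].is_stable, "resting equilibrium must be stable"
    assert not eps[2].is_stable, \
        "depolarized equilibrium is unstable at positive g_Kr"


def test_equilibrium_residuals_below_tolerance(eps_b07):
    ps, eps = eps_b07
    for ep in eps:
        assert ep.residual < 1e-10
        dy = m.rhs(0.0, ep.state, ps)
        assert np.max(np.abs(dy[ps.free_indices()]
                             / bif.STATE_SCALE[ps.free_indices()])) < 1e-9


def test_resting_ep_matches_unstimulated_relaxation(eps_b07):
    ps, eps = eps_b07
    tr = m.integrate(ps, m.DEFAULT_INITIAL_STATE, 120_000.0,
                     out_step=5000.0, dt=DT_TEST)
    assert abs(tr.V[-1] - eps[0].V) < 1.0


def test_eigenvalue_sign_predicts_perturbation_fate(eps_b07):
    """A 1-mV perturbation decays at the stable EP and grows at the
    unstable one (eigenvalue/simulation consistency)."""
    ps, eps = eps_b07
    for ep in (eps[0], eps[2]):
        y = ep.state.copy()
        y[m.IDX["V"]] += 1.0
        tr = m.integrate(ps, y, 3000.0, out_step=10.0, dt=0.01)
        dev = np.abs(tr.V - ep.V)
        if ep.is_stable:
            assert dev[-1] < dev[0]
        else:
            assert np.max(dev) > 2.0


def test_jacobian_step_halving_stable_leading_eigenvalue(eps_b07):
    ps, eps = eps_b07
    ep = eps[0]
    lam1 = np.linalg.eigvals(bif.jacobian(ep.state, ps, rel_step=1e-6))
    lam2 = np.linalg.eigvals(bif.jacobian(ep.state, ps, rel_step=5e-7))
    l1 = lam1[np.argmax(lam1.real)]
    l2 = lam2[np.argmax(lam2.real)]
    assert abs(l1 - l2) <= 1e-4 * max(1.0, abs(l1))


def test_ep_count_can_drop_to_one(ps_original):
    """The original model at control rests on a single stable equilibrium
    when seeded near rest (no depolarized steady states required)."""
    ps = replace(ps_original, fix_Ki=True)
    eps = bif.find_equilibria(ps, v_seeds=np.array([-90.0, -80.0]),
                              relax_ms=RELAX)
    assert len(eps) >= 1
    assert eps[0].is_stable


def test_so_detection_classifies_rest(ps_b, rest_state_b):
    ps = replace(ps_b, fix_Ki=True)
    res = bif.detect_spontaneous_oscillation(ps, rest_state_b,
                                             total_ms=20_000.0,
                                             window_ms=10_000.0, dt=DT_TEST)
    assert res.kind == "rest"


def test_ep_branch_continuation_tracks_ve3(eps_b07):
    """Warm-started continuation follows all three branches and reports
    a consistent frame; ep_stability agrees with the stored class."""
    ps, eps = eps_b07
    ps0 = m.build_parameters("mTP06b", fix_Ki=True)
    br = bif.continue_ep_branch(ps0, "scale_gKr",
                                np.array([0.7, 0.6, 0.5]),
                                relax_ms=10_000.0)
    df = br.to_frame()
    assert set(df["branch"]) == {"V_E1", "V_E2", "V_E3"}
    ve3 = df[df["branch"] == "V_E3"]
    assert len(ve3) == 3
    assert (~ve3["stable"].astype(bool)).all() if "stable" in ve3 else \
        (ve3["stability"] != "stable").all()
    ep = br.points[0][0]
    assert bif.ep_stability(ep) == ep.stability


def test_lc_branch_flags_multiplier_crossings(monkeypatch, ps_b):
    """PDB/NSB/SNB flags fire when a nontrivial multiplier crosses the
    unit circle between consecutive continuation points (logic check
    with scripted orbits)."""
    y0 = m.DEFAULT_INITIAL_STATE.copy()

    def orbit(mults):
        orb = bif.PeriodicOrbit(y0=y0, period=500.0, params=ps_b)
        orb.multipliers = np.array([1.0] + list(mults), dtype=complex)
        return orb

    scripted = {
        0.9: orbit([-0.8, 0.2]),
        0.8: orbit([-1.3, 0.2]),            # PDB between 0.9 and 0.8
        0.7: orbit([0.4 + 0.8j, 0.4 - 0.8j]),
        0.6: orbit([0.9 + 1.1j, 0.9 - 1.1j]),   # NSB between 0.7 and 0.6
    }
    monkeypatch.setattr(bif, "find_limit_cycle",
                        lambda ps, seed, T, **kw: scripted[
                            round(ps.normalized("scale_gKr"), 2)])
    seed = scripted[0.9]
    br = bif.continue_lc_branch(m.build_parameters("mTP06b", fix_Ki=True),
                                "scale_gKr",
                                np.array([0.9, 0.8, 0.7, 0.6]), seed)
    kinds = [b.kind for b in br.bifurcations]
    assert "PDB" in kinds
    assert "NSB" in kinds


def test_branch_frame_and_labels(eps_b07):
    ps, eps = eps_b07
    br = bif.Branch(axis="scale_gKr", values=np.array([0.7]),
                    points=[eps])
    df = br.to_frame()
    assert set(df["branch"]) == {"V_E1", "V_E2", "V_E3"}
    assert df.shape[0] == 3
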