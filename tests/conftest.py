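"""Shared fixtures.

Expensive states (resting relaxations, short paced runs) are computed
once per session and shared; all fixture inputs are generated by the
package itself -- the study has no external data.
"""

from __future__ import annotations

import numpy as np
import pytest

import mtp06 as m

#: coarse step for unit tests (the package default 0.01 ms is used by the
#: acceptance layer; unit-level checks are robust to the coarser step)
DT_TEST = 0.02


@pytest.fixture(scope="session")
def ps_original():
    return m.build_parameters("original")


@pytest.fixture(scope="session")
def ps_b():
    return m.build_parameters("mTP06b")


@pytest.fixture(scope="session")
def ps_a():
    return m.build_parameters("mTP06a")


@pytest.fixture(scope="session")
def rest_state_b(ps_b):
    """Resting state of the control mTP06b cell (60-s relaxation)."""
    tr = m.integrate(ps_b, m.DEFAULT_INITIAL_STATE, 60_000.0,
                     out_step=1000.0, dt=DT_TEST)
    return tr.y[-1]


@pytest.fixture(scope="session")
def paced_beat_b(ps_b, rest_state_b):
    """Five 1-Hz beats of control mTP06b from rest."""
    prot = m.make_pacing(1000.0, n_beats=5)
    return m.simulate_paced(ps_b, prot, init=rest_state_b, dt=DT_TEST)


@pytest.fixture(scope="session")
def ead_trace_b():
    """A 0.2-Hz g_Kr-reduced mTP06b run that exhibits EADs (short)."""
    ps = m.build_parameters("mTP06b", {"scale_gKr": 0.6})
    tr0 = m.integrate(ps, m.DEFAULT_INITIAL_STATE, 60_000.0,
                      out_step=1000.0, dt=DT_TEST)
    prot = m.make_pacing(5000.0, n_beats=12)
    return ps, prot, m.simulate_paced(ps, prot, init=tr0.y[-1], dt=DT_TEST)
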