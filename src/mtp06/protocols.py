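"""Protocol and parameter-grid generators.

Everything the pipeline consumes is generated here deterministically:
pacing protocols (1-ms, 60 pA/pF stimuli), voltage-clamp pulse trains,
parameter grids with a defined traversal order (initial conditions are
chained from point to point, so order matters), and beta-adrenergic
stimulation scaling sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .params import ConfigurationError


@dataclass(frozen=True)
class PacingProtocol:
    """Periodic current-pulse pacing."""

    CL: float                 # cycle length (ms)
    amplitude: float = 60.0   # pA/pF
    width: float = 1.0        # ms
    n_beats: int | None = None          # None => run to convergence
    extra_stimulus: bool = False        # fR/RF discrimination stimulus

    def __post_init__(self):
        if not self.CL > self.width > 0:
            raise ConfigurationError("need CL > width > 0")
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be >= 0")

    @property
    def frequency_hz(self) -> float:
        return 1000.0 / self.CL


def make_pacing(CL: float, **overrides) -> PacingProtocol:
    """Standard pacing protocol: 1-ms stimuli of 60 pA/pF at cycle length CL."""
    if CL < 100.0:
        raise ConfigurationError("CL below 100 ms is not supported")
    return PacingProtocol(CL=CL, **overrides)


@dataclass(frozen=True)
class ClampProtocol:
    """Square voltage-clamp pulse train (step depolarizations)."""

    V_hold: float = -85.0     # mV
    V_test: float = -10.0     # mV
    pulse_ms: float = 1000.0  # test-pulse duration
    period_ms: float = 2000.0  # pulse onset-to-onset interval (0.5 Hz)
    train_ms: float = 600_000.0  # total train duration (10 min)

    def __post_init__(self):
        if not 0 < self.pulse_ms < self.period_ms:
            raise ConfigurationError("need 0 < pulse < period")
        if self.train_ms <= 0:
            raise ConfigurationError("train duration must be > 0")

    def n_pulses(self) -> int:
        return int(self.train_ms // self.period_ms)

    def schedule(self):
        """Yield (duration_ms, V_clamp) segments of the train."""
        for _ in range(self.n_pulses()):
            yield self.pulse_ms, self.V_test
            yield self.period_ms - self.pulse_ms, self.V_hold
        rem = self.train_ms - self.n_pulses() * self.period_ms
        if rem > 0:
            yield min(rem, self.pulse_ms), self.V_test
            if rem > self.pulse_ms:
                yield rem - self.pulse_ms, self.V_hold


def make_clamp(**overrides) -> ClampProtocol:
    return ClampProtocol(**overrides)


_GRID_AXES = (
    "scale_gKs", "scale_gKr", "scale_gCaL", "scale_Pup", "scale_NCX",
    "CL", "xs2", "CaSR", "Vm",
)


@dataclass(frozen=True)
class ParameterGrid:
    """1-D scan axis with explicit traversal order.

    ``descending=True`` scans from the high end downward (the convention
    for conductance-block scans, where each point warm-starts from its
    predecessor's final state).
    """

    axis: str
    start: float
    stop: float
    step: float
    descending: bool = False

    def __post_init__(self):
        if self.axis not in _GRID_AXES:
            raise ConfigurationError(f"unknown grid axis {self.axis!r}")
        if not (np.isfinite(self.start) and np.isfinite(self.stop)):
            raise ConfigurationError("grid range must be finite")
        if self.step <= 0:
            raise ConfigurationError("grid step must be > 0")

    def values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        vals = self.start + self.step * np.arange(n)
        return vals[::-1].copy() if self.descending else vals


def make_grid(axis: str, start: float, stop: float, step: float,
              descending: bool = False) -> ParameterGrid:
    return ParameterGrid(axis, start, stop, step, descending)


def regression_fixture(variant: str, CL: float = 2000.0, n_beats: int = 5,
                       dt: float = 0.02, overrides: dict | None = None):
    """Deterministic short reference trace for regression testing.

    The model is deterministic, so the fixture is regenerated at call
    time rather than stored: identical arguments reproduce the trace
    bit-for-bit.  Returns (trace, provenance) where the provenance dict
    records everything needed to regenerate it.
    """
    from .params import build_parameters
    from .simulate import default_initial_state, simulate_paced

    ps = build_parameters(variant, overrides or {})
    prot = make_pacing(CL, n_beats=n_beats)
    tr = simulate_paced(ps, prot, init=default_initial_state(ps), dt=dt)
    provenance = {
        "variant": variant,
        "overrides": dict(overrides or {}),
        "CL_ms": CL,
        "n_beats": n_beats,
        "dt_ms": dt,
        "integrator": "rush-larsen",
    }
    return tr, provenance


def beta_as_scalings(gCaL_fold: float = 2.5, gKs_fold: float = 2.0,
                     Pup_fold: float = 2.0, extra: dict | None = None) -> dict:
    """Beta-adrenergic stimulation as a named multiplicative scaling set.

    Defaults are the upper-bound folds (g_CaL up to 250%, g_Ks up to 200%,
    P_up doubled); intermediate conditions are obtained by passing smaller
    folds (e.g. ``Pup_fold=1.41`` or ``1.67``).  ``extra`` adds further
    normalized scalings (e.g. ``{"scale_NaK": 1.4}``).
    """
    for name, v in (("gCaL_fold", gCaL_fold), ("gKs_fold", gKs_fold),
                    ("Pup_fold", Pup_fold)):
        if not v > 0:
            raise ConfigurationError(f"{name} must be > 0")
    scalings = {
        "scale_gCaL": gCaL_fold,
        "scale_gKs": gKs_fold,
        "scale_Pup": Pup_fold,
    }
    if extra:
        for key in extra:
            if not key.startswith("scale_"):
                raise ConfigurationError(f"unknown beta-AS key {key!r}")
        scalings.update(extra)
    return scalings
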