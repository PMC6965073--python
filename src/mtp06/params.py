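"""Parameter sets, model variants, and clamping options.

The two modified M-cell variants are encoded as multiplicative scalings
on the original TP06 constants:

* ``mTP06a`` -- g_Ks x 0.4, g_Kr x 1.5, P_up x 0.6 (smaller I_Ks with
  compensating I_Kr, reduced SR uptake).
* ``mTP06b`` -- mTP06a plus halved I_CaL voltage-dependent inactivation
  time constant (tau_fL) and doubled g_CaL.

Scaling factors supplied by the analysis layers are *normalized* values,
i.e. ratios to the control values of the active variant; they multiply
the variant preset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml

from .constants import BASELINE_P, IDX, N_STATE, P_IDX

VARIANTS = ("original", "mTP06a", "mTP06b")

#: preset normalized scalings of each variant (relative to original TP06)
VARIANT_PRESETS = {
    "original": {},
    "mTP06a": {"scale_gKs": 0.4, "scale_gKr": 1.5, "scale_Pup": 0.6},
    "mTP06b": {
        "scale_gKs": 0.4,
        "scale_gKr": 1.5,
        "scale_Pup": 0.6,
        "scale_tau_fL": 0.5,
        "scale_gCaL": 2.0,
    },
}

_SCALE_FIELDS = (
    "scale_gNa", "scale_gCaL", "scale_gKr", "scale_gKs", "scale_gto",
    "scale_gK1", "scale_Pup", "scale_NCX", "scale_NaK", "scale_tau_fL",
    "scale_tau_f", "scale_tau_f2",
)


class ConfigurationError(ValueError):
    """Unknown variant, scaling name, or inconsistent clamp request."""


@dataclass(frozen=True)
class ParameterSet:
    """Complete parameterization of one model configuration.

    ``scale_*`` fields are multipliers on the original TP06 constants
    (the variant preset already folded in).  ``scale_tau_fL`` scales the
    time constants of *both* voltage-dependent I_CaL inactivation gates
    (f and f2); ``scale_tau_f``/``scale_tau_f2`` are per-gate factors
    multiplied on top of it for sensitivity studies.
    """

    variant: str = "original"
    scale_gNa: float = 1.0
    scale_gCaL: float = 1.0
    scale_gKr: float = 1.0
    scale_gKs: float = 1.0
    scale_gto: float = 1.0
    scale_gK1: float = 1.0
    scale_Pup: float = 1.0
    scale_NCX: float = 1.0
    scale_NaK: float = 1.0
    scale_tau_fL: float = 1.0
    scale_tau_f: float = 1.0
    scale_tau_f2: float = 1.0
    fix_Ki: bool = False
    Ki_value: float = 140.0
    fix_Nai: bool = False
    Nai_value: float = 6.0
    clamp_Vm: bool = False
    Vm_value: float = -85.0
    frozen_extra: tuple = field(default_factory=tuple)  # slow-fast freezes

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        for f_ in _SCALE_FIELDS:
            v = getattr(self, f_)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{f_} must be finite and >= 0")
        for name in self.frozen_extra:
            if name not in IDX:
                raise ConfigurationError(f"unknown state {name!r}")

    # -- kernel views -------------------------------------------------------
    def kernel_p(self) -> np.ndarray:
        """Effective kernel parameter vector (scalings applied)."""
        p = BASELINE_P.copy()
        p[P_IDX["gNa"]] *= self.scale_gNa
        p[P_IDX["gCaL"]] *= self.scale_gCaL
        p[P_IDX["gKr"]] *= self.scale_gKr
        p[P_IDX["gKs"]] *= self.scale_gKs
        p[P_IDX["gto"]] *= self.scale_gto
        p[P_IDX["gK1"]] *= self.scale_gK1
        p[P_IDX["Pup"]] *= self.scale_Pup
        p[P_IDX["kNaCa"]] *= self.scale_NCX
        p[P_IDX["PNaK"]] *= self.scale_NaK
        p[P_IDX["tauf_scale"]] = self.scale_tau_fL * self.scale_tau_f
        p[P_IDX["tauf2_scale"]] = self.scale_tau_fL * self.scale_tau_f2
        return p

    def kernel_mask(self) -> np.ndarray:
        """Frozen-state mask (1.0 = state held constant)."""
        mask = np.zeros(N_STATE)
        if self.clamp_Vm:
            mask[IDX["V"]] = 1.0
        if self.fix_Nai:
            mask[IDX["Nai"]] = 1.0
        if self.fix_Ki:
            mask[IDX["Ki"]] = 1.0
        for name in self.frozen_extra:
            mask[IDX[name]] = 1.0
        return mask

    def apply_clamps(self, y: np.ndarray) -> np.ndarray:
        """Return a copy of ``y`` with clamped/fixed entries set."""
        y = np.array(y, dtype=float, copy=True)
        if self.clamp_Vm:
            y[IDX["V"]] = self.Vm_value
        if self.fix_Nai:
            y[IDX["Nai"]] = self.Nai_value
        if self.fix_Ki:
            y[IDX["Ki"]] = self.Ki_value
        return y

    def free_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kernel_mask() == 0.0)

    # -- derived sets -------------------------------------------------------
    def with_scales(self, **normalized) -> "ParameterSet":
        """Apply normalized (variant-relative) scalings.

        ``with_scales(scale_gKr=0.4)`` on an mTP06b set yields an absolute
        g_Kr multiplier of 1.5 x 0.4, i.e. 40% of the variant's control.
        """
        preset = VARIANT_PRESETS[self.variant]
        updates = {}
        for key, val in normalized.items():
            if key not in _SCALE_FIELDS:
                raise ConfigurationError(f"unknown scaling {key!r}")
            updates[key] = preset.get(key, 1.0) * val
        return replace(self, **updates)

    def normalized(self, key: str) -> float:
        """Current value of a scaling as a ratio to the variant control."""
        if key not in _SCALE_FIELDS:
            raise ConfigurationError(f"unknown scaling {key!r}")
        return getattr(self, key) / VARIANT_PRESETS[self.variant].get(key, 1.0)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {}
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if isinstance(v, tuple):
                v = list(v)
            d[f_.name] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        d = dict(d)
        if "frozen_extra" in d:
            d["frozen_extra"] = tuple(d["frozen_extra"])
        known = {f_.name for f_ in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter keys {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_parameters(variant: str = "original", overrides: dict | None = None,
                     **flags) -> ParameterSet:
    """Build a :class:`ParameterSet` for a model variant.

    Parameters
    ----------
    variant : {"original", "mTP06a", "mTP06b"}
    overrides : dict, optional
        Normalized scalings (ratios to the variant's control values),
        applied multiplicatively on top of the preset; e.g.
        ``build_parameters("mTP06b", {"scale_gKr": 0.4})`` gives an
        absolute g_Kr multiplier of 1.5 * 0.4.
    **flags
        Extra dataclass fields (``fix_Ki=True`` etc.).
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"unknown variant {variant!r}")
    ps = ParameterSet(variant=variant, **VARIANT_PRESETS[variant], **flags)
    if overrides:
        ps = ps.with_scales(**overrides)
    return ps
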