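"""Experiment orchestration: serializable configs, figure presets, and a
deterministic ``run`` that writes tidy CSV artifacts plus a manifest.

Every analysis in the study is expressible as an ExperimentConfig; the
named presets encode the printed protocol constants of the study's
figures at desk scale (coarser grids, shorter trains; the full-scale
settings are plain config values).  The pipeline contains no random
numbers: identical configs yield identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constants import IDX
from .features import find_critical_parameter, first_ead_stimulus_index
from .params import ConfigurationError, build_parameters
from .protocols import beta_as_scalings, make_clamp, make_pacing
from .simulate import default_initial_state, simulate_paced

ANALYSES = ("pace", "critical", "branch", "twopar", "slowfast", "clamp",
            "phase", "switch")


@dataclass
class ExperimentConfig:
    """One reproducible analysis run."""

    analysis: str
    variant: str = "mTP06b"
    overrides: dict = field(default_factory=dict)
    beta_as: dict | None = None
    CL: float = 5000.0
    dt: float = 0.01
    fix_Nai: bool = False
    fix_Ki: bool = False
    options: dict = field(default_factory=dict)
    outdir: str = "results"

    def __post_init__(self):
        if self.analysis not in ANALYSES:
            raise ConfigurationError(
                f"unknown analysis {self.analysis!r}; one of {ANALYSES}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def parameter_set(self):
        ov = dict(self.overrides)
        if self.beta_as:
            ba = beta_as_scalings(**self.beta_as) if any(
                k.endswith("_fold") for k in self.beta_as) else self.beta_as
            for k, v in ba.items():
                ov[k] = ov.get(k, 1.0) * v
        return build_parameters(self.variant, ov, fix_Nai=self.fix_Nai,
                                fix_Ki=self.fix_Ki)


def _write_manifest(cfg: ExperimentConfig, outdir: Path, artifacts: list,
                    t_start: float) -> Path:
    manifest = {
        "config": cfg.to_dict(),
        "config_digest": cfg.digest(),
        "package_version": __version__,
        "solver": {"method": "rush-larsen", "dt_ms": cfg.dt},
        "artifacts": artifacts,
        "runtime_s": round(time.time() - t_start, 2),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def run(config: ExperimentConfig) -> dict:
    """Execute one analysis; writes artifacts + manifest, returns paths."""
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ps = config.parameter_set()
    opts = dict(config.options)
    artifacts: list[str] = []

    if config.analysis == "pace":
        n_beats = opts.get("n_beats")
        prot = make_pacing(config.CL, n_beats=n_beats)
        tr = simulate_paced(ps, prot, dt=config.dt,
                            max_duration=opts.get("max_duration_ms", 1.8e6))
        trace_csv = outdir / "trace.csv"
        tr.to_csv(trace_csv)
        feat_csv = outdir / "features.csv"
        tr.features_frame().to_csv(feat_csv, index=False)
        artifacts += [trace_csv.name, feat_csv.name]

    elif config.analysis == "critical":
        crit = find_critical_parameter(
            ps, make_pacing(config.CL), axis=opts.get("axis", "scale_gKr"),
            bracket=tuple(opts.get("bracket", (0.7, 1.0))),
            resolution=opts.get("resolution", 0.001),
            prepace_beats=opts.get("prepace_beats", 360),
            beats_per_point=opts.get("beats_per_point", 12), dt=config.dt)
        path = outdir / "critical.json"
        path.write_text(json.dumps(
            {"axis": opts.get("axis", "scale_gKr"), "critical": crit}))
        artifacts.append(path.name)

    elif config.analysis == "switch":
        idx = first_ead_stimulus_index(
            ps, CL_pre=opts.get("CL_pre", 1000.0), CL_post=config.CL,
            init=None, max_stimuli=opts.get("max_stimuli", 600),
            dt=config.dt)
        path = outdir / "switch.json"
        path.write_text(json.dumps({"CL_post_ms": config.CL,
                                    "first_ead_stimulus": idx}))
        artifacts.append(path.name)

    elif config.analysis == "branch":
        from .bifurcation import continue_ep_branch
        import dataclasses
        ps_b = dataclasses.replace(ps, fix_Ki=True)
        axis = opts.get("axis", "scale_gKr")
        vals = np.asarray(opts.get("values",
                                   np.linspace(1.0, 0.2, 9)), dtype=float)
        br = continue_ep_branch(ps_b, axis, vals,
                                relax_ms=opts.get("relax_ms", 20_000.0))
        path = outdir / "ep_branch.csv"
        br.to_frame().to_csv(path, index=False)
        bpath = outdir / "bifurcations.csv"
        pd.DataFrame([{"kind": b.kind, "value": b.value, "detail": b.detail}
                      for b in br.bifurcations]).to_csv(bpath, index=False)
        artifacts += [path.name, bpath.name]

    elif config.analysis == "twopar":
        from .bifurcation import two_parameter_curves
        import dataclasses
        ps_b = dataclasses.replace(ps, fix_Ki=True)
        curves = two_parameter_curves(
            ps_b, opts.get("axis1", "scale_gKs"),
            np.asarray(opts.get("values1", [0.5, 1.0]), dtype=float),
            opts.get("axis2", "scale_gKr"),
            tuple(opts.get("bracket2", (0.05, 1.0))),
            so_total_ms=opts.get("so_total_ms", 120_000.0),
            tol2=opts.get("tol2", 0.01))
        path = outdir / "twopar_curves.csv"
        rows = [{"curve": name, "axis1": a, "axis2": b}
                for name, pts in curves.items() for a, b in pts]
        pd.DataFrame(rows).to_csv(path, index=False)
        artifacts.append(path.name)

    elif config.analysis == "slowfast":
        from .slowfast import FastSubsystemSpec, quasi_branch
        spec = FastSubsystemSpec(
            axis=opts.get("axis", "xs2"),
            Nai=opts.get("Nai", 6.0),
            CaSR=opts.get("CaSR", 1.5) if opts.get("axis", "xs2") == "xs2"
            else None,
            Vm=opts.get("Vm") if opts.get("axis", "xs2") == "CaSR" else None)
        vals = np.asarray(opts.get("values", np.linspace(0.0, 0.2, 21)),
                          dtype=float)
        qb = quasi_branch(spec, ps, vals,
                          relax_ms=opts.get("relax_ms", 15_000.0))
        path = outdir / "quasi_branch.csv"
        qb.to_frame().to_csv(path, index=False)
        artifacts.append(path.name)

    elif config.analysis == "clamp":
        from .vclamp import detect_release_events, simulate_clamped
        prot = make_clamp(train_ms=opts.get("train_ms", 600_000.0))
        tr = simulate_clamped(ps, prot, dt=config.dt)
        events = detect_release_events(tr)
        path = outdir / "clamp_trace.csv"
        tr.to_csv(path, columns=("V", "Cai", "Cass", "CaSR"))
        epath = outdir / "release_events.csv"
        pd.DataFrame([{"onset_ms": e.onset, "drop_mM": e.casr_drop,
                       "drop_frac": e.casr_drop_frac,
                       "pulse_triggered": e.pulse_triggered}
                      for e in events]).to_csv(epath, index=False)
        artifacts += [path.name, epath.name]

    elif config.analysis == "phase":
        from .phase import sweep_plane
        diag = sweep_plane(
            ps, make_pacing(config.CL),
            opts.get("axis1", "scale_gKs"),
            np.asarray(opts.get("values1", [0.25, 0.5, 1.0]), dtype=float),
            opts.get("axis2", "scale_gKr"),
            np.asarray(opts.get("values2", np.linspace(0.2, 1.0, 5)),
                       dtype=float),
            prepace_beats=opts.get("prepace_beats", 120),
            beats_per_point=opts.get("beats_per_point", 12),
            refine=opts.get("refine", False), dt=config.dt)
        path = outdir / "phase_diagram.csv"
        diag.to_frame().to_csv(path, index=False)
        artifacts.append(path.name)

    manifest = _write_manifest(config, outdir, artifacts, t_start)
    return {"outdir": str(outdir), "manifest": str(manifest),
            "artifacts": artifacts}


# ---------------------------------------------------------------------------
# figure presets (desk scale)
# ---------------------------------------------------------------------------

PRESETS: dict[str, ExperimentConfig] = {
    # I_Kr-reduced EADs at 0.2 Hz and the matching one-parameter branch
    "ikr_block_pace": ExperimentConfig(
        analysis="pace", variant="mTP06b", overrides={"scale_gKr": 0.6},
        CL=5000.0, options={"n_beats": 60}),
    "gkr_ep_branch": ExperimentConfig(
        analysis="branch", variant="mTP06b", fix_Ki=True,
        options={"axis": "scale_gKr", "values": [1.0, 0.8, 0.6, 0.4, 0.2]}),
    "lqt_plane": ExperimentConfig(
        analysis="phase", variant="mTP06b", CL=5000.0,
        options={"axis1": "scale_gKs", "values1": [0.0, 0.5, 1.0],
                 "axis2": "scale_gKr",
                 "values2": [0.2, 0.4, 0.6, 0.8, 1.0]}),
    "pause_switch_cl3": ExperimentConfig(
        analysis="switch", variant="mTP06b", overrides={"scale_gKr": 0.721},
        CL=3000.0, options={"CL_pre": 1000.0, "max_stimuli": 600}),
    "critical_gcal_1hz": ExperimentConfig(
        analysis="critical", variant="mTP06b", CL=1000.0,
        options={"axis": "scale_gCaL", "bracket": (1.0, 2.0),
                 "resolution": 0.002}),
    "xs2_decomposition": ExperimentConfig(
        analysis="slowfast", variant="mTP06b", overrides={"scale_gKr": 0.6},
        options={"axis": "xs2", "CaSR": 1.5, "Nai": 6.0}),
    "clamp_train_beta_as": ExperimentConfig(
        analysis="clamp", variant="mTP06b", fix_Nai=True,
        overrides={"scale_Pup": 1.67}, options={"train_ms": 240_000.0}),
    "casr_decomposition": ExperimentConfig(
        analysis="slowfast", variant="mTP06b", fix_Nai=True,
        options={"axis": "CaSR", "Vm": -10.0,
                 "values": list(np.round(np.linspace(0.5, 4.0, 15), 3))}),
}
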