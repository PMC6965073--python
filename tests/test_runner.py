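"""Experiment configs, orchestration, and the CLI surface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from mtp06.cli import main as cli_main
from mtp06.params import ConfigurationError
from mtp06.runner import PRESETS, ExperimentConfig, run


def test_config_roundtrip_and_digest(tmp_path):
    cfg = ExperimentConfig(analysis="pace", variant="mTP06b",
                           overrides={"scale_gKr": 0.6}, CL=5000.0)
    d = cfg.to_dict()
    cfg2 = ExperimentConfig.from_dict(d)
    assert cfg2 == cfg
    assert cfg.digest() == cfg2.digest()
    other = ExperimentConfig(analysis="pace", CL=4000.0)
    assert cfg.digest() != other.digest()
    import yaml
    p = tmp_path / "cfg.yaml"
    p.write_text(yaml.safe_dump(d))
    assert ExperimentConfig.from_yaml(p) == cfg


def test_config_validation():
    with pytest.raises(ConfigurationError):
        ExperimentConfig(analysis="teleport")
    with pytest.raises(ConfigurationError):
        ExperimentConfig.from_dict({"analysis": "pace", "banana": 1})


def test_beta_as_folds_into_parameter_set():
    cfg = ExperimentConfig(analysis="pace",
                           beta_as={"gCaL_fold": 1.6, "gKs_fold": 2.0,
                                    "Pup_fold": 1.67})
    ps = cfg.parameter_set()
    assert ps.scale_gCaL == pytest.approx(2.0 * 1.6)
    assert ps.scale_gKs == pytest.approx(0.4 * 2.0)
    assert ps.scale_Pup == pytest.approx(0.6 * 1.67)


def test_run_pace_writes_artifacts_and_manifest(tmp_path):
    cfg = ExperimentConfig(analysis="pace", CL=1000.0, dt=0.02,
                           options={"n_beats": 3},
                           outdir=str(tmp_path / "out"))
    res = run(cfg)
    out = tmp_path / "out"
    assert (out / "trace.csv").exists()
    assert (out / "features.csv").exists()
    manifest = json.loads((out / "manifest.json").read_text())
    assert manifest["config_digest"] == cfg.digest()
    assert manifest["solver"]["dt_ms"] == 0.02
    assert set(manifest["artifacts"]) == {"trace.csv", "features.csv"}


def test_rerun_reproduces_identical_csv(tmp_path):
    """Determinism: identical configs yield numerically identical files."""
    outs = []
    for name in ("a", "b"):
        cfg = ExperimentConfig(analysis="pace", CL=1000.0, dt=0.02,
                               options={"n_beats": 2},
                               outdir=str(tmp_path / name))
        run(cfg)
        outs.append((tmp_path / name / "trace.csv").read_text())
    assert outs[0] == outs[1]


def test_presets_are_well_formed():
    assert set(PRESETS) >= {"ikr_block_pace", "lqt_plane",
                            "pause_switch_cl3", "xs2_decomposition",
                            "clamp_train_beta_as", "casr_decomposition"}
    for cfg in PRESETS.values():
        cfg.parameter_set()   # must build without error


def test_cli_help_and_tiny_pace(tmp_path):
    r = CliRunner().invoke(cli_main, ["--help"])
    assert r.exit_code == 0
    for sub in ("pace", "critical", "branch", "twopar", "slowfast",
                "clamp", "phase", "preset"):
        assert sub in r.output
    r2 = CliRunner().invoke(
        cli_main, ["pace", "--cl", "1000", "--dt", "0.02", "--beats", "2",
                   "-s", "scale_gKr=0.8", "--out", str(tmp_path / "cli")])
    assert r2.exit_code == 0, r2.output
    assert (tmp_path / "cli" / "trace.csv").exists()
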