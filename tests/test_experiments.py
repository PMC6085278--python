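"""Twin-experiment harness, sweeps, multistart, outputs, and CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from neuroassim import experiments, fourdvar, ukf
from neuroassim.cli import main as cli_main
from neuroassim.experiments import TwinExperimentSpec


def test_parameter_rmse_hand_values():
    assert experiments.parameter_rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert experiments.parameter_rmse([3.0, 4.0], [0.0, 0.0]) == pytest.approx(
        np.sqrt(25 / 2)
    )
    with pytest.raises(ValueError):
        experiments.parameter_rmse([1.0], [1.0, 2.0])


def test_spec_validation():
    with pytest.raises(ValueError):
        TwinExperimentSpec(method="ekf", model="spiking",
                           true_regime="SNIC", guess_regime="HOPF")
    with pytest.raises(ValueError):
        TwinExperimentSpec(method="ukf", model="spiking",
                           true_regime="square-wave", guess_regime="HOPF")
    with pytest.raises(ValueError):
        TwinExperimentSpec(method="ukf", model="bursting",
                           true_regime="SNIC", guess_regime="SNIC")
    spec = TwinExperimentSpec(method="ukf", model="spiking",
                              true_regime="SNIC", guess_regime="HOPF")
    n, dt, sub = spec.protocol()
    assert (n, dt, sub) == (200_001, 0.1, 1)
    # the guess inherits the known applied current from the truth
    assert spec.guess_params().Iapp == spec.true_params().Iapp


def test_run_twin_deterministic():
    spec = TwinExperimentSpec(
        method="ukf", model="spiking", true_regime="SNIC", guess_regime="HOPF",
        seed=3, scale=0.02, classify=False,
    )
    a = experiments.run_twin(spec)
    b = experiments.run_twin(spec)
    np.testing.assert_array_equal(a.theta, b.theta)
    assert a.status == b.status == "ok"
    assert a.rmse >= 0
    assert a.trajectory is not None


def test_run_twin_4dvar_statuses():
    spec = TwinExperimentSpec(
        method="4dvar", model="spiking", true_regime="SNIC", guess_regime="SNIC",
        seed=3, n_points=300, classify=False,
        config=fourdvar.VarConfig(maxiter=50),
    )
    res = experiments.run_twin(spec)
    assert res.status in ("ok", "optimizer_maxiter")
    assert res.cost_log is not None and len(res.cost_log) >= 1
    assert res.final_cost == pytest.approx(res.cost_log[-1])


def test_run_twin_filter_failure_is_status():
    spec = TwinExperimentSpec(
        method="ukf", model="spiking", true_regime="SNIC", guess_regime="HOPF",
        seed=3, scale=0.02, classify=False,
        config=ukf.UKFConfig(alpha_i=100.0),
    )
    res = experiments.run_twin(spec)  # must not raise
    assert res.status == "filter_failed"
    assert res.regime_label is None


def test_lambda_alpha_sweep_records_failures():
    base = TwinExperimentSpec(
        method="ukf", model="spiking", true_regime="SNIC", guess_regime="HOPF",
        seed=3, scale=0.02, classify=False,
    )
    grid = experiments.lambda_alpha_sweep(base, [5.0], [1e-3, 100.0])
    assert len(grid) == 2
    ok = grid[grid.alpha_i == 1e-3].iloc[0]
    bad = grid[grid.alpha_i == 100.0].iloc[0]
    assert not ok.failed and np.isfinite(ok.rmse)
    assert bad.failed and np.isnan(bad.rmse)


def test_multistart_single_start_single_cluster():
    base = TwinExperimentSpec(
        method="ukf", model="spiking", true_regime="SNIC", guess_regime="HOPF",
        seed=3, scale=0.02, classify=False,
    )
    out = experiments.multistart_study(base, n_starts=1)
    assert out["n_clusters"] == 1
    assert out["clusters"][0]["count"] == 1


def test_multistart_ukf_consistency():
    base = TwinExperimentSpec(
        method="ukf", model="spiking", true_regime="SNIC", guess_regime="SNIC",
        seed=3, scale=0.05, classify=False,
    )
    out = experiments.multistart_study(base, n_starts=5, init_seed=1)
    # randomized gate starts converge to one cluster of estimates
    assert out["n_clusters"] == 1
    assert out["clusters"][0]["count"] == 5


def test_write_outputs_round_trip(tmp_path):
    spec = TwinExperimentSpec(
        method="ukf", model="spiking", true_regime="SNIC", guess_regime="HOPF",
        seed=3, scale=0.02, classify=False,
    )
    res = experiments.run_twin(spec)
    manifest = experiments.write_outputs([res], tmp_path)
    table = pd.read_csv(manifest["table"], index_col=0)
    col = table.columns[0]
    np.testing.assert_allclose(table[col].to_numpy(), res.theta)
    meta = json.loads((tmp_path / "manifest.json").read_text())
    assert meta["seeds"] == [3]
    assert meta["experiments"][0]["status"] == "ok"
    assert (tmp_path / "run.log").exists()
    with pytest.raises(ValueError):
        experiments.write_outputs([], tmp_path)


def test_cli_twin_and_sweep(tmp_path):
    runner = CliRunner()
    out = runner.invoke(
        cli_main,
        ["twin", "--method", "ukf", "--model", "spiking", "--true", "SNIC",
         "--guess", "HOPF", "--seed", "3", "--scale", "0.02",
         "--out", str(tmp_path / "t")],
    )
    assert out.exit_code == 0, out.output
    assert (tmp_path / "t" / "parameters.csv").exists()

    out = runner.invoke(
        cli_main,
        ["sweep", "--method", "ukf", "--model", "spiking", "--true", "SNIC",
         "--guess", "HOPF", "--seed", "3", "--scale", "0.02",
         "--lam", "5", "--alpha-i", "0.001",
         "--out", str(tmp_path / "s")],
    )
    assert out.exit_code == 0, out.output
    assert (tmp_path / "s" / "sweep.csv").exists()
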