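import json

import numpy as np
import pandas as pd
import pytest
from typer.testing import CliRunner

import grnswitch as gs
from grnswitch.cli import app
from grnswitch.experiments import build_network, run_experiment
from grnswitch.residence import cv_sweep, hybrid_cv_sweep


class TestSweeps:
    def test_cv_zero_only_grid_normalizes_to_one(self, toggle, toggle_regions):
        df = cv_sweep(
            toggle, family="gamma", mean=2.0, cv_grid=[0.0],
            min_residences=4, seeds=(1, 2), regions=toggle_regions,
            max_events=10**9,
        )
        assert len(df) == 1
        assert df["norm_mean"].iloc[0] == 1.0
        assert df["norm_se"].iloc[0] == 0.0

    def test_grid_without_baseline_rejected(self, toggle, toggle_regions):
        with pytest.raises(ValueError, match="include 0"):
            cv_sweep(toggle, cv_grid=[0.3, 0.6], regions=toggle_regions)

    def test_sweep_reproducible_and_tidy(self, toggle, toggle_regions):
        kw = dict(
            family="gamma", mean=2.0, cv_grid=[0.0, 2.5],
            min_residences=4, seeds=(1, 2), regions=toggle_regions,
            max_events=10**9,
        )
        a = cv_sweep(toggle, **kw)
        b = cv_sweep(toggle, **kw)
        pd.testing.assert_frame_equal(a, b)
        assert set(a.columns) >= {
            "cv", "state", "n_residences", "mean_residence", "se",
            "norm_mean", "norm_se", "complete",
        }
        assert (a["n_residences"] >= 4).all()

    def test_hybrid_sweep_smoke_grid(self, toggle, toggle_regions):
        df = hybrid_cv_sweep(
            toggle, mu=3.0, r_grid=[1.0], cv_grid=[0.0, 0.5],
            min_residences=4, seeds=(1, 2), regions=toggle_regions,
            max_events=10**9, want_attempts=True,
        )
        assert len(df) == 2
        assert df.loc[df.cv == 0.0, "norm_mean"].iloc[0] == 1.0
        # slow switching destabilizes strongly
        assert df.loc[df.cv == 0.5, "norm_mean"].iloc[0] < 1.0
        assert np.isfinite(df["attempts_per_residency"]).all()


class TestRunner:
    def test_steady_states_experiment(self, tmp_path):
        summary = run_experiment(
            {"experiment": "steady_states", "model": {"name": "pfl"}},
            out=tmp_path,
        )
        assert len(summary["stable"]) == 2
        meta = json.loads((tmp_path / "metadata.json").read_text())
        assert meta["network"]["model"] == "pfl"

    def test_simulate_experiment_writes_trajectory(self, tmp_path):
        summary = run_experiment(
            {
                "experiment": "simulate",
                "model": {"name": "toggle"},
                "kernel": {"family": "gamma", "mean": 2.0, "cv": 0.5},
                "t_max": 50.0,
                "seeds": [3],
            },
            out=tmp_path,
        )
        df = pd.read_csv(tmp_path / "trajectory.csv")
        assert {"time", "kind", "reaction", "Q1", "Q2"} <= set(df.columns)
        assert summary["t_final"] == 50.0
        # metadata records the parameter-parsing decision
        meta = json.loads((tmp_path / "metadata.json").read_text())
        assert "parsing" in meta["network"]

    def test_toggle_parsing_recorded_in_metadata(self):
        net = build_network({"name": "toggle"})
        assert net.metadata["parsing"].startswith("beta=")

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            build_network({"name": "repressilator"})


class TestCLI:
    def test_steady_states_command(self, tmp_path):
        res = CliRunner().invoke(
            app, ["steady-states", "--model", "pfl", "--out", str(tmp_path)]
        )
        assert res.exit_code == 0
        assert "stable fixed points" in res.output

    def test_rm_report_command(self, tmp_path):
        res = CliRunner().invoke(
            app, ["rm-report", "--seed", "3", "--out", str(tmp_path)]
        )
        assert res.exit_code == 0
        assert "monotone decreasing: True" in res.output
        summary = json.loads((tmp_path / "summary.json").read_text())
        assert summary["assumptions"]["rm3_pass"]


class TestPlots:
    def test_cv_response_figure(self):
        import matplotlib
        matplotlib.use("Agg")
        from grnswitch.plots import plot_cv_response

        df = pd.DataFrame(
            {
                "cv": [0.0, 0.3, 1.0] * 2,
                "state": ["H"] * 3 + ["L"] * 3,
                "norm_mean": [1.0, 1.5, 0.6, 1.0, 1.3, 0.4],
                "norm_se": [0.0, 0.2, 0.1] * 2,
            }
        )
        fig = plot_cv_response(df)
        assert fig.axes[0].get_xlabel() == "delay CV"

    def test_switching_heatmap_figure(self):
        import matplotlib
        matplotlib.use("Agg")
        from grnswitch.plots import plot_switching_heatmap

        df = pd.DataFrame(
            {
                "r": [1.0, 1.0, 256.0, 256.0],
                "cv": [0.0, 0.5, 0.0, 0.5],
                "norm_mean": [1.0, 0.1, 1.0, 1.4],
            }
        )
        fig = plot_switching_heatmap(df)
        assert len(fig.axes) == 2  # heatmap + colorbar
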