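"""Configuration, file formats and the command-line interface."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import permclean as pc
from permclean.cli import main
from permclean.errors import InputError, ParameterError
from permclean.io import read_annotations_csv, write_annotations_csv


class TestConfig:
    def test_defaults_are_the_recommended_operating_point(self):
        cfg = pc.PipelineConfig()
        assert cfg.smoother.method == "gaussian" and cfg.smoother.w == 70
        assert (cfg.dra.w1, cfg.dra.w2, cfg.dra.mode) == (1, 15, "overlapping")
        assert cfg.threshold.kind == "static"
        assert cfg.threshold.static_value == pytest.approx(1.06)
        assert cfg.validation_len == cfg.replacement_window == 15

    def test_yaml_round_trip_is_lossless(self, tmp_path):
        cfg = pc.PipelineConfig(
            smoother=pc.SmootherSpec("savitzky_golay", w=21, poly_degree=2),
            dra=pc.DraSpec(2, 9, mode="adjacent"),
            threshold=pc.ThresholdSpec(kind="hampel", w3=20,
                                       threshold_factor=2.5),
            validation_len=10, replacement_window=12)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert pc.PipelineConfig.from_yaml(path) == cfg

    def test_unknown_keys_rejected(self):
        with pytest.raises(ParameterError):
            pc.PipelineConfig.from_dict({"smooother": {}})


class TestSeriesIO:
    def test_csv_round_trip(self, tmp_path):
        series = pc.PermittivitySeries(np.linspace(2, 20, 50))
        path = tmp_path / "series.csv"
        series.to_csv(path)
        back = pc.PermittivitySeries.from_csv(path)
        np.testing.assert_allclose(back.values, series.values, rtol=1e-5)
        assert back.sample_period_s == pytest.approx(60.0)

    def test_non_uniform_grid_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"time_min": [0, 1, 3, 4],
                      "permittivity_pF_cm": [1, 2, 3, 4]}).to_csv(path,
                                                                  index=False)
        with pytest.raises(InputError):
            pc.PermittivitySeries.from_csv(path)
        filled = pc.PermittivitySeries.from_csv(path, gap_fill=True)
        assert len(filled) == 5
        assert filled.values[2] == filled.values[1]  # held value over the gap

    def test_annotation_round_trip(self, tmp_path):
        path = tmp_path / "ann.csv"
        write_annotations_csv(path, [(10, 12, "spike"), (40, 40, "shift")])
        assert read_annotations_csv(path) == [(10, 12, "spike"),
                                              (40, 40, "shift")]


class TestCli:
    def test_generate_run_evaluate_chain(self, tmp_path):
        runner = CliRunner()
        series = tmp_path / "series.csv"
        ann = tmp_path / "ann.csv"
        clean = tmp_path / "clean.csv"
        out = tmp_path / "out.csv"
        matrix = tmp_path / "matrix.csv"
        cfg_path = tmp_path / "cfg.yaml"
        pc.PipelineConfig(smoother=pc.SmootherSpec("gaussian", w=5)).to_yaml(
            cfg_path)

        res = runner.invoke(main, [
            "generate", "--duration-h", "10", "--baseline", "5",
            "--mu-batch", "0.12", "--switch-time-h", "11",
            "--dip-depth-frac", "0", "--plateau-cap", "12",
            "--noise-sigma", "0.2", "--shift", "510:5.0", "--seed", "4",
            "--out", str(series), "--annotations", str(ann),
            "--clean", str(clean)])
        assert res.exit_code == 0, res.output
        assert "1 annotated anomalies" in res.output

        res = runner.invoke(main, ["run", str(series), "--config",
                                   str(cfg_path), "--out", str(out),
                                   "--anomalies", str(matrix)])
        assert res.exit_code == 0, res.output
        assert "1 anomalies" in res.output

        res = runner.invoke(main, ["evaluate", str(out), "--annotations",
                                   str(ann), "--reference", str(clean)])
        assert res.exit_code == 0, res.output
        assert "precision=" in res.output and "NRMSE=" in res.output

    def test_rerun_is_byte_identical(self, tmp_path):
        runner = CliRunner()
        series = tmp_path / "series.csv"
        runner.invoke(main, ["generate", "--duration-h", "6", "--seed", "1",
                             "--noise-sigma", "0.5", "--out", str(series)])
        outs = []
        for name in ("a.csv", "b.csv"):
            out = tmp_path / name
            res = runner.invoke(main, ["run", str(series), "--out", str(out)])
            assert res.exit_code == 0, res.output
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]

    def test_sweep_enumerates_full_static_grid(self, tmp_path):
        """The classic manual-threshold sweep 0.10-1.45 step 0.01 has exactly
        136 grid points."""
        runner = CliRunner()
        series = tmp_path / "series.csv"
        ann = tmp_path / "ann.csv"
        runner.invoke(main, [
            "generate", "--duration-h", "4", "--baseline", "5",
            "--switch-time-h", "5", "--plateau-cap", "8",
            "--noise-sigma", "0.2", "--spike", "120:5.0:3", "--seed", "2",
            "--out", str(series), "--annotations", str(ann)])
        manifest = tmp_path / "manifest.csv"
        pd.DataFrame({"series": [str(series)],
                      "annotations": [str(ann)]}).to_csv(manifest, index=False)
        grid_path = tmp_path / "grid.yaml"
        thresholds = [round(0.10 + 0.01 * i, 2) for i in range(136)]
        grid_path.write_text(
            "smoother.w: [5]\nthreshold.static_value: "
            + "[" + ", ".join(map(str, thresholds)) + "]\n")
        out = tmp_path / "sweep.csv"
        res = runner.invoke(main, ["sweep", "--manifest", str(manifest),
                                   "--grid", str(grid_path), "--out",
                                   str(out)])
        assert res.exit_code == 0, res.output
        table = pd.read_csv(out)
        assert len(table) == 136
        f1 = table["mean_f1"].to_numpy()
        assert np.all(np.diff(f1) <= 1e-12)  # ranked descending
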