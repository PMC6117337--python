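"""Study orchestration: pair geometry, region logic, caching, config, CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from microstim import (GridCache, SurrogateModel, electrode_pair, pair_study,
                       ratio_at_async_volume, surrogate_grid)
from microstim.cli import main as cli_main
from microstim.config import load_config
from microstim.experiments import (period_z_step, run_diameter_sweep,
                                   run_spacing_sweep)
from microstim.vta import VolumeRatioCurve


class TestGeometryHelpers:
    def test_electrode_pair_axes(self):
        e1, e2 = electrode_pair("longitudinal", 400.0)
        assert e2.position == (0.0, 0.0, 400.0)
        _, e2 = electrode_pair("transverse", 600.0)
        assert e2.position == (600.0, 0.0, 0.0)
        _, e2 = electrode_pair("slant", 800.0)
        assert e2.position == (0.0, 200.0, 800.0)
        with pytest.raises(ValueError):
            electrode_pair("diagonal", 100.0)

    @pytest.mark.parametrize("L,target,expected", [
        (1400.0, 40.0, 40.0),    # divides exactly
        (1150.0, 40.0, 46.0),    # nearest integer divisor
        (1450.0, 40.0, 50.0),
        (500.0, 40.0, 50.0),
    ])
    def test_period_z_step(self, L, target, expected):
        s = period_z_step(L, target)
        assert s == expected
        assert (L / s) == int(L / s)

    def test_ratio_at_async_volume_interpolates(self):
        c = VolumeRatioCurve(np.array([1.0, 2.0, 3.0]),
                             np.array([20.0, 60.0, 90.0]),
                             np.array([10.0, 20.0, 30.0]))
        out = ratio_at_async_volume(c, [15.0])
        assert out[0] == pytest.approx(2.5)      # between ratios 2 and 3
        assert np.isnan(ratio_at_async_volume(c, [5.0]))[0:1].all()


class TestPairStudyIntegration:
    def test_small_fiber_pair_study(self):
        """End-to-end 3D study on the smallest fiber (500 µm internodal
        length keeps the grid tiny): the synchronous field dominates the
        asynchronous one and the volume ratio stays at or above 1."""
        st = pair_study(5.7, (0.0, 0.0, 200.0), step=100.0,
                        amplitudes=np.arange(4.0, 30.0, 4.0))
        f_sync = st.fields["sync"].values
        f_async = st.fields["async"].values
        both = np.isfinite(f_sync) & np.isfinite(f_async)
        assert both.any()
        # sync threshold ≤ async threshold up to the 0.1 µA quantization
        assert np.all(f_sync[both] <= f_async[both] + 0.100001)
        r = st.curve.ratios
        ok = np.isfinite(r)
        assert ok.any()
        assert np.all(r[ok] >= 1.0 - 1e-9)
        # one-period longitudinal window
        assert st.fields["sync"].z_period == st.internodal_length


class TestSweepRecords:
    def test_sweep_dataframes_are_long_format(self):
        """Diameter and spacing sweeps share cached engines/grids, so the
        tiny-fiber configuration from the integration test makes these
        nearly free; check the long-format record contract."""
        df = run_diameter_sweep(diameters=[5.7], pairings=["longitudinal"],
                                spacing=200.0, step=100.0,
                                amplitudes=np.arange(4.0, 30.0, 4.0))
        expected = {"amplitude", "sync_volume", "async_volume", "ratio",
                    "varied", "value", "pairing", "spacing", "config_hash",
                    "fiber_diameter", "cathodic_width"}
        assert expected <= set(df.columns)
        assert (df["varied"] == "diameter").all()
        assert df["ratio"].dropna().between(0.5, 20).all()
        df2 = run_spacing_sweep("longitudinal", [200.0], fiber_diameter=5.7,
                                step=100.0, amplitudes=np.arange(4.0, 30.0, 4.0))
        assert (df2["varied"] == "spacing").all()
        assert len(df2) == len(df)
        # identical configuration ⇒ identical cached grids and records
        np.testing.assert_allclose(df2["ratio"], df["ratio"])


class TestGridCache:
    def test_cache_roundtrip_and_reuse(self, tmp_path, iso_surrogate):
        calls = []

        def compute():
            calls.append(1)
            return surrogate_grid(iso_surrogate, (0, 0, 0), (3, 3, 3), 20.0)

        cache = GridCache(tmp_path)
        key = {"purpose": "test", "step": 20.0}
        f1 = cache.get_or_compute(key, compute)
        f2 = cache.get_or_compute(key, compute)
        assert len(calls) == 1
        np.testing.assert_array_equal(f1.values, f2.values)
        f3 = cache.get_or_compute({**key, "step": 10.0}, compute)
        assert len(calls) == 2


class TestPlotting:
    def test_threshold_map_and_contours_render(self, iso_surrogate, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        from microstim.plotting import (iso_threshold_contours,
                                        plot_ratio_curves,
                                        plot_threshold_slice)

        f = surrogate_grid(iso_surrogate, (-200, -40, -200), (21, 5, 21), 20.0)
        ax = plot_threshold_slice(f, depth=0.0)
        assert ax.get_images()
        ax2 = iso_threshold_contours([f, f], amplitudes=(2.0, 3.0))
        assert ax2 is not None
        df = pd.DataFrame({"amplitude": [1.0, 2.0], "ratio": [1.5, 2.0],
                           "value": [10.0, 10.0]})
        ax3 = plot_ratio_curves(df)
        ax3.figure.savefig(tmp_path / "curves.png")
        matplotlib.pyplot.close("all")


class TestConfig:
    def test_load_config(self, tmp_path):
        p = tmp_path / "study.yaml"
        p.write_text(
            "fiber_diameter: 14.0\n"
            "cathodic_width: 100.0\n"
            "resistivities: {rho_x: 1300.0, rho_y: 1300.0, rho_z: 150.0}\n"
            "electrodes:\n  - [0, 0, 0]\n  - [400, 200, 800]\n"
            "search: {accuracy: 0.2, amplitude_max: 20.0}\n"
            "solver: {dt: 2.5}\n")
        cfg = load_config(p)
        assert cfg.fiber_diameter == 14.0
        assert cfg.waveform.cathodic_width == 100.0
        assert cfg.waveform.anodic_width == 200.0
        assert cfg.rho.rho_z == 150.0
        assert len(cfg.electrodes) == 2
        assert cfg.settings.amplitude_max == 20.0
        assert cfg.solver.dt == 2.5


class TestCli:
    def test_surrogate_grid_vta_and_report(self, tmp_path):
        runner = CliRunner()
        cfgf = tmp_path / "c.yaml"
        cfgf.write_text("fiber_diameter: 14.0\nelectrodes:\n"
                        "  - [0, 0, 0]\n  - [0, 0, 0]\n")
        for cond, name in [("sync", "gs"), ("single:0", "g0"), ("single:1", "g1")]:
            res = runner.invoke(cli_main, [
                "grid", "--config", str(cfgf), "--surrogate",
                "--origin", "-200", "-200", "-200",
                "--shape", "21", "21", "21", "--step", "20", "20", "20",
                "--condition", cond, "--out", str(tmp_path / name)])
            assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, [
            "vta", "--sync", str(tmp_path / "gs"),
            "--single", str(tmp_path / "g0"), "--single", str(tmp_path / "g1"),
            "--amplitudes", "2:5:1", "--out", str(tmp_path / "curve.csv")])
        assert res.exit_code == 0, res.output
        df = pd.read_csv(tmp_path / "curve.csv")
        assert {"amplitude", "sync_volume", "async_volume", "ratio"} <= set(df.columns)
        # co-located surrogate pair: ratio above 1 wherever defined
        assert np.all(df["ratio"].dropna() >= 1.0)

        df["pairing"] = "colocated"
        df["value"] = 0.0
        sweep_csv = tmp_path / "sweep.csv"
        df.to_csv(sweep_csv, index=False)
        res = runner.invoke(cli_main, ["report", "--csv", str(sweep_csv)])
        assert res.exit_code == 0, res.output
        assert "max" in res.output
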