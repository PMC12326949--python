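"""Fixture round-trips, the model facade, manifests and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from telefire import (PipelineConfig, PlantedPathway, TeleconnectionFireModel,
                      WorldConfig, generate_world, run_pipeline)
from telefire.cli import main as cli_main
from telefire.io import read_cube, read_fixture, read_indices, write_fixture


@pytest.fixture(scope="module")
def small_world():
    mask = np.ones((5, 5), bool)
    mask[0, 0] = False
    return generate_world(WorldConfig(n_years=8, grid_shape=(5, 5), n_tcms=2,
                                      burnable_mask=mask, seed=42))


class TestFixtureRoundTrip:
    def test_arrays_survive_exactly(self, small_world, tmp_path):
        write_fixture(small_world, tmp_path / "fx")
        back = read_fixture(tmp_path / "fx")
        assert np.array_equal(back.ba.values, small_world.ba.values, equal_nan=True)
        for name, grid in small_world.mediators.items():
            assert np.array_equal(back.mediators[name].values, grid.values,
                                  equal_nan=True)
        for a, b in zip(back.indices, small_world.indices):
            assert a.name == b.name and np.array_equal(a.values, b.values)
        assert back.config.seed == small_world.config.seed

    def test_mask_round_trip(self, small_world, tmp_path):
        write_fixture(small_world, tmp_path / "fx")
        back = read_fixture(tmp_path / "fx")
        assert np.array_equal(back.mask, small_world.mask)
        assert np.isnan(back.ba.values[:, 0, 0]).all()

    def test_missing_time_coordinate_errors(self, tmp_path):
        import xarray as xr
        p = tmp_path / "bad.nc"
        xr.Dataset({"BA": (("a", "b"), np.zeros((2, 2)))}).to_netcdf(p)
        with pytest.raises(ValueError, match="time"):
            read_cube(p)

    def test_gap_in_time_axis_errors(self, small_world, tmp_path):
        import xarray as xr
        write_fixture(small_world, tmp_path / "fx")
        with xr.open_dataset(tmp_path / "fx" / "cubes.nc") as ds:
            broken = ds.isel(time=[0, 1, 2, 5, 6])
            broken.to_netcdf(tmp_path / "gap.nc")
        with pytest.raises(ValueError, match="cadence|missing months"):
            read_cube(tmp_path / "gap.nc")

    def test_unknown_index_column_warned_and_carried(self, tmp_path):
        df = pd.DataFrame({"time": ["2003-01", "2003-02"], "ENSO": [0.1, 0.2],
                           "MYSTERY": [1.0, 2.0]})
        df.to_csv(tmp_path / "idx.csv", index=False)
        with pytest.warns(UserWarning, match="MYSTERY"):
            series = read_indices(tmp_path / "idx.csv")
        assert {s.name for s in series} == {"ENSO", "MYSTERY"}


class TestModelFacade:
    def test_misaligned_time_axis_names_offender(self, small_world):
        bad = generate_world(WorldConfig(n_years=8, grid_shape=(5, 5), n_tcms=2,
                                         start_year=2010, seed=1,
                                         burnable_mask=small_world.mask))
        with pytest.raises(ValueError, match="Tmax"):
            TeleconnectionFireModel(small_world.ba, {"Tmax": bad.mediators["Tmax"]},
                                    small_world.indices)

    def test_excessive_max_lag_rejected(self, small_world):
        with pytest.raises(ValueError, match="max_lag"):
            TeleconnectionFireModel(small_world.ba, small_world.mediators,
                                    small_world.indices,
                                    config=PipelineConfig(max_lag=90))

    def test_stage_toggle_skips_later_outputs(self, small_world, tmp_path):
        cfg = PipelineConfig(stages=("predictability",), seed=1)
        res = TeleconnectionFireModel.from_world(small_world, cfg).fit()
        assert res.predictability is not None
        assert res.hotspot_map is None and res.lag_profiles is None
        res.save(tmp_path / "out")
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert "hotspots" in manifest["skipped"]
        assert "predictability.csv" in manifest["files"]

    def test_rerun_same_seed_identical_artifacts(self, small_world, tmp_path):
        cfg = PipelineConfig(stages=("predictability",))
        for d in ("a", "b"):
            run_pipeline(small_world, cfg, outdir=tmp_path / d, seed=9)
        ma = json.loads((tmp_path / "a" / "manifest.json").read_text())
        mb = json.loads((tmp_path / "b" / "manifest.json").read_text())
        assert ma["files"] == mb["files"]

    def test_summary_mentions_key_quantities(self, planted_results):
        text = planted_results.summary()
        assert "Predictable-area fraction" in text
        assert "Hot spots" in text


@pytest.fixture(scope="module")
def planted_results():
    pw = PlantedPathway(0, "SM", ((2, 6), (2, 6)), 4, 6, strength=2.0)
    world = generate_world(WorldConfig(n_years=22, grid_shape=(10, 10), n_tcms=2,
                                       pathway_specs=[pw], seed=77))
    return TeleconnectionFireModel.from_world(
        world, PipelineConfig(seed=5)).fit()


class TestEndToEndRecovery:
    def test_hot_region_overlaps_planted_region(self, planted_results):
        assert planted_results.regions
        truth = {(r, c) for r in range(2, 6) for c in range(2, 6)}
        got = set(planted_results.regions[0].cells)
        assert len(truth & got) / len(truth | got) >= 0.3

    def test_dominant_mediator_is_planted(self, planted_results):
        dom = planted_results.contributions.dominance
        row = dom[(dom.region_id == 1) & (dom.tcm == "AO")].iloc[0]
        assert row.dominant_mediator == "SM"
        assert row.dominant_group_sum == "fuel"

    def test_lag_profile_peaks_at_total_lag(self, planted_results):
        prof = [p for p in planted_results.lag_profiles
                if p.region_id == 1 and p.tcm == "AO"][0]
        assert int(np.argmax(prof.weight)) == 10

    def test_combined_model_not_worse_than_best_single(self, planted_results):
        df = planted_results.multi_tcm.dropna()
        ok = (df.combined_r2 >= df.best_single_r2 - 0.25).mean()
        assert ok >= 0.7


class TestCli:
    def test_simulate_then_run(self, tmp_path):
        runner = CliRunner()
        fx = tmp_path / "fx"
        r = runner.invoke(cli_main, [
            "simulate", "--out", str(fx), "--seed", "3", "--n-years", "8",
            "--grid", "5", "5", "--n-tcms", "1"])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, [
            "predictability", "--fixture", str(fx), "--seed", "1",
            "--out", str(tmp_path / "res")])
        assert r.exit_code == 0, r.output
        assert "Predictable-area fraction" in r.output
        assert (tmp_path / "res" / "manifest.json").exists()
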