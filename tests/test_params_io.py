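import pandas as pd
import pytest
import yaml

from landghg.params_io import (
    ParameterError,
    Prescription,
    RunConfig,
    Scenario,
    load_parameters,
    load_scenario,
    materialize_case,
    write_scenario,
)


class TestLoadParameters:
    def test_fixture_directory_loads_with_documented_defaults(self, params):
        assert params.severity.high_start == 0.26
        assert params.severity.medium_start == 0.29
        assert params.severity.low_start == 0.45
        assert params.severity.high_increment == 0.0027
        assert params.gwp.ch4 == 25.0
        assert params.gwp.bc == 900.0
        assert params.practices["clearcut"].slash_burn_frac == 0.25
        assert params.practices["prescribed_burn"].slash_burn_frac == 1.0

    def test_out_of_range_speciation_rejected(self, params_dir, tmp_path):
        import shutil
        bad = tmp_path / "bad"
        shutil.copytree(params_dir, bad)
        spec = pd.read_csv(bad / "speciation.csv")
        spec.loc[0, "ch4_share"] = 1.2
        spec.to_csv(bad / "speciation.csv", index=False)
        with pytest.raises(ParameterError, match="ch4_share"):
            load_parameters(bad)

    def test_nonzero_ice_delta_rejected(self, params_dir, tmp_path):
        import shutil
        bad = tmp_path / "ice"
        shutil.copytree(params_dir, bad)
        tbl = pd.read_csv(bad / "lulcc_land_use_driven.csv")
        tbl.loc[0, "land_type"] = "Ice"
        tbl.loc[0, "delta_ha_yr"] = 5.0
        tbl.to_csv(bad / "lulcc_land_use_driven.csv", index=False)
        with pytest.raises(ParameterError, match="Ice"):
            load_parameters(bad)

    def test_unknown_rate_category_rejected(self, params_dir, tmp_path):
        import shutil
        bad = tmp_path / "cat"
        shutil.copytree(params_dir, bad)
        tbl = pd.read_csv(bad / "rates.csv")
        tbl.loc[0, "region"] = "Atlantis"
        tbl.to_csv(bad / "rates.csv", index=False)
        with pytest.raises(ParameterError, match="unknown category"):
            load_parameters(bad)


class TestLoadScenario:
    def test_control_scenario_has_no_disturbance(self, scenario_files, params):
        s = load_scenario(scenario_files["ecosystem_control"], params.practices)
        assert s.prescriptions == []
        assert not s.wildfire_on
        assert s.lulcc_option == "none"

    def test_repeat_intervals_make_distinct_scenarios(self, tmp_path):
        for interval in (10, 30):
            doc = {"name": f"compost_{interval}", "prescriptions": [
                {"practice": "compost", "annual_area_ha": 100.0,
                 "repeat_interval": interval}]}
            path = tmp_path / f"s{interval}.yaml"
            path.write_text(yaml.safe_dump(doc))
            s = load_scenario(path)
            assert s.prescriptions[0].repeat_interval == interval

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        with pytest.raises(ParameterError, match="empty"):
            load_scenario(path)

    def test_unknown_practice_rejected(self, tmp_path, params):
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump({
            "name": "bad",
            "prescriptions": [{"practice": "terraforming",
                               "annual_area_ha": 1.0}]}))
        with pytest.raises(ParameterError, match="unknown practice"):
            load_scenario(path, params.practices)

    def test_defaults_fill_missing_options(self, tmp_path):
        path = tmp_path / "min.yaml"
        path.write_text(yaml.safe_dump({"name": "minimal"}))
        s = load_scenario(path)
        assert s.wildfire_on and s.nonregen_on and s.bc_as_co2
        assert s.mortality_doubling == (2015, 2024)

    def test_scenario_round_trip(self, tmp_path):
        scenario = Scenario(
            name="rt",
            prescriptions=[Prescription("thinning", 120.0, 2012, 2040, 5,
                                        ("R1",), ("O2",))],
            lulcc_option="remote_sensing", wildfire_on=False)
        path = tmp_path / "rt.yaml"
        write_scenario(scenario, path)
        back = load_scenario(path)
        assert back == scenario


class TestRunConfig:
    def test_rejects_inverted_years(self):
        with pytest.raises(ValueError):
            RunConfig(start_year=2050, end_year=2010)

    def test_rejects_horizon_past_2100(self):
        with pytest.raises(ValueError):
            RunConfig(start_year=2010, end_year=2150)


class TestMaterializeCase:
    def test_mean_case_is_identity(self, params):
        out = materialize_case(params, "mean")
        pd.testing.assert_frame_equal(out.initial, params.initial)
        pd.testing.assert_frame_equal(out.rates, params.rates)

    def test_high_emission_offsets(self):
        initial = pd.DataFrame([{"region": "R1", "ownership": "O1",
                                 "land_type": "Forest", "area_ha": 1.0,
                                 "above_main_mean": 100.0, "above_main_sd": 30.0}])
        rates = pd.DataFrame(
            {"veg_mean": [2.0], "veg_sd": [3.0],
             "soil_mean": [0.5], "soil_sd": [0.1]},
            index=pd.MultiIndex.from_tuples(
                [("R1", "O1", "Forest")],
                names=["region", "ownership", "land_type"]))
        import dataclasses
        base = dataclasses.replace(
            _minimal_params(), initial=initial, rates=rates)
        out = materialize_case(base, "high_emission")
        assert out.initial["above_main_mean"].iloc[0] == pytest.approx(130.0)
        # accumulation may go negative: fluxes can be sources
        assert out.rates["veg_mean"].iloc[0] == pytest.approx(-1.0)

    def test_density_floored_at_zero(self):
        initial = pd.DataFrame([{"region": "R1", "ownership": "O1",
                                 "land_type": "Forest", "area_ha": 1.0,
                                 "soil_mean": 10.0, "soil_sd": 30.0}])
        import dataclasses
        base = dataclasses.replace(_minimal_params(), initial=initial)
        out = materialize_case(base, "low_emission")
        assert out.initial["soil_mean"].iloc[0] == 0.0


def _minimal_params():
    from landghg.ghg_accounting import GwpSet
    from landghg.management import ProductParams
    from landghg.params_io import ParameterSet
    from landghg.wildfire import SeveritySchedule
    idx = pd.MultiIndex.from_tuples(
        [("R1", "O1", "Forest")], names=["region", "ownership", "land_type"])
    return ParameterSet(
        regions=["R1"], ownerships=["O1"], land_types=["Forest"],
        initial=pd.DataFrame([{"region": "R1", "ownership": "O1",
                               "land_type": "Forest", "area_ha": 1.0}]),
        rates=pd.DataFrame({"veg_mean": [0.0], "veg_sd": [0.0],
                            "soil_mean": [0.0], "soil_sd": [0.0]}, index=idx),
        allocation={}, mortality=pd.Series(0.0, index=idx),
        practices={}, burn_area=pd.Series(dtype=float),
        fire_effects=pd.DataFrame(
            columns=["combusted_frac", "transfer_frac"]),
        severity=SeveritySchedule(), nonregen_fraction=0.0, lulcc={},
        dispositions={}, products=ProductParams({"c": 10.0}, {"c": 1.0}),
        speciation=pd.DataFrame({"pathway": [], "ch4_share": [],
                                 "bc_share": []}).set_index("pathway"),
        gwp=GwpSet())


class TestWriteOutputs:
    def test_rerun_is_byte_identical(self, params, scenario_files, tmp_path):
        from landghg.engine import run_scenario
        from landghg.params_io import load_scenario, write_outputs
        s = load_scenario(scenario_files["ecosystem_control"], params.practices)
        cfg = RunConfig(2010, 2014, "mean", 3)
        for d in ("a", "b"):
            out = run_scenario(params, s, cfg)
            write_outputs(out, cfg, tmp_path / d)
        for name in ("stocks.csv", "emissions.csv", "fluxes.csv",
                     "diagnostics.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_emissions_co2eq_recomputable(self, params, scenario_files,
                                          tmp_path):
        from landghg.engine import run_scenario
        from landghg.ghg_accounting import co2eq
        from landghg.params_io import load_scenario, write_outputs
        s = load_scenario(scenario_files["baseline"], params.practices)
        cfg = RunConfig(2010, 2013, "mean", 3)
        out = run_scenario(params, s, cfg)
        write_outputs(out, cfg, tmp_path / "r")
        df = pd.read_csv(tmp_path / "r" / "emissions.csv")
        for row in df.itertuples():
            assert row.co2eq_Mg == pytest.approx(
                co2eq(row.co2_Mg, row.ch4_Mg, row.bc_Mg, params.gwp),
                rel=1e-9)
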