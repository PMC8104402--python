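import pandas as pd
import pytest

from landghg.land_state import build_categories, total_carbon
from landghg.lulcc import (
    ALL_DECAY,
    CARRY_ALL,
    ConversionDisposition,
    apply_baseline_lulcc,
    apply_restoration,
    avoided_conversion,
    conversion_carbon,
    linear_ramp,
    urban_forest_area,
)

TYPES = ["Forest", "Shrubland", "Grassland", "Meadow", "Urban", "Cultivated",
         "Fresh_Marsh", "Woodland"]


def _state(areas: dict[str, float], densities: dict[str, dict] | None = None):
    rows = []
    for lt in TYPES:
        row = {"region": "R1", "ownership": "O1", "land_type": lt,
               "area_ha": areas.get(lt, 0.0)}
        row.update((densities or {}).get(lt, {}))
        rows.append(row)
    return build_categories(["R1"], ["O1"], TYPES, pd.DataFrame(rows))


def _deltas(vals: dict[str, float]) -> pd.Series:
    idx = pd.MultiIndex.from_tuples(
        [("R1", "O1", lt) for lt in TYPES],
        names=["region", "ownership", "land_type"])
    return pd.Series([vals.get(lt, 0.0) for lt in TYPES], index=idx)


class TestBaselineLulcc:
    def test_zero_deltas_unchanged(self):
        state = _state({"Forest": 100.0, "Grassland": 50.0})
        before = state.df.copy()
        apply_baseline_lulcc(state, _deltas({}), {}, 2010)
        pd.testing.assert_frame_equal(state.df, before)

    def test_loss_floored_at_zero_area(self):
        state = _state({"Grassland": 100.0, "Urban": 10.0},
                       {"Grassland": {"soil": 5.0}})
        apply_baseline_lulcc(
            state, _deltas({"Grassland": -130.0, "Urban": 130.0}),
            {("*", "*"): ALL_DECAY}, 2010)
        assert state.df.at[("R1", "O1", "Grassland"), "area_ha"] == \
            pytest.approx(0.0)

    def test_carbon_conserved_through_conversion(self):
        state = _state({"Grassland": 200.0, "Urban": 50.0, "Shrubland": 100.0},
                       {"Grassland": {"soil": 40.0, "above_main": 2.0},
                        "Shrubland": {"soil": 50.0, "above_main": 12.0},
                        "Urban": {"soil": 30.0, "above_main": 20.0}})
        before = total_carbon(state)
        flows = apply_baseline_lulcc(
            state, _deltas({"Grassland": -30.0, "Shrubland": -20.0,
                            "Urban": 50.0}),
            {("*", "*"): ALL_DECAY}, 2010)
        lost = flows.burned + flows.decayed + flows.to_products
        assert total_carbon(state) + lost == pytest.approx(before, rel=1e-9)
        # area conserved within the region-ownership
        assert state.df["area_ha"].sum() == pytest.approx(350.0)


class TestRestoration:
    def test_availability_caps_target(self):
        state = _state({"Grassland": 4.0, "Shrubland": 4.0, "Meadow": 0.0})
        demands = [("meadow", "Meadow", ("Grassland", "Shrubland"), 10.0)]
        result, _ = apply_restoration(state, "R1", "O1", demands,
                                      {("*", "*"): ALL_DECAY})
        assert result.realized["meadow"] == pytest.approx(8.0)
        assert result.shortfall["meadow"] == pytest.approx(2.0)

    def test_competing_demands_share_proportionally(self):
        state = _state({"Grassland": 6.0, "Meadow": 0.0, "Woodland": 0.0})
        demands = [("meadow", "Meadow", ("Grassland",), 6.0),
                   ("woodland", "Woodland", ("Grassland",), 6.0)]
        result, _ = apply_restoration(state, "R1", "O1", demands,
                                      {("*", "*"): ALL_DECAY})
        assert result.realized["meadow"] == pytest.approx(3.0)
        assert result.realized["woodland"] == pytest.approx(3.0)

    def test_fresh_marsh_grows_from_zero(self):
        state = _state({"Cultivated": 50.0, "Fresh_Marsh": 0.0},
                       {"Cultivated": {"soil": 50.0, "above_main": 5.0}})
        demands = [("marsh", "Fresh_Marsh", ("Cultivated",), 10.0)]
        result, _ = apply_restoration(state, "R1", "O1", demands,
                                      {("*", "*"): ALL_DECAY})
        assert result.realized["marsh"] == pytest.approx(10.0)
        assert state.df.at[("R1", "O1", "Fresh_Marsh"), "area_ha"] == \
            pytest.approx(10.0)


class TestAvoidedConversion:
    def test_unit_multiplier_is_identity(self):
        deltas = _deltas({"Urban": 80.0, "Grassland": -50.0,
                          "Cultivated": -30.0})
        adjusted = avoided_conversion(deltas, 1.0)
        pd.testing.assert_series_equal(adjusted, deltas)

    def test_linear_ramp_midpoint(self):
        # ramp 1.0 at 2019 to 0.5 at 2050; 2034/2035 straddle ~0.75
        assert linear_ramp(2034, 2019, 2050, 1.0, 0.5) == pytest.approx(
            0.758, abs=1e-3)
        assert linear_ramp(2019, 2019, 2050, 1.0, 0.5) == 1.0
        assert linear_ramp(2060, 2019, 2050, 1.0, 0.5) == 0.5

    def test_foregone_urban_gain_returned_to_sources(self):
        deltas = _deltas({"Urban": 80.0, "Grassland": -50.0,
                          "Cultivated": -30.0})
        adjusted = avoided_conversion(deltas, 0.5)
        assert adjusted[("R1", "O1", "Urban")] == pytest.approx(40.0)
        # conservation: total delta sum unchanged
        assert adjusted.sum() == pytest.approx(deltas.sum())
        # returned proportionally to baseline losses (50:30)
        assert adjusted[("R1", "O1", "Grassland")] == pytest.approx(
            -50.0 + 40.0 * 50.0 / 80.0)


class TestConversionCarbon:
    def test_same_type_is_noop(self):
        state = _state({"Forest": 10.0})
        flows = conversion_carbon(state, "R1", "O1", "Forest", "Forest", 5.0,
                                  CARRY_ALL)
        assert flows.decayed == flows.burned == flows.to_products == 0.0

    def test_all_decay_disposition(self):
        state = _state({"Shrubland": 10.0, "Meadow": 0.0},
                       {"Shrubland": {"above_main": 20.0}})
        flows = conversion_carbon(state, "R1", "O1", "Shrubland", "Meadow",
                                  1.0, ALL_DECAY)
        assert flows.decayed == pytest.approx(20.0)
        assert state.df.at[("R1", "O1", "Meadow"), "area_ha"] == 1.0

    def test_afforestation_carries_biomass(self):
        state = _state({"Grassland": 10.0, "Forest": 10.0},
                       {"Grassland": {"soil": 40.0, "above_main": 2.0},
                        "Forest": {"soil": 80.0, "above_main": 90.0}})
        flows = conversion_carbon(state, "R1", "O1", "Grassland", "Forest",
                                  2.0, CARRY_ALL)
        assert flows.decayed == flows.burned == flows.to_products == 0.0

    def test_mass_balance_closes(self):
        dens = {"Shrubland": {"soil": 50.0, "above_main": 12.0, "root": 6.0,
                              "litter": 1.0},
                "Meadow": {"soil": 90.0, "above_main": 3.0}}
        state = _state({"Shrubland": 30.0, "Meadow": 5.0}, dens)
        before = total_carbon(state)
        disp = ConversionDisposition(burn_frac=0.25, decay_frac=0.5,
                                     product_frac=0.1)
        flows = conversion_carbon(state, "R1", "O1", "Shrubland", "Meadow",
                                  12.0, disp)
        removed = flows.burned + flows.decayed + flows.to_products
        assert total_carbon(state) + removed == pytest.approx(before, rel=1e-9)


class TestUrbanForest:
    def test_statewide_fraction_arithmetic(self):
        # 14.4% of 2,786,367 ha of urban land is ~401,237 ha of urban forest
        assert urban_forest_area(2_786_367.0, 0.144) == pytest.approx(
            401_236.91, abs=1.0)

    def test_expansion_fraction_monotone(self):
        fracs = [linear_ramp(y, 2010, 2050, 0.144, 0.209)
                 for y in range(2010, 2052)]
        assert fracs == sorted(fracs)
        assert fracs[0] == 0.144 and fracs[-1] == pytest.approx(0.209)
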