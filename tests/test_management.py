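import pandas as pd
import pytest
from hypothesis import given, strategies as st

from landghg.land_state import ProductPools, build_categories, total_carbon
from landghg.management import (
    PracticeDefinition,
    PracticeEffectLedger,
    ProductParams,
    active_adjustments,
    apply_practice,
    partition_slash,
    schedule_management,
    wood_products_step,
)
from landghg.params_io import Prescription

KEY = ("R1", "O1", "Forest")


def _forest_state(area, above):
    tbl = pd.DataFrame([{"region": "R1", "ownership": "O1",
                         "land_type": "Forest", "area_ha": area,
                         "above_main": above}])
    return build_categories(["R1"], ["O1"], ["Forest"], tbl)


class TestScheduleManagement:
    def _practices(self):
        return {"thin": PracticeDefinition(name="thin", land_types=("Forest",))}

    def test_proportional_split(self):
        areas = pd.Series({("R1", "O1", "Forest"): 300.0,
                           ("R2", "O1", "Forest"): 100.0})
        plan, short = schedule_management(
            [Prescription("thin", 100.0)], areas, self._practices(), 2010)
        got = {k: a for k, _, a in plan}
        assert got[("R1", "O1", "Forest")] == pytest.approx(75.0)
        assert got[("R2", "O1", "Forest")] == pytest.approx(25.0)
        assert not short

    def test_shortfall_when_target_exceeds_area(self):
        areas = pd.Series({KEY: 50.0})
        plan, short = schedule_management(
            [Prescription("thin", 80.0)], areas, self._practices(), 2010)
        assert plan[0][2] == pytest.approx(50.0)
        assert short["thin"] == pytest.approx(30.0)

    @pytest.mark.parametrize("year,fires", [
        (2010, True), (2015, False), (2020, True), (2030, True), (2031, False)])
    def test_repeat_interval_schedule(self, year, fires):
        areas = pd.Series({KEY: 100.0})
        plan, _ = schedule_management(
            [Prescription("thin", 10.0, start_year=2010, repeat_interval=10)],
            areas, self._practices(), year)
        assert bool(plan) is fires

    def test_no_eligible_category_reports_shortfall(self):
        areas = pd.Series({("R1", "O1", "Grassland"): 100.0})
        plan, short = schedule_management(
            [Prescription("thin", 10.0)], areas, self._practices(), 2010)
        assert plan == [] and short["thin"] == 10.0


class TestApplyPractice:
    def test_zero_removal_is_noop(self):
        state = _forest_state(100.0, 100.0)
        practice = PracticeDefinition(name="null", removal={})
        state, harvest, slash = apply_practice(state, KEY, practice, 10.0, 2010)
        assert harvest == 0.0 and slash == 0.0
        assert state.df.at[KEY, "above_main"] == 100.0

    def test_hand_mass_balance(self):
        # 10 ha of 100 ha at 100 Mg C/ha, removal 0.5 all to harvest:
        # harvest 500, merged density (90*100 + 10*50)/100 = 95
        state = _forest_state(100.0, 100.0)
        practice = PracticeDefinition(
            name="cut", removal={"above_main": 0.5}, harvest_frac=1.0)
        state, harvest, slash = apply_practice(state, KEY, practice, 10.0, 2010)
        assert harvest == pytest.approx(500.0)
        assert slash == 0.0
        assert state.df.at[KEY, "above_main"] == pytest.approx(95.0)

    def test_conserves_carbon(self):
        state = _forest_state(80.0, 120.0)
        state.df.at[KEY, "understory"] = 10.0
        state.df.at[KEY, "litter"] = 5.0
        before = total_carbon(state)
        practice = PracticeDefinition(
            name="thin", removal={"above_main": 0.3, "understory": 0.5,
                                  "litter": 0.2}, harvest_frac=0.6)
        state, harvest, slash = apply_practice(state, KEY, practice, 20.0, 2010)
        assert total_carbon(state) + harvest + slash == pytest.approx(
            before, rel=1e-9)

    def test_area_exceeding_category_raises(self):
        state = _forest_state(10.0, 100.0)
        practice = PracticeDefinition(name="cut", removal={"above_main": 0.5})
        with pytest.raises(Exception, match="exceeds"):
            apply_practice(state, KEY, practice, 20.0, 2010)


class TestPartitionSlash:
    def test_default_burn_decay_split(self):
        practice = PracticeDefinition(name="thin", slash_burn_frac=0.25)
        parts = partition_slash(100.0, practice)
        assert parts["burned"] == pytest.approx(25.0)
        assert parts["decayed"] == pytest.approx(75.0)

    def test_prescribed_burn_burns_everything(self):
        practice = PracticeDefinition(name="rx", slash_burn_frac=1.0)
        parts = partition_slash(100.0, practice)
        assert parts["burned"] == pytest.approx(100.0)
        assert parts["decayed"] == 0.0

    def test_zero_slash(self):
        practice = PracticeDefinition(name="thin")
        assert all(v == 0.0 for v in partition_slash(0.0, practice).values())

    @given(st.floats(0.0, 1e6), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_components_sum_to_input(self, slash, burn, collect):
        practice = PracticeDefinition(
            name="x", slash_burn_frac=burn, slash_collect_frac=collect)
        parts = partition_slash(slash, practice)
        assert sum(parts.values()) == pytest.approx(slash, rel=1e-12, abs=1e-12)


class TestWoodProducts:
    PARAMS = ProductParams(half_lives={"short": 10.0, "long": 50.0},
                           inflow_shares={"short": 0.5, "long": 0.5})

    def test_empty_pools_zero_inflow(self):
        pools, emitted = wood_products_step(ProductPools(), 0.0, self.PARAMS)
        assert emitted == 0.0 and pools.total_stored() == 0.0

    def test_landfill_decay_rate(self):
        params = ProductParams(half_lives={"c": 10.0}, inflow_shares={"c": 1.0},
                               landfill_decay_rate=0.5)
        pools = ProductPools(landfill=100.0)
        pools, emitted = wood_products_step(pools, 0.0, params)
        assert emitted == pytest.approx(50.0)
        assert pools.landfill == pytest.approx(50.0)

    def test_multi_year_mass_ledger(self):
        """Cumulative inflow equals stored change plus emitted carbon."""
        pools = ProductPools()
        inflows = [100.0, 50.0, 0.0, 20.0, 80.0, 0.0, 10.0, 5.0, 0.0, 40.0]
        emitted_total = 0.0
        for inflow in inflows:
            pools, emitted = wood_products_step(pools, inflow, self.PARAMS)
            emitted_total += emitted
        assert pools.total_stored() + emitted_total == pytest.approx(
            sum(inflows), rel=1e-9)

    def test_half_life_halves_stock(self):
        pools = ProductPools(in_use={"short": 1.0, "long": 0.0})
        for _ in range(10):
            pools, _ = wood_products_step(pools, 0.0, self.PARAMS)
        assert pools.in_use["short"] == pytest.approx(0.5, rel=1e-9)


class TestActiveAdjustments:
    def test_empty_ledger_identity(self):
        assert active_adjustments(PracticeEffectLedger(), KEY, 2020) == (
            1.0, 1.0, 0.0)

    def test_effect_expires_after_duration(self):
        ledger = PracticeEffectLedger()
        practice = PracticeDefinition(name="thin", growth_mult=1.1,
                                      growth_duration=20)
        ledger.add(KEY, practice, 2010, 10.0)
        g20, _, _ = active_adjustments(ledger, KEY, 2030)
        g21, _, _ = active_adjustments(ledger, KEY, 2031)
        assert g20 > 1.0 and g21 == 1.0

    def test_whole_category_multipliers_compose(self):
        ledger = PracticeEffectLedger()
        a = PracticeDefinition(name="a", growth_mult=1.1, growth_duration=20)
        b = PracticeDefinition(name="b", growth_mult=1.2, growth_duration=20)
        ledger.add(KEY, a, 2010, 10.0)
        ledger.add(KEY, b, 2012, 10.0)
        growth, _, _ = active_adjustments(ledger, KEY, 2015, category_area=10.0)
        assert growth == pytest.approx(1.1 * 1.2)

    def test_severity_shift_weighted_by_treated_share(self):
        ledger = PracticeEffectLedger()
        practice = PracticeDefinition(name="thin", severity_reduction=0.2,
                                      severity_duration=20)
        ledger.add(KEY, practice, 2010, 25.0)
        _, _, shift = active_adjustments(ledger, KEY, 2011, category_area=100.0)
        assert shift == pytest.approx(0.2 * 0.25)
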