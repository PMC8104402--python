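"""Annual simulation loop.

Each simulated year executes four processes in fixed order, committing the
carbon state after each: (1) net ecosystem exchange and mortality, (2)
management (biomass removal, slash disposition, wood products, bioenergy),
(3) wildfire (burn allocation, severity-specific combustion and transfer,
non-regeneration area), and (4) land conversion (baseline LULCC, avoided
conversion, restoration, non-regeneration execution). Every year closes a
global carbon ledger — the change in ecosystem plus product carbon must
equal the negated net emitted carbon — and a violation aborts the run.

The core loop is fully deterministic; stochasticity exists only in the
fixture generator and the divergence diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import ecosystem_flux, lulcc, management, wildfire
from .ecosystem_flux import AccumulationRates
from .ghg_accounting import EmissionLedger, GwpSet, co2eq
from .land_state import BURNABLE_TYPES, CarbonState, build_categories, total_carbon
from .lulcc import CARRY_ALL, ConversionFlows
from .management import PracticeEffectLedger
from .params_io import ParameterSet, RunConfig, Scenario, materialize_case

BALANCE_TOL = 1e-6


class ConservationError(RuntimeError):
    """Carbon or area budget failed to close during a run."""


@dataclass
class AnnualOutput:
    year: int
    stocks: pd.DataFrame
    fluxes: dict[str, float]
    emissions: pd.DataFrame
    realized_areas: dict[str, float]
    product_c: float
    diagnostics: dict[str, float]


def _initial_state(params: ParameterSet) -> CarbonState:
    tbl = params.initial.copy()
    return build_categories(params.regions, params.ownerships, params.land_types, tbl)


def _urban_fraction(scenario: Scenario, params: ParameterSet, year: int) -> float:
    uf = scenario.urban_forest
    base = params.urban_forest_base_fraction
    if not uf or uf.get("mode", "constant") == "constant":
        return float(uf.get("fraction", base)) if uf else base
    return lulcc.linear_ramp(
        year,
        int(uf.get("start_year", 2010)),
        int(uf.get("end_year", 2050)),
        float(uf.get("start_fraction", base)),
        float(uf.get("end_fraction", base)),
    )


def run_scenario(
    params: ParameterSet, scenario: Scenario, config: RunConfig
) -> list[AnnualOutput]:
    """Run one scenario; returns the per-year output series.

    Simulation years are calendar-labelled with state at year start; the
    default 2010-2051 span executes 41 years of dynamics.
    """
    p = materialize_case(params, config.uncertainty_case)
    state = _initial_state(p)
    gwp = GwpSet(params.gwp.co2, params.gwp.ch4, params.gwp.bc,
                 bc_as_co2=scenario.bc_as_co2)
    ledger = PracticeEffectLedger()
    emissions = EmissionLedger()
    base_rates = AccumulationRates(
        p.rates.rename(columns={"veg_mean": "veg", "soil_mean": "soil"})[
            ["veg", "soil"]],
        p.allocation,
    )
    deltas = None
    if scenario.lulcc_option != "none":
        if scenario.lulcc_option not in p.lulcc:
            raise ValueError(
                f"scenario requests LULCC option {scenario.lulcc_option!r} "
                "but no delta table was provided")
        deltas = p.lulcc[scenario.lulcc_option].set_index(
            ["region", "ownership", "land_type"])["delta_ha_yr"]

    outputs: list[AnnualOutput] = []
    for year in range(config.start_year, config.end_year):
        year_start_c = total_carbon(state)
        ro_areas_start = state.df["area_ha"].groupby(level=[0, 1]).sum()
        fluxes: dict[str, float] = {}
        realized_areas: dict[str, float] = {}
        ledger.prune(year)

        # --- process 1: net ecosystem exchange + mortality ----------------
        areas = state.df["area_ha"]
        growth_mult = pd.Series(1.0, index=state.df.index)
        mort_mult = pd.Series(1.0, index=state.df.index)
        sev_shift = pd.Series(0.0, index=state.df.index)
        if ledger.entries:
            for key in state.df.index:
                g, m, s = management.active_adjustments(
                    ledger, key, year, float(areas[key]))
                growth_mult[key], mort_mult[key], sev_shift[key] = g, m, s
        rates = ecosystem_flux.effective_rates(base_rates, None, growth_mult, year)
        # soil practices adjust the soil rate on their treated area
        if ledger.entries:
            for key in rates.table.index:
                adj = management.soil_rate_adjustment(ledger, key, year)
                if adj != 0.0 and areas[key] > 0:
                    rates.table.at[key, "soil"] += adj / float(areas[key])
        # urban forest fraction scales Urban vegetation accumulation
        frac = _urban_fraction(scenario, p, year)
        if frac != p.urban_forest_base_fraction and p.urban_forest_base_fraction > 0:
            urban_rows = rates.table.index.get_level_values("land_type") == "Urban"
            rates.table.loc[urban_rows, "veg"] *= frac / p.urban_forest_base_fraction
        state, uptake = ecosystem_flux.nee_step(state, rates, year)
        fluxes["nee_uptake_MgC"] = float(uptake.sum())
        emissions.add_co2_carbon(year, "nee", -float(uptake.sum()))
        # wetland soil CH4 (Fresh Marsh anaerobic decomposition)
        if p.fresh_marsh_ch4_rate > 0.0:
            fm = state.df.index.get_level_values("land_type") == "Fresh_Marsh"
            ch4_c = 0.0
            for key in state.df.index[fm]:
                area = float(state.df.at[key, "area_ha"])
                if area <= 0:
                    continue
                flux = min(p.fresh_marsh_ch4_rate,
                           float(state.df.at[key, "soil"])) * area
                state.df.at[key, "soil"] -= flux / area
                ch4_c += flux
            if ch4_c > 0.0:
                emissions.add_carbon(year, "wetland_soil", ch4_c, p.speciation)
        mort = p.mortality.reindex(state.df.index).fillna(0.0) * mort_mult
        mort = mort.clip(upper=1.0)
        state = ecosystem_flux.mortality_step(
            state, mort, year, scenario.mortality_doubling)

        # --- process 2: management ----------------------------------------
        active = [pr for pr in scenario.prescriptions
                  if p.practices.get(pr.practice) is not None
                  and p.practices[pr.practice].kind != "restoration"]
        plan, _short = management.schedule_management(
            active, state.df["area_ha"], p.practices, year)
        harvest_total = slash_total = product_inflow = bioenergy = 0.0
        slash_burned = slash_decayed = 0.0
        for key, practice, area in plan:
            state, harvest, slash = management.apply_practice(
                state, key, practice, area, year, ledger)
            parts = management.partition_slash(slash, practice)
            collected = parts["collected"]
            slash_burned += parts["burned"]
            slash_decayed += parts["decayed"]
            product_inflow += (harvest + collected) * practice.product_frac
            bioenergy += (harvest + collected) * (1.0 - practice.product_frac)
            harvest_total += harvest
            slash_total += slash
            realized_areas[practice.name] = realized_areas.get(practice.name, 0.0) + area
        if slash_burned > 0.0:
            emissions.add_carbon(year, "slash_burn", slash_burned, p.speciation)
        if slash_decayed > 0.0:
            emissions.add_co2_carbon(year, "slash_decay", slash_decayed)
        if bioenergy > 0.0:
            emissions.add_carbon(year, "bioenergy", bioenergy, p.speciation)
            state.products.bioenergy_emitted += bioenergy
        state.products, landfill_c = management.wood_products_step(
            state.products, product_inflow, p.products)
        if landfill_c > 0.0:
            emissions.add_carbon(year, "landfill", landfill_c, p.speciation)
        fluxes["harvest_MgC"] = harvest_total
        fluxes["slash_MgC"] = slash_total
        fluxes["product_inflow_MgC"] = product_inflow
        fluxes["bioenergy_MgC"] = bioenergy

        # --- process 3: wildfire ------------------------------------------
        burned_total = 0.0
        fire_c = 0.0
        nonregen: dict[tuple[str, str], float] = {}
        if scenario.wildfire_on and len(p.burn_area):
            for (region, own), burn_ha in p.burn_area.items():
                try:
                    type_areas = state.df.loc[(region, own)]["area_ha"]
                except KeyError:
                    continue
                burned, _cap = wildfire.allocate_burn(float(burn_ha), type_areas)
                for land_type, area_burned in burned.items():
                    if area_burned <= 0.0:
                        continue
                    key = (region, own, land_type)
                    sev = wildfire.severity_fractions(
                        p.severity, year, float(sev_shift.get(key, 0.0)))
                    emitted, hs_forest = wildfire.burn_step(
                        state, region, own,
                        pd.Series({land_type: area_burned}), sev, p.fire_effects)
                    fire_c += emitted
                    burned_total += area_burned
                    if hs_forest > 0.0:
                        area_conv = wildfire.nonregen_area(
                            hs_forest, p.nonregen_fraction, scenario.nonregen_on)
                        if area_conv > 0.0:
                            nonregen[(region, own)] = (
                                nonregen.get((region, own), 0.0) + area_conv)
            if fire_c > 0.0:
                emissions.add_carbon(year, "wildfire", fire_c, p.speciation)
        fluxes["wildfire_emitted_MgC"] = fire_c
        fluxes["burned_area_ha"] = burned_total

        # area closure: processes 1-3 must not change region-ownership areas
        ro_areas_mid = state.df["area_ha"].groupby(level=[0, 1]).sum()
        if not _areas_close(ro_areas_start, ro_areas_mid):
            raise ConservationError(
                f"area balance broken before conversion step, year {year}")

        # --- process 4: land conversion -----------------------------------
        conv = ConversionFlows()
        if deltas is not None:
            year_deltas = deltas
            ac = scenario.avoided_conversion
            if ac:
                mult = lulcc.linear_ramp(
                    year, int(ac.get("start_year", 2019)),
                    int(ac.get("end_year", 2050)),
                    float(ac.get("start_multiplier", 1.0)),
                    float(ac.get("end_multiplier", 0.5)))
                year_deltas = lulcc.avoided_conversion(deltas, mult)
            conv += lulcc.apply_baseline_lulcc(
                state, year_deltas, p.dispositions, year)
        # restoration prescriptions compete for sources region by region
        rest = [pr for pr in scenario.prescriptions
                if pr.active_in(year)
                and p.practices.get(pr.practice) is not None
                and p.practices[pr.practice].kind == "restoration"]
        if rest:
            conv, realized = _run_restoration(
                state, p, rest, conv, realized_areas)
        for (region, own), area_conv in sorted(nonregen.items()):
            key = (region, own, "Forest")
            avail = float(state.df.at[key, "area_ha"]) if key in state.df.index else 0.0
            area_conv = min(area_conv, avail)
            if area_conv > 0.0:
                disp = p.dispositions.get(("Forest", "Shrubland"), CARRY_ALL)
                conv += lulcc.conversion_carbon(
                    state, region, own, "Forest", "Shrubland", area_conv, disp)
                fluxes["nonregen_area_ha"] = (
                    fluxes.get("nonregen_area_ha", 0.0) + area_conv)
        if conv.burned > 0.0:
            emissions.add_carbon(year, "slash_burn", conv.burned, p.speciation)
        if conv.decayed > 0.0:
            emissions.add_co2_carbon(year, "conversion", conv.decayed)
        if conv.to_products > 0.0:
            for cls, share in p.products.inflow_shares.items():
                state.products.in_use[cls] = (
                    state.products.in_use.get(cls, 0.0) + conv.to_products * share)
        fluxes["conversion_cleared_MgC"] = conv.burned + conv.decayed + conv.to_products

        # --- yearly carbon ledger -----------------------------------------
        state.check_masks(f"in year {year}")
        year_end_c = total_carbon(state)
        net_emitted = emissions.net_carbon(year)
        residual = (year_end_c - year_start_c) + net_emitted
        scale = max(abs(year_start_c), abs(year_end_c), 1.0)
        if abs(residual) > BALANCE_TOL * scale:
            raise ConservationError(
                f"carbon balance residual {residual:.6g} Mg C in year {year} "
                f"({abs(residual) / scale:.2e} relative)")

        frame = emissions.to_frame(gwp)
        frame = frame[frame["year"] == year].reset_index(drop=True)
        outputs.append(AnnualOutput(
            year=year,
            stocks=state.df.copy(),
            fluxes=fluxes,
            emissions=frame,
            realized_areas=dict(realized_areas),
            product_c=state.products.total_stored(),
            diagnostics={
                "ecosystem_MgC": state.ecosystem_carbon(),
                "product_MgC": state.products.total_stored(),
                "net_emitted_MgC": net_emitted,
                "net_co2eq_Mg": float(frame["co2eq_Mg"].sum()),
                "balance_residual_MgC": residual,
                "urban_forest_ha": _urban_forest_total(state, frac),
            },
        ))
    return outputs


def _areas_close(a: pd.Series, b: pd.Series, tol: float = 1e-6) -> bool:
    a, b = a.align(b, fill_value=0.0)
    scale = a.abs().clip(lower=1.0)
    return bool(((a - b).abs() / scale <= tol).all())


def _urban_forest_total(state: CarbonState, fraction: float) -> float:
    rows = state.df.index.get_level_values("land_type") == "Urban"
    return float(state.df.loc[rows, "area_ha"].sum() * fraction)


def _run_restoration(state, p, prescriptions, conv, realized_areas):
    """Distribute restoration targets over region-ownerships and fulfil them."""
    df = state.df
    for region in p.regions:
        for own in p.ownerships:
            demands = []
            for pr in prescriptions:
                practice = p.practices[pr.practice]
                if pr.regions and region not in pr.regions:
                    continue
                if pr.ownerships and own not in pr.ownerships:
                    continue
                if practice.ownerships and own not in practice.ownerships:
                    continue
                if practice.regions and region not in practice.regions:
                    continue
                target = _restoration_share(
                    df, p, pr, practice, region, own)
                if target > 0.0:
                    demands.append((practice.name, practice.to_type,
                                    practice.sources, target))
            if not demands:
                continue
            result, flows = lulcc.apply_restoration(
                state, region, own, demands, p.dispositions)
            conv += flows
            for name, got in result.realized.items():
                realized_areas[name] = realized_areas.get(name, 0.0) + got
    return conv, realized_areas


def _restoration_share(df, p, pr, practice, region, own) -> float:
    """Share of a restoration target for one region-ownership, proportional
    to that cell's source-land availability."""
    def source_area(r, o):
        tot = 0.0
        for s in practice.sources:
            key = (r, o, s)
            if key in df.index:
                tot += float(df.at[key, "area_ha"])
        return tot

    cells = [(r, o) for r in (pr.regions or p.regions)
             for o in (pr.ownerships or p.ownerships)
             if (not practice.ownerships or o in practice.ownerships)
             and (not practice.regions or r in practice.regions)]
    total = sum(source_area(r, o) for r, o in cells)
    if total <= 0.0:
        return 0.0
    return pr.annual_area_ha * source_area(region, own) / total


def run_uncertainty_suite(
    params: ParameterSet, scenario: Scenario, config: RunConfig
) -> dict[str, list[AnnualOutput]]:
    """Run the mean, low-emission and high-emission cases of one scenario."""
    out = {}
    for case in ("mean", "low_emission", "high_emission"):
        cfg = RunConfig(config.start_year, config.end_year, case,
                        config.seed, config.output_dir)
        out[case] = run_scenario(params, scenario, cfg)
    return out


def emission_series(outputs: list[AnnualOutput]) -> pd.DataFrame:
    """Annual and cumulative net CO2eq series (Mg and MMT) from a run."""
    years = [o.year for o in outputs]
    annual = [o.diagnostics["net_co2eq_Mg"] for o in outputs]
    df = pd.DataFrame({"year": years, "annual_co2eq_Mg": annual}).set_index("year")
    df["cumulative_co2eq_Mg"] = df["annual_co2eq_Mg"].cumsum()
    df["annual_co2eq_MMT"] = df["annual_co2eq_Mg"] * 1e-6
    df["cumulative_co2eq_MMT"] = df["cumulative_co2eq_Mg"] * 1e-6
    return df
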