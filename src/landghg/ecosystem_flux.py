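"""Process 1: net ecosystem carbon exchange and mortality.

Net ecosystem exchange (NEE) is driven by empirical per-category rates: a
net vegetation carbon flux (Mg C ha^-1 yr^-1 of an undisturbed patch with
no mortality) allocated across live pools, and a net soil carbon density
change. Climate scalars and management growth multipliers scale the rates
multiplicatively. Mortality then transfers a fraction of live biomass to
dead pools (a pure within-land transfer), with rates doubled inside a
configurable elevated-mortality window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .land_state import CarbonState, LIVE_POOLS

#: default allocation of net vegetation accumulation across live pools;
#: renormalised over the pools present in each land type's mask
DEFAULT_ALLOCATION = {"above_main": 0.7, "root": 0.2, "understory": 0.1}

#: where dead biomass from each live pool goes on mortality
MORTALITY_ROUTING = {
    "above_main": "standing_dead",
    "root": "down_dead",
    "understory": "litter",
}


@dataclass
class AccumulationRates:
    """Effective per-category accumulation rates.

    ``table`` is indexed by (region, ownership, land_type) with columns
    ``veg`` and ``soil`` in Mg C ha^-1 yr^-1. ``allocation`` gives the split
    of the vegetation flux across live pools, per land type (falling back
    to :data:`DEFAULT_ALLOCATION`).
    """

    table: pd.DataFrame
    allocation: dict[str, dict[str, float]] = field(default_factory=dict)

    def allocation_for(self, land_type: str, mask) -> dict[str, float]:
        base = self.allocation.get(land_type, DEFAULT_ALLOCATION)
        present = {p: f for p, f in base.items() if p in mask and f > 0}
        if not present:
            # soil-only or canopy-only types: put everything above ground
            if "above_main" in mask:
                return {"above_main": 1.0}
            return {}
        tot = sum(present.values())
        return {p: f / tot for p, f in present.items()}


def effective_rates(
    rates: AccumulationRates,
    climate_scalars: pd.DataFrame | None,
    growth_multiplier: pd.Series | None,
    year: int,
) -> AccumulationRates:
    """Apply climate scalars and management growth multipliers for ``year``.

    ``climate_scalars`` (optional) is indexed like the rate table with
    columns ``year``, ``veg_scalar``, ``soil_scalar``; absent entries mean
    1.0. ``growth_multiplier`` (optional) is a per-category multiplier on
    the vegetation rate from active management effects.
    """
    table = rates.table.copy()
    if climate_scalars is not None and len(climate_scalars):
        sel = climate_scalars[climate_scalars["year"] == year]
        if len(sel):
            sel = sel.set_index(["region", "ownership", "land_type"])
            veg = sel["veg_scalar"].reindex(table.index).fillna(1.0)
            soil = sel["soil_scalar"].reindex(table.index).fillna(1.0)
            table["veg"] = table["veg"] * veg
            table["soil"] = table["soil"] * soil
    if growth_multiplier is not None:
        mult = growth_multiplier.reindex(table.index).fillna(1.0)
        table["veg"] = table["veg"] * mult
    return AccumulationRates(table, rates.allocation)


def nee_step(
    state: CarbonState, rates: AccumulationRates, year: int
) -> tuple[CarbonState, pd.Series]:
    """Advance live and soil pools one year; return per-category uptake.

    Uptake (Mg C) is the realised atmosphere-to-land flux: positive for net
    accumulation, negative for net loss. A decrement that would drive a
    density negative is clamped at zero and the unrealised loss reduces the
    reported uptake, so mass balance against the atmosphere always closes.
    """
    df = state.df
    uptake = pd.Series(0.0, index=df.index)
    tbl = rates.table
    for key in df.index[df["area_ha"].to_numpy() > 0]:
        if key not in tbl.index:
            continue
        area = df.at[key, "area_ha"]
        land_type = key[2]
        mask = state.mask_for(land_type)
        veg = float(tbl.at[key, "veg"])
        soil = float(tbl.at[key, "soil"])
        moved = 0.0
        if veg != 0.0:
            for pool, frac in rates.allocation_for(land_type, mask).items():
                delta = veg * frac
                new = df.at[key, pool] + delta
                if new < 0.0:
                    delta = -df.at[key, pool]
                    new = 0.0
                df.at[key, pool] = new
                moved += delta
        if soil != 0.0 and "soil" in mask:
            new = df.at[key, "soil"] + soil
            if new < 0.0:
                soil_delta = -df.at[key, "soil"]
                new = 0.0
            else:
                soil_delta = soil
            df.at[key, "soil"] = new
            moved += soil_delta
        uptake.at[key] = moved * area
    return state, uptake


def mortality_step(
    state: CarbonState,
    mortality: pd.Series,
    year: int,
    doubling_window: tuple[int, int] | None = None,
) -> CarbonState:
    """Transfer live biomass to dead pools at the annual mortality rate.

    ``mortality`` is a per-category fraction yr^-1 of live biomass. Inside
    ``doubling_window`` (inclusive years) the rate is doubled, capped at 1.
    Pure transfer: total carbon is conserved; routing follows
    :data:`MORTALITY_ROUTING`, skipping destinations absent from the mask
    (that biomass then stays live, as with herbaceous canopies).
    """
    df = state.df
    for key, rate in mortality.items():
        if key not in df.index:
            continue
        rate = float(rate)
        if doubling_window and doubling_window[0] <= year <= doubling_window[1]:
            rate = min(1.0, 2.0 * rate)
        if rate <= 0.0 or df.at[key, "area_ha"] <= 0.0:
            continue
        mask = state.mask_for(key[2])
        for live in LIVE_POOLS:
            if live not in mask:
                continue
            dest = MORTALITY_ROUTING[live]
            if dest not in mask:
                continue
            moved = df.at[key, live] * rate
            df.at[key, live] -= moved
            df.at[key, dest] += moved
    return state
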