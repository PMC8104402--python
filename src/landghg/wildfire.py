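"""Process 3: wildfire.

Annual burn area is prescribed per region-ownership (constant under
historical climate) and distributed proportionally across the five burnable
land types (Forest, Woodland, Savanna, Shrubland, Grassland) by their
current areas. Burned area is split into high/medium/low severity classes
whose fractions evolve linearly over time (high severity rising, low
severity absorbing the change) and can be shifted down by recent fuel
treatments. Severity- and pool-specific fractions of carbon are combusted
(speciated into CO2/CH4/BC downstream) or transferred live-to-dead. A
fraction of high-severity Forest burn area can fail to regenerate,
converting to Shrubland in the same year's conversion step.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .land_state import BURNABLE_TYPES, CarbonState

SEVERITIES = ("high", "medium", "low")

#: where burned live carbon that survives combustion goes
FIRE_ROUTING = {
    "above_main": "standing_dead",
    "root": "down_dead",
    "understory": "litter",
    "standing_dead": "down_dead",
}


@dataclass(frozen=True)
class SeveritySchedule:
    """Linear evolution of burn-severity fractions."""

    high_start: float = 0.26
    medium_start: float = 0.29
    low_start: float = 0.45
    high_increment: float = 0.0027  # yr^-1
    start_year: int = 2010

    def __post_init__(self):
        s = self.high_start + self.medium_start + self.low_start
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"severity start fractions sum to {s}, not 1")
        if min(self.high_start, self.medium_start, self.low_start) < 0:
            raise ValueError("negative severity fraction")


def severity_fractions(
    schedule: SeveritySchedule, year: int, severity_shift: float = 0.0
) -> tuple[float, float, float]:
    """(high, medium, low) fractions for ``year`` after management shift.

    High severity trends linearly upward from its start value and is
    reduced by the treatment-induced ``severity_shift`` (floored at 0);
    the low-severity class absorbs the change, with medium held constant
    where possible. Fractions are clipped to [0, 1] and renormalised to
    sum exactly to 1.
    """
    if year < schedule.start_year:
        raise ValueError(f"year {year} precedes schedule start {schedule.start_year}")
    high = schedule.high_start + schedule.high_increment * (year - schedule.start_year)
    high = max(0.0, high - severity_shift)
    med = schedule.medium_start
    low = 1.0 - high - med
    if low < 0.0:
        low = 0.0
    if high > 1.0:
        high = 1.0
    total = high + med + low
    return high / total, med / total, low / total


def allocate_burn(
    burn_area: float, type_areas: pd.Series
) -> tuple[pd.Series, float]:
    """Distribute a region-ownership burn area over burnable land types.

    Only the five burnable types receive burn area, proportional to their
    current areas; the total burned is capped at the total burnable area.
    Returns (burned ha per land type, capped shortfall ha).
    """
    if burn_area < 0:
        raise ValueError("negative burn area")
    burnable = type_areas.reindex(list(BURNABLE_TYPES)).fillna(0.0).clip(lower=0.0)
    total = float(burnable.sum())
    if total <= 0.0 or burn_area == 0.0:
        return burnable * 0.0, burn_area if total <= 0.0 else 0.0
    effective = min(burn_area, total)
    burned = burnable / total * effective
    return burned, burn_area - effective


def burn_step(
    state: CarbonState,
    region: str,
    ownership: str,
    burned_by_type: pd.Series,
    severities: tuple[float, float, float],
    fire_effects: pd.DataFrame,
) -> tuple[float, float]:
    """Combust and transfer carbon on burned area; return (C, high-sev Forest ha).

    ``fire_effects`` is indexed by (land_type, severity, pool) with columns
    ``combusted_frac`` and ``transfer_frac``. For each burned (type,
    severity, pool): area x density x combusted_frac of carbon is emitted
    (returned for speciation) and area x density x transfer_frac moves from
    live to the routed dead pool. Density updates are the area-weighted
    merge of burned and unburned sub-areas. Mass balance: state change plus
    emitted carbon is zero.
    """
    df = state.df
    emitted = 0.0
    high_sev_forest = 0.0
    sev_map = dict(zip(SEVERITIES, severities))
    for land_type, area_burned in burned_by_type.items():
        if area_burned <= 0.0:
            continue
        key = (region, ownership, land_type)
        if key not in df.index:
            continue
        cat_area = float(df.at[key, "area_ha"])
        if cat_area <= 0.0:
            continue
        mask = state.mask_for(land_type)
        if land_type == "Forest":
            high_sev_forest += area_burned * sev_map["high"]
        for severity, sev_frac in sev_map.items():
            sub_area = area_burned * sev_frac
            if sub_area <= 0.0:
                continue
            try:
                effects = fire_effects.loc[(land_type, severity)]
            except KeyError:
                continue
            transfers: dict[str, float] = {}
            for pool, row in effects.iterrows():
                if pool not in mask:
                    continue
                dens = float(df.at[key, pool])
                if dens <= 0.0:
                    continue
                comb = sub_area * dens * float(row["combusted_frac"])
                trans = sub_area * dens * float(row["transfer_frac"])
                emitted += comb
                df.at[key, pool] -= (comb + trans) / cat_area
                if df.at[key, pool] < 0:
                    df.at[key, pool] = 0.0
                dest = FIRE_ROUTING.get(pool)
                if trans > 0.0 and dest and dest in mask:
                    transfers[dest] = transfers.get(dest, 0.0) + trans
                elif trans > 0.0:
                    # no dead pool to receive it: combusted instead
                    emitted += trans
            for dest, mass in transfers.items():
                df.at[key, dest] += mass / cat_area
    return emitted, high_sev_forest


def nonregen_area(
    high_sev_forest_area: float,
    interior_fraction: float,
    enabled: bool = True,
) -> float:
    """Forest area (ha) converting to Shrubland after high-severity fire.

    ``interior_fraction`` approximates the share of high-severity burn
    deeper than the regeneration edge distance; disabled -> 0.
    """
    if not enabled:
        return 0.0
    if not 0.0 <= interior_fraction <= 1.0:
        raise ValueError("interior fraction outside [0,1]")
    return interior_fraction * high_sev_forest_area
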