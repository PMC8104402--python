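"""Process 2: land management practices.

A practice removes per-pool fractions of biomass from a treated sub-area,
splits the removal into a harvest stream and a slash stream, and leaves
multi-year adjustments (growth multiplier, mortality multiplier, wildfire
severity reduction) behind in an effect ledger. Slash is partitioned among
in-situ burning, rapid decay, and (for utilization variants) collection;
harvested and collected carbon flows to wood products and bioenergy.
Discarded products decay first-order to a landfill pool which emits CO2
and CH4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .land_state import POOLS, CarbonState, LandStateError, ProductPools


@dataclass(frozen=True)
class PracticeDefinition:
    """All fractions and durations describing one management practice."""

    name: str
    kind: str = "manipulate"  # manipulate | soil | restoration
    land_types: tuple[str, ...] = ("Forest",)
    ownerships: tuple[str, ...] = ()  # empty = all
    regions: tuple[str, ...] = ()     # empty = all
    removal: dict[str, float] = field(default_factory=dict)  # pool -> fraction
    harvest_frac: float = 1.0         # of removed above_main to harvest stream
    slash_burn_frac: float = 0.25     # of uncollected slash that burns in situ
    slash_collect_frac: float = 0.0   # of slash collected for utilization
    product_frac: float = 1.0         # of harvest+collected to products (rest bioenergy)
    growth_mult: float = 1.0
    growth_duration: int = 20
    mortality_mult: float = 1.0
    mortality_duration: int = 0
    severity_reduction: float = 0.0
    severity_duration: int = 20
    # restoration-only fields
    to_type: str = ""
    sources: tuple[str, ...] = ()
    # soil-practice accumulation adjustment (added to soil rate, Mg C/ha/yr)
    soil_rate_delta: float = 0.0
    soil_effect_duration: int = 1

    def __post_init__(self):
        for name, frac in (("harvest_frac", self.harvest_frac),
                           ("slash_burn_frac", self.slash_burn_frac),
                           ("slash_collect_frac", self.slash_collect_frac),
                           ("product_frac", self.product_frac)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{self.name}: {name}={frac} outside [0,1]")
        for pool, frac in self.removal.items():
            if pool not in POOLS:
                raise ValueError(f"{self.name}: unknown pool {pool!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{self.name}: removal[{pool}]={frac} outside [0,1]")
        if min(self.growth_duration, self.mortality_duration,
               self.severity_duration) < 0:
            raise ValueError(f"{self.name}: negative effect duration")

    def eligible(self, region: str, ownership: str, land_type: str) -> bool:
        if self.land_types and land_type not in self.land_types:
            return False
        if self.ownerships and ownership not in self.ownerships:
            return False
        if self.regions and region not in self.regions:
            return False
        return True


@dataclass
class LedgerEntry:
    category: tuple
    practice: PracticeDefinition
    year_applied: int
    area: float


@dataclass
class PracticeEffectLedger:
    """Rolling history of applied areas with remaining effect-years."""

    entries: list[LedgerEntry] = field(default_factory=list)

    def add(self, category: tuple, practice: PracticeDefinition,
            year: int, area: float) -> None:
        self.entries.append(LedgerEntry(category, practice, year, area))

    def prune(self, year: int) -> None:
        """Drop entries whose longest effect window has passed."""
        def alive(e: LedgerEntry) -> bool:
            longest = max(e.practice.growth_duration,
                          e.practice.mortality_duration,
                          e.practice.severity_duration,
                          e.practice.soil_effect_duration)
            return year <= e.year_applied + longest

        self.entries = [e for e in self.entries if alive(e)]


def active_adjustments(
    ledger: PracticeEffectLedger,
    category: tuple,
    year: int,
    category_area: float = 0.0,
) -> tuple[float, float, float]:
    """Combined (growth mult, mortality mult, severity shift) for a category.

    An effect applied in year y is active for years y+1 .. y+duration.
    Each entry's multiplier is diluted to the category scale by its
    treated-area share (a practice covering the whole category contributes
    its full multiplier); the diluted multipliers from overlapping entries
    compose multiplicatively. Severity reductions add, likewise weighted by
    treated-area share. Pass ``category_area`` <= 0 to treat entries as
    whole-category (share 1).
    """
    growth, mort, shift = 1.0, 1.0, 0.0
    for e in ledger.entries:
        if e.category != category:
            continue
        age = year - e.year_applied
        if age < 1:
            continue
        w = min(1.0, e.area / category_area) if category_area > 0 else 1.0
        p = e.practice
        if age <= p.growth_duration and p.growth_mult != 1.0:
            growth *= 1.0 + (p.growth_mult - 1.0) * w
        if age <= p.mortality_duration and p.mortality_mult != 1.0:
            mort *= 1.0 + (p.mortality_mult - 1.0) * w
        if age <= p.severity_duration and p.severity_reduction > 0.0:
            shift += p.severity_reduction * w
    return growth, mort, max(0.0, shift)


def soil_rate_adjustment(
    ledger: PracticeEffectLedger, category: tuple, year: int
) -> float:
    """Additive soil-accumulation adjustment (Mg C/ha/yr x treated ha)
    from active soil practices, returned as a total Mg C/yr for the
    category (the engine divides by area to get a density rate)."""
    total = 0.0
    for e in ledger.entries:
        if e.category != category or e.practice.soil_rate_delta == 0.0:
            continue
        age = year - e.year_applied
        if 1 <= age <= e.practice.soil_effect_duration:
            total += e.practice.soil_rate_delta * e.area
    return total


def schedule_management(
    prescriptions,
    areas: pd.Series,
    practices: dict[str, PracticeDefinition],
    year: int,
) -> tuple[list[tuple[tuple, PracticeDefinition, float]], dict[str, float]]:
    """Distribute prescribed areas over eligible categories for ``year``.

    Each prescription's target area is split over eligible categories in
    proportion to their current areas, capped at availability. Practices
    with a repeat interval fire only on schedule years. Returns realized
    (category, practice, area) triples and per-practice shortfalls.
    """
    realized: list[tuple[tuple, PracticeDefinition, float]] = []
    shortfalls: dict[str, float] = {}
    for presc in prescriptions:
        if not presc.active_in(year):
            continue
        practice = practices.get(presc.practice)
        if practice is None:
            raise LandStateError(f"unknown practice {presc.practice!r}")
        elig = [k for k in areas.index
                if practice.eligible(*k)
                and (not presc.regions or k[0] in presc.regions)
                and (not presc.ownerships or k[1] in presc.ownerships)
                and areas[k] > 0]
        target = presc.annual_area_ha
        if not elig:
            shortfalls[presc.practice] = shortfalls.get(presc.practice, 0.0) + target
            continue
        avail = areas[elig]
        total = float(avail.sum())
        want = avail / total * target
        got = want.clip(upper=avail)
        short = target - float(got.sum())
        if short > 1e-9:
            shortfalls[presc.practice] = shortfalls.get(presc.practice, 0.0) + short
        for k in elig:
            if got[k] > 0:
                realized.append((k, practice, float(got[k])))
    return realized, shortfalls


def apply_practice(
    state: CarbonState,
    category: tuple,
    practice: PracticeDefinition,
    area: float,
    year: int,
    ledger: PracticeEffectLedger | None = None,
) -> tuple[CarbonState, float, float]:
    """Apply a practice to ``area`` ha of a category; return (state, harvest, slash).

    Per-pool removal fractions act on the treated sub-area's (category
    average) densities; removed above-ground carbon splits between the
    harvest stream (``harvest_frac``) and slash, while removals from the
    understory/dead/litter pools all enter the slash stream. The treated
    sub-area is merged back by area-weighted average, which here reduces
    each pool by area x density x removal / category area.
    """
    df = state.df
    cat_area = float(df.at[category, "area_ha"])
    if area > cat_area * (1 + 1e-9):
        raise LandStateError(
            f"treated area {area} exceeds category area {cat_area} for {category}")
    harvest = 0.0
    slash = 0.0
    if area > 0 and cat_area > 0:
        mask = state.mask_for(category[2])
        for pool, frac in practice.removal.items():
            if pool not in mask or frac == 0.0:
                continue
            removed = area * float(df.at[category, pool]) * frac
            if removed <= 0.0:
                continue
            df.at[category, pool] -= removed / cat_area
            if df.at[category, pool] < 0:  # numerical guard
                df.at[category, pool] = 0.0
            if pool == "above_main":
                harvest += removed * practice.harvest_frac
                slash += removed * (1.0 - practice.harvest_frac)
            else:
                slash += removed
    if ledger is not None and area > 0:
        ledger.add(category, practice, year, area)
    return state, harvest, slash


def partition_slash(
    slash: float, practice: PracticeDefinition
) -> dict[str, float]:
    """Split slash into collected / burned / decayed components (Mg C).

    Collection (utilization variants) takes its fraction first; the
    remainder burns in situ per ``slash_burn_frac`` (1.0 for prescribed
    burn) and the rest decays rapidly. Components sum exactly to input.
    """
    if slash < 0:
        raise ValueError("negative slash mass")
    collected = slash * practice.slash_collect_frac
    remainder = slash - collected
    burned = remainder * practice.slash_burn_frac
    decayed = remainder - burned
    return {"collected": collected, "burned": burned, "decayed": decayed}


@dataclass(frozen=True)
class ProductParams:
    """Wood-product decay parameters.

    ``half_lives`` maps in-use class -> half-life (years); ``inflow_shares``
    maps class -> share of product inflow. Discarded product carbon accrues
    to the landfill, which decays first-order; the landfill CH4 carbon share
    is taken from the speciation table's landfill pathway.
    """

    half_lives: dict[str, float]
    inflow_shares: dict[str, float]
    landfill_decay_rate: float = 0.03  # yr^-1

    def __post_init__(self):
        if abs(sum(self.inflow_shares.values()) - 1.0) > 1e-9:
            raise ValueError("product inflow shares must sum to 1")
        if any(h <= 0 for h in self.half_lives.values()):
            raise ValueError("half-lives must be positive")
        if not 0 <= self.landfill_decay_rate <= 1:
            raise ValueError("landfill decay rate outside [0,1]")


def wood_products_step(
    pools: ProductPools, inflow: float, params: ProductParams
) -> tuple[ProductPools, float]:
    """Advance product pools one year; return (pools, landfill carbon emitted).

    Inflow enters in-use classes by their shares; each class decays
    first-order (rate ln2 / half-life) to the landfill; the landfill emits
    ``landfill_decay_rate`` of its stock as carbon (speciated downstream
    into CO2 and CH4). Mass balance: inflow = d(stored) + emitted.
    """
    if inflow < 0:
        raise ValueError("negative product inflow")
    discard = 0.0
    for cls, half_life in params.half_lives.items():
        stock = pools.in_use.get(cls, 0.0) + inflow * params.inflow_shares.get(cls, 0.0)
        rate = 1.0 - math.exp(-math.log(2.0) / half_life)
        out = stock * rate
        pools.in_use[cls] = stock - out
        discard += out
    pools.landfill += discard
    emitted = pools.landfill * params.landfill_decay_rate
    pools.landfill -= emitted
    return pools, emitted
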