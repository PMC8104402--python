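"""Land-category grid and carbon-pool state.

The atomic simulation unit is a *land category*: one region x ownership x
land-type cell carrying a single representative area (ha) and a vector of
carbon densities (Mg C ha^-1), one per pool. Sub-category treatments are
merged back into the category by an area-weighted average, so carbon mass
is conserved while densities evolve.

Pools follow the standard seven-pool accounting: soil organic carbon, main
canopy above-ground and root, understory, standing dead, down dead, and
litter. Each land type carries only a subset of pools (its *pool mask*);
pools outside the mask are structurally zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical pool order used across the package
POOLS = (
    "soil",
    "above_main",
    "root",
    "understory",
    "standing_dead",
    "down_dead",
    "litter",
)

LIVE_POOLS = ("above_main", "root", "understory")
DEAD_POOLS = ("standing_dead", "down_dead", "litter")

ALL_POOLS = frozenset(POOLS)
_WOODY = ALL_POOLS
_SOIL_ONLY = frozenset({"soil"})

#: per-land-type pool masks. Water, Ice, Fresh Marsh and Seagrass carry only
#: soil carbon; Barren and Sparse add main canopy; marsh/cultivated/urban
#: carry soil plus an above-ground canopy; the woody and herbaceous upland
#: types carry all seven pools.
DEFAULT_POOL_MASKS: dict[str, frozenset[str]] = {
    "Water": _SOIL_ONLY,
    "Ice": _SOIL_ONLY,
    "Barren": frozenset({"soil", "above_main", "root"}),
    "Sparse": frozenset({"soil", "above_main", "root"}),
    "Desert": _WOODY,
    "Shrubland": _WOODY,
    "Grassland": _WOODY,
    "Savanna": _WOODY,
    "Woodland": _WOODY,
    "Forest": _WOODY,
    "Meadow": _WOODY,
    "Tidal_Marsh": frozenset({"soil", "above_main"}),
    "Fresh_Marsh": _SOIL_ONLY,
    "Cultivated": frozenset({"soil", "above_main"}),
    "Urban": frozenset({"soil", "above_main"}),
    "Seagrass": _SOIL_ONLY,
}

#: land types eligible to burn in wildfire
BURNABLE_TYPES = ("Forest", "Woodland", "Savanna", "Shrubland", "Grassland")

CATEGORY_INDEX = ["region", "ownership", "land_type"]


class LandStateError(ValueError):
    """Raised for invalid land-state construction or manipulation."""


@dataclass
class ProductPools:
    """Harvested-wood-product carbon outside the ecosystem.

    ``in_use`` is keyed by half-life class name; ``landfill`` holds
    discarded product carbon awaiting anaerobic decay; ``bioenergy_emitted``
    is a cumulative diagnostic of carbon combusted for energy.
    """

    in_use: dict[str, float] = field(default_factory=dict)
    landfill: float = 0.0
    bioenergy_emitted: float = 0.0

    def total_stored(self) -> float:
        """Carbon currently stored in products and landfill (Mg C)."""
        return float(sum(self.in_use.values()) + self.landfill)

    def copy(self) -> "ProductPools":
        return ProductPools(dict(self.in_use), self.landfill, self.bioenergy_emitted)


@dataclass
class CarbonState:
    """Areas and pool densities for every land category, plus product pools.

    ``df`` is indexed by (region, ownership, land_type) and has columns
    ``area_ha`` plus one density column per pool (Mg C ha^-1).
    """

    df: pd.DataFrame
    products: ProductPools = field(default_factory=ProductPools)
    pool_masks: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_POOL_MASKS)
    )

    def copy(self) -> "CarbonState":
        return CarbonState(self.df.copy(), self.products.copy(), dict(self.pool_masks))

    # -- queries -----------------------------------------------------------

    def mask_for(self, land_type: str) -> frozenset[str]:
        try:
            return self.pool_masks[land_type]
        except KeyError:
            raise LandStateError(f"unknown land type: {land_type!r}") from None

    def ecosystem_carbon(self) -> float:
        """Total on-the-land carbon, Mg C (excludes product pools)."""
        dens = self.df[list(POOLS)].to_numpy()
        area = self.df["area_ha"].to_numpy()
        return float((area[:, None] * dens).sum())

    def areas(self) -> pd.Series:
        return self.df["area_ha"]

    def enforce_masks(self) -> None:
        """Zero every density outside its land type's pool mask."""
        for lt, mask in self.pool_masks.items():
            absent = [p for p in POOLS if p not in mask]
            if not absent:
                continue
            rows = self.df.index.get_level_values("land_type") == lt
            if rows.any():
                self.df.loc[rows, absent] = 0.0

    def check_masks(self, where: str = "") -> None:
        for lt, mask in self.pool_masks.items():
            absent = [p for p in POOLS if p not in mask]
            if not absent:
                continue
            rows = self.df.index.get_level_values("land_type") == lt
            if rows.any() and (self.df.loc[rows, absent].to_numpy() != 0.0).any():
                raise LandStateError(
                    f"masked pool holds carbon for land type {lt}{' ' + where if where else ''}"
                )


def build_categories(
    regions: list[str],
    ownerships: list[str],
    land_types: list[str],
    initial_table: pd.DataFrame,
    pool_masks: dict[str, frozenset[str]] | None = None,
) -> CarbonState:
    """Build a :class:`CarbonState` from an initial area/density table.

    ``initial_table`` has columns region, ownership, land_type, area_ha and
    per-pool density columns (plain pool names or ``<pool>_mean``). Categories
    absent from the table get zero area and zero carbon; rows with unknown
    land types or negative values are rejected with their row identity.
    """
    masks = dict(pool_masks) if pool_masks is not None else {
        lt: DEFAULT_POOL_MASKS.get(lt, ALL_POOLS) for lt in land_types
    }
    for lt in land_types:
        masks.setdefault(lt, ALL_POOLS)

    idx = pd.MultiIndex.from_product(
        [regions, ownerships, land_types], names=CATEGORY_INDEX
    )
    df = pd.DataFrame(0.0, index=idx, columns=["area_ha", *POOLS])

    tbl = initial_table.copy()
    for required in ("region", "ownership", "land_type", "area_ha"):
        if required not in tbl.columns:
            raise LandStateError(f"initial table missing column {required!r}")

    seen: set[tuple] = set()
    for i, row in tbl.iterrows():
        key = (row["region"], row["ownership"], row["land_type"])
        if row["land_type"] not in masks:
            raise LandStateError(f"row {i}: unknown land_type {row['land_type']!r}")
        if key in seen:
            raise LandStateError(f"row {i}: duplicate category {key}")
        seen.add(key)
        if row["area_ha"] < 0:
            raise LandStateError(f"row {i} {key}: negative area {row['area_ha']}")
        df.loc[key, "area_ha"] = float(row["area_ha"])
        for pool in POOLS:
            col = pool if pool in tbl.columns else f"{pool}_mean"
            if col not in tbl.columns:
                continue
            val = row[col]
            if pd.isna(val):
                val = 0.0
            if val < 0:
                raise LandStateError(f"row {i} {key}: negative density {pool}={val}")
            df.loc[key, pool] = float(val)

    state = CarbonState(df, ProductPools(), masks)
    state.enforce_masks()
    return state


def area_weighted_merge(
    sub_states: list[tuple[float, dict[str, float] | pd.Series]],
    parent_area: float | None = None,
    category: str = "",
) -> dict[str, float]:
    """Merge sub-stand (area, densities) pairs into one density vector.

    Densities merge as sum(area_i * d_i) / sum(area_i), which conserves
    carbon mass exactly. If ``parent_area`` is given, sub-areas must sum to
    it (within 1e-6 relative) and must not exceed it.
    """
    if not sub_states:
        raise LandStateError(f"no sub-states to merge for {category or 'category'}")
    total = float(sum(a for a, _ in sub_states))
    if parent_area is not None:
        if total > parent_area * (1 + 1e-9) + 1e-9:
            raise LandStateError(
                f"sub-areas {total} exceed parent area {parent_area}"
                f" for {category or 'category'}"
            )
        if abs(total - parent_area) > 1e-6 * max(1.0, abs(parent_area)):
            raise LandStateError(
                f"sub-areas {total} do not sum to parent area {parent_area}"
                f" for {category or 'category'}"
            )
    if total == 0.0:
        return {p: 0.0 for p in POOLS}
    merged: dict[str, float] = {}
    pools = set()
    for _, dens in sub_states:
        pools.update(dens.keys() if isinstance(dens, dict) else dens.index)
    for pool in pools:
        mass = sum(a * float(d.get(pool, 0.0) if isinstance(d, dict) else d.get(pool, 0.0))
                   for a, d in sub_states)
        merged[pool] = mass / total
    return merged


def total_carbon(state: CarbonState) -> float:
    """Total carbon of the system, Mg C: ecosystem plus product pools."""
    return state.ecosystem_carbon() + state.products.total_stored()
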