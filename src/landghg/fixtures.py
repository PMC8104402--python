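"""Seeded synthetic-input generator.

Produces a complete, validated parameter directory and a catalog of
scenario files at reduced geography (default 2 regions x 2 ownerships x 8
land types), with the statistical structure the simulator assumes: positive
densities drawn log-normally around configurable means, net accumulation
fluxes drawn normally (sources allowed), severity fractions and slash
splits at their standard defaults, and two alternative LULCC delta tables.
Magnitudes are scaled so landscape totals are of order 1-100 MMT CO2eq,
keeping the 1-MMT sampling grid of the divergence diagnostic meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .land_state import BURNABLE_TYPES

DEFAULT_LAND_TYPES = (
    "Forest", "Woodland", "Shrubland", "Grassland",
    "Meadow", "Urban", "Cultivated", "Fresh_Marsh",
)

# per-type mean area (ha) for one region-ownership cell
_AREA = {
    "Forest": 150_000.0, "Woodland": 60_000.0, "Shrubland": 120_000.0,
    "Grassland": 100_000.0, "Meadow": 8_000.0, "Urban": 40_000.0,
    "Cultivated": 80_000.0, "Fresh_Marsh": 0.0,
}

# per-type mean densities (Mg C/ha) by pool
_DENSITY = {
    "Forest":     {"soil": 80, "above_main": 90, "root": 20, "understory": 5,
                   "standing_dead": 8, "down_dead": 6, "litter": 5},
    "Woodland":   {"soil": 60, "above_main": 40, "root": 12, "understory": 4,
                   "standing_dead": 4, "down_dead": 3, "litter": 3},
    "Shrubland":  {"soil": 50, "above_main": 12, "root": 6, "understory": 2,
                   "standing_dead": 1, "down_dead": 1, "litter": 1},
    "Grassland":  {"soil": 45, "above_main": 2, "root": 3, "understory": 0.5,
                   "standing_dead": 0.2, "down_dead": 0.2, "litter": 0.5},
    "Meadow":     {"soil": 90, "above_main": 3, "root": 4, "understory": 0.5,
                   "standing_dead": 0.2, "down_dead": 0.2, "litter": 0.5},
    "Urban":      {"soil": 40, "above_main": 25},
    "Cultivated": {"soil": 50, "above_main": 5},
    "Fresh_Marsh": {"soil": 0.0},
}

# (veg accumulation, soil accumulation) means, Mg C/ha/yr
_RATES = {
    "Forest": (1.2, 0.10), "Woodland": (0.6, 0.08), "Shrubland": (0.30, 0.05),
    "Grassland": (0.15, 0.04), "Meadow": (0.30, 0.25), "Urban": (0.90, 0.02),
    "Cultivated": (0.05, -0.05), "Fresh_Marsh": (0.0, 0.60),
}

_MORTALITY = {"Forest": 0.010, "Woodland": 0.008, "Shrubland": 0.005}


@dataclass
class FixtureSpec:
    n_regions: int = 2
    n_ownerships: int = 2
    land_types: tuple[str, ...] = DEFAULT_LAND_TYPES
    seed: int = 0
    area_scale: float = 1.0
    density_cv: float = 0.3        # SD as fraction of the mean
    rate_cv: float = 0.3
    spatial_jitter: float = 0.15   # log-normal sigma across cells
    burn_fraction: float = 0.01    # of burnable area per region-ownership
    scarce_grassland: bool = False  # shrink Grassland to force competition
    restoration_area_ha: float = 300.0

    @property
    def regions(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.n_regions)]

    @property
    def ownerships(self) -> list[str]:
        return [f"O{i + 1}" for i in range(self.n_ownerships)]


def generate_params(spec: FixtureSpec, out_dir: str | Path) -> Path:
    """Write a complete parameter directory; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    regions, ownerships = spec.regions, spec.ownerships
    land_types = list(spec.land_types)

    cat_rows = []
    rate_rows = []
    mort_rows = []
    for region in regions:
        for own in ownerships:
            for lt in land_types:
                area = _AREA.get(lt, 0.0) * spec.area_scale
                if spec.scarce_grassland and lt == "Grassland":
                    area = 500.0
                if area > 0:
                    area *= float(np.exp(rng.normal(0.0, spec.spatial_jitter)))
                row = {"region": region, "ownership": own, "land_type": lt,
                       "area_ha": round(area, 4)}
                for pool, mean in _DENSITY.get(lt, {}).items():
                    if mean > 0:
                        d = mean * float(np.exp(rng.normal(0.0, spec.spatial_jitter)))
                    else:
                        d = 0.0
                    row[f"{pool}_mean"] = round(d, 6)
                    row[f"{pool}_sd"] = round(d * spec.density_cv, 6)
                cat_rows.append(row)
                veg, soil = _RATES.get(lt, (0.0, 0.0))
                jit = float(np.exp(rng.normal(0.0, spec.spatial_jitter)))
                rate_rows.append({
                    "region": region, "ownership": own, "land_type": lt,
                    "veg_mean": round(veg * jit, 6),
                    "veg_sd": round(abs(veg) * spec.rate_cv, 6),
                    "soil_mean": round(soil * jit, 6),
                    "soil_sd": round(abs(soil) * spec.rate_cv, 6),
                })
                mort_rows.append({
                    "region": region, "ownership": own, "land_type": lt,
                    "rate": _MORTALITY.get(lt, 0.0),
                })
    pd.DataFrame(cat_rows).to_csv(out / "categories.csv", index=False)
    pd.DataFrame(rate_rows).to_csv(out / "rates.csv", index=False)
    pd.DataFrame(mort_rows).to_csv(out / "mortality.csv", index=False)

    alloc = []
    for lt in land_types:
        pools = _DENSITY.get(lt, {})
        if "root" in pools:
            alloc += [
                {"land_type": lt, "pool": "above_main", "fraction": 0.7},
                {"land_type": lt, "pool": "root", "fraction": 0.2},
                {"land_type": lt, "pool": "understory", "fraction": 0.1},
            ]
        elif "above_main" in pools:
            alloc.append({"land_type": lt, "pool": "above_main", "fraction": 1.0})
    pd.DataFrame(alloc).to_csv(out / "allocation.csv", index=False)

    practices = pd.DataFrame([
        dict(name="clearcut", kind="manipulate", land_types="Forest",
             ownerships="", regions="",
             removal_above_main=0.90, removal_understory=0.50,
             removal_down_dead=0.30, removal_litter=0.20,
             harvest_frac=0.80, slash_burn_frac=0.25, slash_collect_frac=0.0,
             product_frac=0.85, growth_mult=1.05, growth_duration=20,
             mortality_mult=1.0, mortality_duration=0,
             severity_reduction=0.05, severity_duration=20,
             to_type="", sources="", soil_rate_delta=0.0, soil_effect_duration=1),
        dict(name="thinning", kind="manipulate", land_types="Forest",
             ownerships="", regions="",
             removal_above_main=0.35, removal_understory=0.30,
             removal_down_dead=0.25, removal_litter=0.15,
             harvest_frac=0.60, slash_burn_frac=0.25, slash_collect_frac=0.0,
             product_frac=0.80, growth_mult=1.15, growth_duration=20,
             mortality_mult=0.9, mortality_duration=10,
             severity_reduction=0.10, severity_duration=20,
             to_type="", sources="", soil_rate_delta=0.0, soil_effect_duration=1),
        dict(name="prescribed_burn", kind="manipulate", land_types="Forest",
             ownerships="", regions="",
             removal_above_main=0.05, removal_understory=0.50,
             removal_down_dead=0.60, removal_litter=0.70,
             harvest_frac=0.0, slash_burn_frac=1.0, slash_collect_frac=0.0,
             product_frac=0.0, growth_mult=1.0, growth_duration=20,
             mortality_mult=1.0, mortality_duration=0,
             severity_reduction=0.12, severity_duration=20,
             to_type="", sources="", soil_rate_delta=0.0, soil_effect_duration=1),
        dict(name="compost", kind="soil", land_types="Grassland",
             ownerships="", regions="",
             removal_above_main=0.0, removal_understory=0.0,
             removal_down_dead=0.0, removal_litter=0.0,
             harvest_frac=0.0, slash_burn_frac=0.0, slash_collect_frac=0.0,
             product_frac=0.0, growth_mult=1.0, growth_duration=0,
             mortality_mult=1.0, mortality_duration=0,
             severity_reduction=0.0, severity_duration=0,
             to_type="", sources="", soil_rate_delta=0.25, soil_effect_duration=5),
        dict(name="meadow_restoration", kind="restoration", land_types="",
             ownerships="", regions="",
             removal_above_main=0.0, removal_understory=0.0,
             removal_down_dead=0.0, removal_litter=0.0,
             harvest_frac=0.0, slash_burn_frac=0.25, slash_collect_frac=0.0,
             product_frac=0.0, growth_mult=1.0, growth_duration=0,
             mortality_mult=1.0, mortality_duration=0,
             severity_reduction=0.0, severity_duration=0,
             to_type="Meadow", sources="Grassland|Shrubland",
             soil_rate_delta=0.0, soil_effect_duration=1),
        dict(name="woodland_restoration", kind="restoration", land_types="",
             ownerships="", regions="",
             removal_above_main=0.0, removal_understory=0.0,
             removal_down_dead=0.0, removal_litter=0.0,
             harvest_frac=0.0, slash_burn_frac=0.0, slash_collect_frac=0.0,
             product_frac=0.0, growth_mult=1.0, growth_duration=0,
             mortality_mult=1.0, mortality_duration=0,
             severity_reduction=0.0, severity_duration=0,
             to_type="Woodland", sources="Grassland",
             soil_rate_delta=0.0, soil_effect_duration=1),
        dict(name="marsh_restoration", kind="restoration", land_types="",
             ownerships="", regions="",
             removal_above_main=0.0, removal_understory=0.0,
             removal_down_dead=0.0, removal_litter=0.0,
             harvest_frac=0.0, slash_burn_frac=0.0, slash_collect_frac=0.0,
             product_frac=0.0, growth_mult=1.0, growth_duration=0,
             mortality_mult=1.0, mortality_duration=0,
             severity_reduction=0.0, severity_duration=0,
             to_type="Fresh_Marsh", sources="Cultivated",
             soil_rate_delta=0.0, soil_effect_duration=1),
    ])
    practices.to_csv(out / "practices.csv", index=False)

    burn_rows = []
    cats = pd.DataFrame(cat_rows)
    for region in regions:
        for own in ownerships:
            sub = cats[(cats["region"] == region) & (cats["ownership"] == own)]
            burnable = sub[sub["land_type"].isin(BURNABLE_TYPES)]["area_ha"].sum()
            burn_rows.append({"region": region, "ownership": own,
                              "area_ha": round(burnable * spec.burn_fraction, 4)})
    pd.DataFrame(burn_rows).to_csv(out / "burn_area.csv", index=False)

    # severity-specific combustion/transfer fractions per pool
    fire_rows = []
    base = {
        # pool: (combusted by severity, transferred live->dead by severity)
        "above_main":    {"high": (0.30, 0.50), "medium": (0.15, 0.30),
                          "low": (0.05, 0.10)},
        "root":          {"high": (0.00, 0.40), "medium": (0.00, 0.20),
                          "low": (0.00, 0.05)},
        "understory":    {"high": (0.80, 0.15), "medium": (0.55, 0.25),
                          "low": (0.30, 0.20)},
        "standing_dead": {"high": (0.40, 0.30), "medium": (0.25, 0.20),
                          "low": (0.10, 0.10)},
        "down_dead":     {"high": (0.60, 0.00), "medium": (0.40, 0.00),
                          "low": (0.20, 0.00)},
        "litter":        {"high": (0.90, 0.00), "medium": (0.70, 0.00),
                          "low": (0.40, 0.00)},
    }
    for lt in BURNABLE_TYPES:
        if lt not in land_types:
            continue
        for pool, by_sev in base.items():
            for sev, (comb, trans) in by_sev.items():
                fire_rows.append({
                    "land_type": lt, "severity": sev, "pool": pool,
                    "combusted_frac": comb, "transfer_frac": trans,
                })
    pd.DataFrame(fire_rows).to_csv(out / "fire_effects.csv", index=False)

    # LULCC delta tables: per-cell deltas that net to zero
    def lulcc_rows(deltas: dict[str, float]) -> pd.DataFrame:
        rows = []
        for region in regions:
            for own in ownerships:
                for lt in land_types:
                    rows.append({
                        "region": region, "ownership": own, "land_type": lt,
                        "delta_ha_yr": deltas.get(lt, 0.0) * spec.area_scale,
                    })
        return pd.DataFrame(rows)

    lulcc_rows({"Urban": 80.0, "Grassland": -30.0, "Cultivated": -30.0,
                "Shrubland": -20.0}).to_csv(
        out / "lulcc_land_use_driven.csv", index=False)
    lulcc_rows({"Shrubland": -200.0, "Grassland": 150.0, "Woodland": -30.0,
                "Urban": 60.0, "Cultivated": 20.0}).to_csv(
        out / "lulcc_remote_sensing.csv", index=False)

    pd.DataFrame([
        {"from_type": "*", "to_type": "*",
         "burn_frac": 0.0, "decay_frac": 1.0, "product_frac": 0.0},
        {"from_type": "Grassland", "to_type": "Woodland",
         "burn_frac": 0.0, "decay_frac": 0.0, "product_frac": 0.0},
        {"from_type": "Grassland", "to_type": "Forest",
         "burn_frac": 0.0, "decay_frac": 0.0, "product_frac": 0.0},
        {"from_type": "Forest", "to_type": "Shrubland",
         "burn_frac": 0.0, "decay_frac": 0.0, "product_frac": 0.0},
        {"from_type": "Shrubland", "to_type": "Meadow",
         "burn_frac": 0.25, "decay_frac": 0.75, "product_frac": 0.0},
        {"from_type": "Grassland", "to_type": "Meadow",
         "burn_frac": 0.0, "decay_frac": 1.0, "product_frac": 0.0},
        {"from_type": "Cultivated", "to_type": "Fresh_Marsh",
         "burn_frac": 0.0, "decay_frac": 1.0, "product_frac": 0.0},
        {"from_type": "Forest", "to_type": "Urban",
         "burn_frac": 0.10, "decay_frac": 0.40, "product_frac": 0.30},
    ]).to_csv(out / "conversions.csv", index=False)

    pd.DataFrame([
        {"class": "short", "half_life_yr": 10.0, "inflow_share": 0.5},
        {"class": "long", "half_life_yr": 50.0, "inflow_share": 0.5},
    ]).to_csv(out / "products.csv", index=False)

    pd.DataFrame([
        {"pathway": "wildfire", "ch4_share": 0.010, "bc_share": 0.010},
        {"pathway": "slash_burn", "ch4_share": 0.010, "bc_share": 0.010},
        {"pathway": "bioenergy", "ch4_share": 0.005, "bc_share": 0.002},
        {"pathway": "landfill", "ch4_share": 0.50, "bc_share": 0.0},
        {"pathway": "wetland_soil", "ch4_share": 1.0, "bc_share": 0.0},
    ]).to_csv(out / "speciation.csv", index=False)

    cfg = {
        "regions": regions,
        "ownerships": ownerships,
        "land_types": land_types,
        "severity": {"high_start": 0.26, "medium_start": 0.29,
                     "low_start": 0.45, "high_increment": 0.0027,
                     "start_year": 2010},
        "nonregen_fraction": 0.3,
        "gwp": {"co2": 1.0, "ch4": 25.0, "bc": 900.0, "bc_as_co2": True},
        "landfill_decay_rate": 0.03,
        "fresh_marsh_ch4_rate": 0.2,
        "urban_forest_base_fraction": 0.144,
    }
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    return out


#: the integrated scenario's prescriptions; individual scenarios partition it
BAU_PRESCRIPTIONS = [
    {"practice": "clearcut", "annual_area_ha": 400.0},
    {"practice": "thinning", "annual_area_ha": 1200.0},
    {"practice": "prescribed_burn", "annual_area_ha": 500.0},
    {"practice": "compost", "annual_area_ha": 2000.0, "repeat_interval": 10},
]


def generate_scenarios(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the scenario catalog: control, baseline, integrated, individual,
    and a restoration-competition case. Returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def write(name: str, doc: dict) -> None:
        path = out / f"{name}.yaml"
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        files[name] = path

    common = {"mortality_doubling": [2015, 2024], "bc_as_co2": True}
    write("ecosystem_control", {
        "name": "ecosystem_control", "wildfire": False, "nonregen": False,
        "lulcc_option": "none", "prescriptions": [], **common})
    write("baseline", {
        "name": "baseline", "wildfire": True, "nonregen": True,
        "lulcc_option": "land_use_driven", "prescriptions": [], **common})
    write("bau_all", {
        "name": "bau_all", "wildfire": True, "nonregen": True,
        "lulcc_option": "land_use_driven",
        "prescriptions": [dict(p) for p in BAU_PRESCRIPTIONS], **common})
    for p in BAU_PRESCRIPTIONS:
        write(f"individual_{p['practice']}", {
            "name": f"individual_{p['practice']}",
            "wildfire": True, "nonregen": True,
            "lulcc_option": "land_use_driven",
            "prescriptions": [dict(p)], **common})
    write("restoration_competition", {
        "name": "restoration_competition", "wildfire": False, "nonregen": False,
        "lulcc_option": "none",
        "prescriptions": [
            {"practice": "meadow_restoration",
             "annual_area_ha": spec.restoration_area_ha},
            {"practice": "woodland_restoration",
             "annual_area_ha": spec.restoration_area_ha},
        ], **common})
    return files
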