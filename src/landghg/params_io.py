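"""Parameter-table, scenario and run-configuration I/O.

A parameter directory holds schema'd CSVs (initial densities with standard
deviations, accumulation rates, mortality, practice definitions, wildfire
burn areas and severity effects, LULCC delta tables per option, conversion
dispositions, wood-product decay classes, burn speciation) plus a
``config.yaml`` of scalar parameters (severity schedule, GWPs, landfill
decay, non-regeneration fraction). Scenarios are YAML documents listing
prescriptions and option flags. All fractions are validated into [0, 1] at
load and every category referenced by a rate must exist.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .ghg_accounting import PATHWAYS, GwpSet
from .land_state import CATEGORY_INDEX, POOLS, LandStateError
from .management import PracticeDefinition, ProductParams
from .lulcc import ConversionDisposition
from .wildfire import SEVERITIES, SeveritySchedule


class ParameterError(ValueError):
    """Schema or cross-reference violation in an input file."""


# ---------------------------------------------------------------------------
# domain containers

@dataclass
class ParameterSet:
    regions: list[str]
    ownerships: list[str]
    land_types: list[str]
    initial: pd.DataFrame            # categories.csv rows
    rates: pd.DataFrame              # indexed by category: veg/soil mean & sd
    allocation: dict[str, dict[str, float]]
    mortality: pd.Series             # indexed by category, fraction/yr
    practices: dict[str, PracticeDefinition]
    burn_area: pd.Series             # (region, ownership) -> ha/yr
    fire_effects: pd.DataFrame       # (land_type, severity, pool)
    severity: SeveritySchedule
    nonregen_fraction: float
    lulcc: dict[str, pd.DataFrame]   # option -> delta table
    dispositions: dict[tuple[str, str], ConversionDisposition]
    products: ProductParams
    speciation: pd.DataFrame         # indexed by pathway
    gwp: GwpSet
    fresh_marsh_ch4_rate: float = 0.0   # Mg C/ha/yr of soil C emitted as CH4
    urban_forest_base_fraction: float = 0.144


@dataclass(frozen=True)
class Prescription:
    practice: str
    annual_area_ha: float
    start_year: int = 2010
    end_year: int = 2100
    repeat_interval: int = 1
    regions: tuple[str, ...] = ()
    ownerships: tuple[str, ...] = ()

    def active_in(self, year: int) -> bool:
        if not self.start_year <= year <= self.end_year:
            return False
        step = max(1, self.repeat_interval)
        return (year - self.start_year) % step == 0


@dataclass
class Scenario:
    name: str
    prescriptions: list[Prescription] = field(default_factory=list)
    lulcc_option: str = "none"       # none | land_use_driven | remote_sensing
    wildfire_on: bool = True
    nonregen_on: bool = True
    bc_as_co2: bool = True
    mortality_doubling: tuple[int, int] | None = (2015, 2024)
    climate_option: str = "historical"
    avoided_conversion: dict | None = None   # {start_year, end_year, end_multiplier}
    urban_forest: dict | None = None         # {mode, fraction / start.., end..}


@dataclass(frozen=True)
class RunConfig:
    start_year: int = 2010
    end_year: int = 2051
    uncertainty_case: str = "mean"   # mean | low_emission | high_emission
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if not self.start_year < self.end_year:
            raise ValueError("start_year must precede end_year")
        if self.end_year > 2100:
            raise ValueError("simulations run through 2100 at most")
        if self.uncertainty_case not in ("mean", "low_emission", "high_emission"):
            raise ValueError(f"unknown uncertainty case {self.uncertainty_case!r}")


# ---------------------------------------------------------------------------
# loading helpers

def _read_csv(directory: Path, name: str, required: list[str]) -> pd.DataFrame:
    path = directory / name
    if not path.exists():
        raise ParameterError(f"{name}: file missing from {directory}")
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise ParameterError(f"{name}: missing column {col!r}")
    return df


def _check_fraction(df: pd.DataFrame, name: str, cols: list[str]) -> None:
    for col in cols:
        bad = df[(df[col] < 0) | (df[col] > 1)]
        if len(bad):
            row = bad.index[0]
            raise ParameterError(
                f"{name}: row {row}, column {col}: value {bad[col].iloc[0]} "
                "outside [0,1]")


def _split(cell) -> tuple[str, ...]:
    if pd.isna(cell) or cell == "":
        return ()
    return tuple(str(cell).split("|"))


def load_parameters(directory: str | Path) -> ParameterSet:
    """Read and validate a full parameter directory."""
    directory = Path(directory)
    cfg_path = directory / "config.yaml"
    if not cfg_path.exists():
        raise ParameterError(f"config.yaml missing from {directory}")
    cfg = yaml.safe_load(cfg_path.read_text())

    cats = _read_csv(directory, "categories.csv",
                     ["region", "ownership", "land_type", "area_ha"])
    regions = cfg.get("regions") or sorted(cats["region"].unique())
    ownerships = cfg.get("ownerships") or sorted(cats["ownership"].unique())
    land_types = cfg.get("land_types") or sorted(cats["land_type"].unique())
    if (cats["area_ha"] < 0).any():
        row = cats[cats["area_ha"] < 0].index[0]
        raise ParameterError(f"categories.csv: row {row}: negative area")
    for col in cats.columns:
        if col.endswith("_sd") and (cats[col] < 0).any():
            raise ParameterError(f"categories.csv: negative SD in {col}")

    rates = _read_csv(directory, "rates.csv",
                      CATEGORY_INDEX + ["veg_mean", "veg_sd", "soil_mean", "soil_sd"])
    if (rates[["veg_sd", "soil_sd"]] < 0).any().any():
        raise ParameterError("rates.csv: negative SD")
    known = set(map(tuple, cats[CATEGORY_INDEX].itertuples(index=False)))
    for i, row in rates.iterrows():
        key = (row["region"], row["ownership"], row["land_type"])
        if key not in known:
            raise ParameterError(f"rates.csv: row {i}: unknown category {key}")
    rates = rates.set_index(CATEGORY_INDEX)

    alloc_df = _read_csv(directory, "allocation.csv",
                         ["land_type", "pool", "fraction"])
    _check_fraction(alloc_df, "allocation.csv", ["fraction"])
    allocation: dict[str, dict[str, float]] = {}
    for lt, grp in alloc_df.groupby("land_type"):
        allocation[lt] = dict(zip(grp["pool"], grp["fraction"]))
        if abs(sum(allocation[lt].values()) - 1.0) > 1e-9:
            raise ParameterError(
                f"allocation.csv: fractions for {lt} do not sum to 1")

    mort = _read_csv(directory, "mortality.csv", CATEGORY_INDEX + ["rate"])
    _check_fraction(mort, "mortality.csv", ["rate"])
    mortality = mort.set_index(CATEGORY_INDEX)["rate"]

    pr = _read_csv(directory, "practices.csv", ["name", "kind"])
    practices: dict[str, PracticeDefinition] = {}
    for i, row in pr.iterrows():
        removal = {}
        for pool in ("above_main", "understory", "down_dead", "litter"):
            col = f"removal_{pool}"
            if col in pr.columns and not pd.isna(row[col]) and row[col] != 0:
                removal[pool] = float(row[col])

        def num(col, default):
            return float(row[col]) if col in pr.columns and not pd.isna(row[col]) \
                else default

        try:
            practices[row["name"]] = PracticeDefinition(
                name=row["name"],
                kind=row["kind"],
                land_types=_split(row.get("land_types")),
                ownerships=_split(row.get("ownerships")),
                regions=_split(row.get("regions")),
                removal=removal,
                harvest_frac=num("harvest_frac", 1.0),
                slash_burn_frac=num("slash_burn_frac", 0.25),
                slash_collect_frac=num("slash_collect_frac", 0.0),
                product_frac=num("product_frac", 1.0),
                growth_mult=num("growth_mult", 1.0),
                growth_duration=int(num("growth_duration", 20)),
                mortality_mult=num("mortality_mult", 1.0),
                mortality_duration=int(num("mortality_duration", 0)),
                severity_reduction=num("severity_reduction", 0.0),
                severity_duration=int(num("severity_duration", 20)),
                to_type=row.get("to_type", "") if not pd.isna(row.get("to_type", "")) else "",
                sources=_split(row.get("sources")),
                soil_rate_delta=num("soil_rate_delta", 0.0),
                soil_effect_duration=int(num("soil_effect_duration", 1)),
            )
        except ValueError as exc:
            raise ParameterError(f"practices.csv: row {i}: {exc}") from exc

    burn = _read_csv(directory, "burn_area.csv", ["region", "ownership", "area_ha"])
    if (burn["area_ha"] < 0).any():
        raise ParameterError("burn_area.csv: negative burn area")
    burn_area = burn.set_index(["region", "ownership"])["area_ha"]

    fire = _read_csv(directory, "fire_effects.csv",
                     ["land_type", "severity", "pool",
                      "combusted_frac", "transfer_frac"])
    _check_fraction(fire, "fire_effects.csv", ["combusted_frac", "transfer_frac"])
    over = fire[fire["combusted_frac"] + fire["transfer_frac"] > 1 + 1e-12]
    if len(over):
        raise ParameterError(
            f"fire_effects.csv: row {over.index[0]}: combusted+transfer > 1")
    if not set(fire["severity"]).issubset(SEVERITIES):
        raise ParameterError("fire_effects.csv: unknown severity label")
    fire_effects = fire.set_index(["land_type", "severity", "pool"]).sort_index()

    sev_cfg = cfg.get("severity", {})
    severity = SeveritySchedule(
        high_start=float(sev_cfg.get("high_start", 0.26)),
        medium_start=float(sev_cfg.get("medium_start", 0.29)),
        low_start=float(sev_cfg.get("low_start", 0.45)),
        high_increment=float(sev_cfg.get("high_increment", 0.0027)),
        start_year=int(sev_cfg.get("start_year", 2010)),
    )

    lulcc: dict[str, pd.DataFrame] = {}
    for option in ("land_use_driven", "remote_sensing"):
        name = f"lulcc_{option}.csv"
        if (directory / name).exists():
            tbl = _read_csv(directory, name, CATEGORY_INDEX + ["delta_ha_yr"])
            ice = tbl[(tbl["land_type"] == "Ice") & (tbl["delta_ha_yr"] != 0)]
            if len(ice):
                raise ParameterError(f"{name}: row {ice.index[0]}: Ice delta "
                                     "must be zero (Ice area is constant)")
            lulcc[option] = tbl

    conv = _read_csv(directory, "conversions.csv",
                     ["from_type", "to_type", "burn_frac", "decay_frac",
                      "product_frac"])
    _check_fraction(conv, "conversions.csv",
                    ["burn_frac", "decay_frac", "product_frac"])
    dispositions = {}
    for i, row in conv.iterrows():
        try:
            dispositions[(row["from_type"], row["to_type"])] = ConversionDisposition(
                burn_frac=float(row["burn_frac"]),
                decay_frac=float(row["decay_frac"]),
                product_frac=float(row["product_frac"]),
            )
        except ValueError as exc:
            raise ParameterError(f"conversions.csv: row {i}: {exc}") from exc

    prod = _read_csv(directory, "products.csv",
                     ["class", "half_life_yr", "inflow_share"])
    _check_fraction(prod, "products.csv", ["inflow_share"])
    try:
        products = ProductParams(
            half_lives=dict(zip(prod["class"], prod["half_life_yr"])),
            inflow_shares=dict(zip(prod["class"], prod["inflow_share"])),
            landfill_decay_rate=float(cfg.get("landfill_decay_rate", 0.03)),
        )
    except ValueError as exc:
        raise ParameterError(f"products.csv: {exc}") from exc

    spec = _read_csv(directory, "speciation.csv",
                     ["pathway", "ch4_share", "bc_share"])
    _check_fraction(spec, "speciation.csv", ["ch4_share", "bc_share"])
    over = spec[spec["ch4_share"] + spec["bc_share"] > 1 + 1e-12]
    if len(over):
        raise ParameterError(
            f"speciation.csv: row {over.index[0]}: shares sum above 1")
    unknown = set(spec["pathway"]) - set(PATHWAYS)
    if unknown:
        raise ParameterError(f"speciation.csv: unknown pathway {sorted(unknown)}")
    speciation = spec.set_index("pathway")

    gwp_cfg = cfg.get("gwp", {})
    gwp = GwpSet(
        co2=float(gwp_cfg.get("co2", 1.0)),
        ch4=float(gwp_cfg.get("ch4", 25.0)),
        bc=float(gwp_cfg.get("bc", 900.0)),
        bc_as_co2=bool(gwp_cfg.get("bc_as_co2", True)),
    )

    return ParameterSet(
        regions=regions,
        ownerships=ownerships,
        land_types=land_types,
        initial=cats,
        rates=rates,
        allocation=allocation,
        mortality=mortality,
        practices=practices,
        burn_area=burn_area,
        fire_effects=fire_effects,
        severity=severity,
        nonregen_fraction=float(cfg.get("nonregen_fraction", 0.0)),
        lulcc=lulcc,
        dispositions=dispositions,
        products=products,
        speciation=speciation,
        gwp=gwp,
        fresh_marsh_ch4_rate=float(cfg.get("fresh_marsh_ch4_rate", 0.0)),
        urban_forest_base_fraction=float(cfg.get("urban_forest_base_fraction", 0.144)),
    )


def load_scenario(path: str | Path,
                  practices: dict[str, PracticeDefinition] | None = None) -> Scenario:
    """Read a scenario YAML file; defaults fill unspecified options."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) if path.exists() else None
    if not raw:
        raise ParameterError(f"{path}: empty or missing scenario file")
    if "name" not in raw:
        raise ParameterError(f"{path}: scenario must have a name")
    prescriptions = []
    seen = set()
    for i, p in enumerate(raw.get("prescriptions") or []):
        if "practice" not in p:
            raise ParameterError(f"{path}: prescription {i} missing practice")
        if practices is not None and p["practice"] not in practices:
            raise ParameterError(
                f"{path}: prescription {i}: unknown practice {p['practice']!r}")
        presc = Prescription(
            practice=p["practice"],
            annual_area_ha=float(p.get("annual_area_ha", 0.0)),
            start_year=int(p.get("start_year", 2010)),
            end_year=int(p.get("end_year", 2100)),
            repeat_interval=int(p.get("repeat_interval", 1)),
            regions=tuple(p.get("regions") or ()),
            ownerships=tuple(p.get("ownerships") or ()),
        )
        if presc.annual_area_ha < 0:
            raise ParameterError(f"{path}: prescription {i}: negative area")
        key = (presc.practice, presc.regions, presc.ownerships, presc.start_year)
        if key in seen:
            raise ParameterError(
                f"{path}: duplicate prescription for {presc.practice!r}")
        seen.add(key)
        prescriptions.append(presc)
    lulcc_option = raw.get("lulcc_option", "none")
    if lulcc_option not in ("none", "land_use_driven", "remote_sensing"):
        raise ParameterError(f"{path}: unknown lulcc_option {lulcc_option!r}")
    doubling = raw.get("mortality_doubling", [2015, 2024])
    return Scenario(
        name=raw["name"],
        prescriptions=prescriptions,
        lulcc_option=lulcc_option,
        wildfire_on=bool(raw.get("wildfire", True)),
        nonregen_on=bool(raw.get("nonregen", True)),
        bc_as_co2=bool(raw.get("bc_as_co2", True)),
        mortality_doubling=tuple(doubling) if doubling else None,
        climate_option=raw.get("climate_option", "historical"),
        avoided_conversion=raw.get("avoided_conversion"),
        urban_forest=raw.get("urban_forest"),
    )


def write_scenario(scenario: Scenario, path: str | Path) -> None:
    doc = {
        "name": scenario.name,
        "lulcc_option": scenario.lulcc_option,
        "wildfire": scenario.wildfire_on,
        "nonregen": scenario.nonregen_on,
        "bc_as_co2": scenario.bc_as_co2,
        "mortality_doubling": list(scenario.mortality_doubling)
        if scenario.mortality_doubling else None,
        "climate_option": scenario.climate_option,
        "prescriptions": [
            {
                "practice": p.practice,
                "annual_area_ha": p.annual_area_ha,
                "start_year": p.start_year,
                "end_year": p.end_year,
                "repeat_interval": p.repeat_interval,
                "regions": list(p.regions),
                "ownerships": list(p.ownerships),
            }
            for p in scenario.prescriptions
        ],
    }
    if scenario.avoided_conversion:
        doc["avoided_conversion"] = scenario.avoided_conversion
    if scenario.urban_forest:
        doc["urban_forest"] = scenario.urban_forest
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_outputs(outputs, config: RunConfig, directory: str | Path,
                  params_dir: str | Path | None = None) -> None:
    """Write a completed run to per-table CSVs plus a JSON manifest.

    ``outputs`` is the AnnualOutput series from the engine. Numeric columns
    are written with full precision so a re-run with the same config and
    seed is byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stocks = pd.concat([o.stocks.assign(year=o.year) for o in outputs])
    stocks.to_csv(directory / "stocks.csv", float_format="%.10g")
    emissions = pd.concat([o.emissions for o in outputs], ignore_index=True)
    emissions.to_csv(directory / "emissions.csv", index=False, float_format="%.10g")
    fluxes = pd.DataFrame([{"year": o.year, **o.fluxes} for o in outputs])
    fluxes.to_csv(directory / "fluxes.csv", index=False, float_format="%.10g")
    diag = pd.DataFrame([{"year": o.year, **o.diagnostics} for o in outputs])
    diag.to_csv(directory / "diagnostics.csv", index=False, float_format="%.10g")
    manifest = {
        "config": {
            "start_year": config.start_year,
            "end_year": config.end_year,
            "uncertainty_case": config.uncertainty_case,
            "seed": config.seed,
        },
        "years": [o.year for o in outputs],
    }
    if params_dir is not None:
        checksums = {}
        for f in sorted(Path(params_dir).iterdir()):
            if f.is_file():
                checksums[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        manifest["parameter_checksums"] = checksums
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def materialize_case(params: ParameterSet, case: str) -> ParameterSet:
    """Resolve an uncertainty case to concrete parameters.

    ``low_emission`` pairs low initial densities with high accumulation
    rates; ``high_emission`` the reverse; ``mean`` uses the means. Densities
    are floored at zero; accumulation rates may go negative (net sources).
    """
    offsets = {
        "mean": (0, 0),
        "low_emission": (-1, +1),
        "high_emission": (+1, -1),
    }
    if case not in offsets:
        raise ValueError(f"unknown uncertainty case {case!r}")
    d_off, a_off = offsets[case]
    cats = params.initial.copy()
    for pool in POOLS:
        mcol, scol = f"{pool}_mean", f"{pool}_sd"
        if mcol in cats.columns:
            sd = cats[scol] if scol in cats.columns else 0.0
            cats[mcol] = (cats[mcol] + d_off * sd).clip(lower=0.0)
    rates = params.rates.copy()
    rates["veg_mean"] = rates["veg_mean"] + a_off * rates["veg_sd"]
    rates["soil_mean"] = rates["soil_mean"] + a_off * rates["soil_sd"]
    return replace(params, initial=cats, rates=rates)
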