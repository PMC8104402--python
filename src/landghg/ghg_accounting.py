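"""Speciation of carbon fluxes and CO2-equivalent accounting.

Carbon leaving the land (combustion, decay, anaerobic decomposition) is
split by pathway into CO2, CH4 and black carbon (BC). Species masses are
reported in their own mass units (CO2 as 44/12 of its carbon, CH4 as 16/12,
BC as elemental carbon) and aggregated to CO2-equivalent with 100-year
global warming potentials. Sign convention: positive = emission to the
atmosphere, negative = sequestration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CO2_PER_C = 44.0 / 12.0
CH4_PER_C = 16.0 / 12.0

#: recognised emission pathways and their role
PATHWAYS = (
    "nee",           # net ecosystem exchange (negative C = uptake), pure CO2
    "wetland_soil",  # anaerobic soil decomposition (CH4-dominated)
    "wildfire",      # open burning of live and dead biomass
    "slash_burn",    # in-situ burning of harvest residue / prescribed burn
    "slash_decay",   # rapid decay of uncollected residue, pure CO2
    "bioenergy",     # combustion of collected biomass for energy
    "landfill",      # anaerobic decay of discarded wood products
    "conversion",    # decay of biomass cleared during land conversion
)


@dataclass(frozen=True)
class GwpSet:
    """100-yr global warming potentials; BC optionally treated as CO2."""

    co2: float = 1.0
    ch4: float = 25.0
    bc: float = 900.0
    bc_as_co2: bool = True

    def __post_init__(self):
        if min(self.co2, self.ch4, self.bc) <= 0:
            raise ValueError("GWP values must be positive")


@dataclass
class EmissionRecord:
    """One year x process flux, species masses in Mg of each species."""

    year: int
    pathway: str
    co2: float
    ch4: float
    bc: float

    @property
    def carbon(self) -> float:
        """Carbon content of the record, Mg C."""
        return self.co2 / CO2_PER_C + self.ch4 / CH4_PER_C + self.bc

    def co2eq(self, gwp: GwpSet) -> float:
        return co2eq(self.co2, self.ch4, self.bc, gwp)


def speciate(
    carbon: float,
    pathway: str,
    speciation: pd.DataFrame | dict[str, tuple[float, float]],
) -> tuple[float, float, float]:
    """Split a carbon mass into (CO2, CH4, BC) species masses.

    ``speciation`` maps pathway -> (ch4_share, bc_share) of the carbon; the
    remainder goes to CO2. Shares are fractions of carbon mass; species
    masses use molecular-weight conversion (CO2 x44/12, CH4 x16/12, BC as C).
    """
    if isinstance(speciation, pd.DataFrame):
        row = speciation.loc[pathway]
        ch4_share, bc_share = float(row["ch4_share"]), float(row["bc_share"])
    else:
        ch4_share, bc_share = speciation.get(pathway, (0.0, 0.0))
    if not (0 <= ch4_share <= 1 and 0 <= bc_share <= 1 and ch4_share + bc_share <= 1):
        raise ValueError(f"invalid speciation shares for {pathway}")
    ch4_c = carbon * ch4_share
    bc_c = carbon * bc_share
    co2_c = carbon - ch4_c - bc_c
    return co2_c * CO2_PER_C, ch4_c * CH4_PER_C, bc_c


def co2eq(co2: float, ch4: float, bc: float, gwp: GwpSet) -> float:
    """CO2-equivalent mass (Mg) of a species triple."""
    bc_gwp = gwp.co2 if gwp.bc_as_co2 else gwp.bc
    return co2 * gwp.co2 + ch4 * gwp.ch4 + bc * bc_gwp


@dataclass
class EmissionLedger:
    """Collects per-year, per-pathway emission records for a run."""

    records: list[EmissionRecord] = field(default_factory=list)

    def add_carbon(self, year: int, pathway: str, carbon: float,
                   speciation) -> EmissionRecord:
        """Speciate ``carbon`` (Mg C) on ``pathway`` and record it."""
        co2, ch4, bc = speciate(carbon, pathway, speciation)
        rec = EmissionRecord(year, pathway, co2, ch4, bc)
        self.records.append(rec)
        return rec

    def add_co2_carbon(self, year: int, pathway: str, carbon: float) -> EmissionRecord:
        """Record a pure-CO2 flux given its carbon mass (Mg C)."""
        rec = EmissionRecord(year, pathway, carbon * CO2_PER_C, 0.0, 0.0)
        self.records.append(rec)
        return rec

    def net_carbon(self, year: int | None = None) -> float:
        """Net emitted carbon in Mg C (negative = net uptake)."""
        return sum(r.carbon for r in self.records
                   if year is None or r.year == year)

    def to_frame(self, gwp: GwpSet) -> pd.DataFrame:
        rows = [
            {
                "year": r.year,
                "pathway": r.pathway,
                "co2_Mg": r.co2,
                "ch4_Mg": r.ch4,
                "bc_Mg": r.bc,
                "carbon_MgC": r.carbon,
                "co2eq_Mg": r.co2eq(gwp),
            }
            for r in self.records
        ]
        cols = ["year", "pathway", "co2_Mg", "ch4_Mg", "bc_Mg", "carbon_MgC", "co2eq_Mg"]
        return pd.DataFrame(rows, columns=cols)


def aggregate(
    records: pd.DataFrame, gwp: GwpSet | None = None, by: str = "year"
) -> pd.DataFrame:
    """Aggregate an emission-record frame to annual and cumulative series.

    Returns a frame indexed by ``by`` (default year) with ``annual_co2eq_Mg``,
    ``cumulative_co2eq_Mg`` and MMT (1e6 Mg) variants. If ``records`` lacks a
    ``co2eq_Mg`` column it is recomputed from the species columns.
    """
    df = records.copy()
    if "co2eq_Mg" not in df.columns:
        if gwp is None:
            raise ValueError("gwp required to recompute co2eq")
        df["co2eq_Mg"] = [
            co2eq(r.co2_Mg, r.ch4_Mg, r.bc_Mg, gwp) for r in df.itertuples()
        ]
    annual = df.groupby(by)["co2eq_Mg"].sum().sort_index()
    out = pd.DataFrame({"annual_co2eq_Mg": annual})
    out["cumulative_co2eq_Mg"] = out["annual_co2eq_Mg"].cumsum()
    out["annual_co2eq_MMT"] = out["annual_co2eq_Mg"] * 1e-6
    out["cumulative_co2eq_MMT"] = out["cumulative_co2eq_Mg"] * 1e-6
    return out
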