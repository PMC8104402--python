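"""Process 4: land use / land cover change and restoration.

Baseline annual area deltas (exogenous, from land-use-driven or
remote-sensing datasets) shift land-type areas within each fixed
region-ownership. Restoration practices convert source land to a target
type, competing for scarce sources; avoided conversion scales back urban
gains and returns the foregone area to its source types. Every conversion
moves the source's soil carbon with the land and disposes of its standing
biomass per a (from, to) disposition table — burned, rapidly decayed, sent
to wood products, or carried onto the destination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .land_state import POOLS, CarbonState, LandStateError


@dataclass(frozen=True)
class ConversionDisposition:
    """Fate of non-soil carbon on land converting between types.

    Fractions apply to each non-soil pool on the moved area; the remainder
    (1 - burn - decay - product) is carried into the destination category's
    matching pools where its mask allows, otherwise it decays.
    """

    burn_frac: float = 0.0
    decay_frac: float = 0.0
    product_frac: float = 0.0

    def __post_init__(self):
        s = self.burn_frac + self.decay_frac + self.product_frac
        if not 0.0 <= s <= 1.0 + 1e-12 or min(
            self.burn_frac, self.decay_frac, self.product_frac
        ) < 0:
            raise ValueError("disposition fractions must be in [0,1] and sum <= 1")

    @property
    def retained_frac(self) -> float:
        return max(0.0, 1.0 - self.burn_frac - self.decay_frac - self.product_frac)


#: carry everything (e.g. afforestation, non-regeneration)
CARRY_ALL = ConversionDisposition()
#: clear woody biomass to rapid decay (e.g. meadow restoration sources)
ALL_DECAY = ConversionDisposition(decay_frac=1.0)


@dataclass
class ConversionFlows:
    """Carbon mobilised by conversions this step, Mg C."""

    burned: float = 0.0
    decayed: float = 0.0
    to_products: float = 0.0

    def __iadd__(self, other: "ConversionFlows") -> "ConversionFlows":
        self.burned += other.burned
        self.decayed += other.decayed
        self.to_products += other.to_products
        return self


def validate_deltas(deltas: pd.DataFrame, areas: pd.Series,
                    tolerance: float = 1e-3,
                    nonconserving: tuple[str, ...] = ("Water", "Seagrass")) -> None:
    """Validate a LULCC delta table against the current land base.

    Ice must have zero delta; within each region-ownership the deltas must
    net to ~0 (relative to the region-ownership area) unless the imbalance
    is attributable to a declared non-conserving type (e.g. Water gain in
    remote-sensing datasets).
    """
    idx = deltas.set_index(["region", "ownership", "land_type"])["delta_ha_yr"]
    ice = idx[idx.index.get_level_values("land_type") == "Ice"]
    if (ice != 0.0).any():
        raise LandStateError("Ice area must remain constant: nonzero Ice delta")
    for (region, own), grp in idx.groupby(level=[0, 1]):
        net = float(grp.sum())
        conserving = grp[~grp.index.get_level_values("land_type").isin(nonconserving)]
        net_conserving = float(conserving.sum())
        ro_area = float(areas.loc[region, own].sum()) if (region, own) in \
            areas.groupby(level=[0, 1]).sum().index else 0.0
        tol = tolerance * max(ro_area, 1.0)
        if abs(net) > tol and abs(net_conserving) > tol:
            raise LandStateError(
                f"LULCC deltas for {region}/{own} net to {net:.3f} ha/yr "
                f"(tolerance {tol:.3f})")


def apply_baseline_lulcc(
    state: CarbonState,
    deltas: pd.Series,
    dispositions: dict[tuple[str, str], ConversionDisposition],
    year: int,
) -> ConversionFlows:
    """Apply one year of baseline area deltas with carbon bookkeeping.

    Within each region-ownership, shrinking types supply area to growing
    types in proportion to the gains; each implied (from, to) flow runs
    through :func:`conversion_carbon`. A loss exceeding the available area
    is floored at zero (unmet loss logged via the returned shortfall is
    simply forgone). Net imbalances (declared non-conserving types) appear
    or disappear with bare carbon so that mass still balances.
    """
    flows = ConversionFlows()
    df = state.df
    by_ro: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for key, delta in deltas.items():
        region, own, lt = key
        if delta == 0.0 or lt == "Ice":
            continue
        by_ro.setdefault((region, own), []).append((lt, float(delta)))
    for (region, own), items in sorted(by_ro.items()):
        losses = {}
        gains = {}
        for lt, delta in items:
            if delta < 0.0:
                avail = float(df.at[(region, own, lt), "area_ha"]) \
                    if (region, own, lt) in df.index else 0.0
                losses[lt] = min(-delta, avail)  # floor at zero area
            elif delta > 0.0:
                gains[lt] = delta
        total_loss = sum(losses.values())
        total_gain = sum(gains.values())
        matched = min(total_loss, total_gain)
        for src, loss in sorted(losses.items()):
            for dst, gain in sorted(gains.items()):
                if matched <= 0.0:
                    continue
                flow = matched * (loss / total_loss) * (gain / total_gain)
                if flow > 0.0:
                    disp = dispositions.get((src, dst),
                                            dispositions.get(("*", "*"), CARRY_ALL))
                    flows += conversion_carbon(state, region, own, src, dst, flow, disp)
        # residual loss: area leaves the land base (e.g. to Water); its
        # non-soil carbon decays, its soil carbon stays via merge into a
        # shrinking category (density unchanged as area shrinks -> carbon
        # lost); account it as decay to keep the ledger closed.
        if total_loss > matched:
            scale = (total_loss - matched) / total_loss
            for src, loss in sorted(losses.items()):
                extra = loss * scale
                if extra <= 0.0:
                    continue
                key = (region, own, src)
                dens = df.loc[key, list(POOLS)]
                df.at[key, "area_ha"] -= extra
                flows.decayed += float(extra * dens.sum())
        # residual gain: new area enters bare (zero density), diluting the
        # destination by area-weighted merge.
        if total_gain > matched and total_gain > 0.0:
            scale = (total_gain - matched) / total_gain
            for dst, gain in sorted(gains.items()):
                extra = gain * scale
                if extra <= 0.0:
                    continue
                key = (region, own, dst)
                old_area = float(df.at[key, "area_ha"])
                new_area = old_area + extra
                df.loc[key, list(POOLS)] = (
                    df.loc[key, list(POOLS)].to_numpy() * (old_area / new_area))
                df.at[key, "area_ha"] = new_area
    return flows


def avoided_conversion(
    deltas: pd.Series,
    multiplier: float,
) -> pd.Series:
    """Scale urban-gain deltas by ``multiplier``, returning adjusted deltas.

    The foregone urban gain within each region-ownership is returned to the
    source types in proportion to their baseline losses, so total area is
    conserved exactly.
    """
    if multiplier < 0.0:
        raise ValueError("negative urban-growth multiplier")
    adjusted = deltas.copy()
    frame = deltas.reset_index()
    frame.columns = ["region", "ownership", "land_type", "delta"]
    for (region, own), grp in frame.groupby(["region", "ownership"]):
        urban = grp[grp["land_type"] == "Urban"]
        if urban.empty:
            continue
        gain = float(urban["delta"].iloc[0])
        if gain <= 0.0:
            continue
        foregone = gain * (1.0 - multiplier)
        if foregone == 0.0:
            continue
        adjusted.loc[(region, own, "Urban")] = gain - foregone
        losses = grp[(grp["delta"] < 0.0) & (grp["land_type"] != "Urban")]
        total_loss = float(-losses["delta"].sum())
        if total_loss <= 0.0:
            # nothing to return area to: keep urban gain unscaled
            adjusted.loc[(region, own, "Urban")] = gain
            continue
        for row in losses.itertuples():
            share = -row.delta / total_loss
            adjusted.loc[(region, own, row.land_type)] = (
                row.delta + foregone * share)
    return adjusted


def linear_ramp(year: int, start_year: int, end_year: int,
                start_value: float, end_value: float) -> float:
    """Linearly interpolated multiplier, clamped outside the ramp."""
    if year <= start_year:
        return start_value
    if year >= end_year:
        return end_value
    f = (year - start_year) / (end_year - start_year)
    return start_value + f * (end_value - start_value)


@dataclass
class RestorationResult:
    realized: dict[str, float] = field(default_factory=dict)
    shortfall: dict[str, float] = field(default_factory=dict)


def apply_restoration(
    state: CarbonState,
    region: str,
    ownership: str,
    demands: list[tuple[str, str, tuple[str, ...], float]],
    dispositions: dict[tuple[str, str], ConversionDisposition],
) -> tuple[RestorationResult, ConversionFlows]:
    """Fulfil restoration targets within one region-ownership.

    ``demands`` holds (practice name, target type, source types, target ha).
    Each demand draws from its source types in proportion to availability;
    when competing demands oversubscribe a source, every draw on that
    source is scaled down proportionally. Realized conversions run through
    :func:`conversion_carbon`; restored area never reverts (handled by
    never listing restored types as sources).
    """
    df = state.df
    avail = {}
    for _, _, sources, _ in demands:
        for s in sources:
            key = (region, ownership, s)
            if s not in avail:
                avail[s] = float(df.at[key, "area_ha"]) if key in df.index else 0.0
    draws: dict[tuple[int, str], float] = {}
    for i, (name, to_type, sources, target) in enumerate(demands):
        pool = sum(avail.get(s, 0.0) for s in sources)
        if pool <= 0.0 or target <= 0.0:
            continue
        for s in sources:
            draws[(i, s)] = target * avail.get(s, 0.0) / pool
    # scale down oversubscribed sources proportionally
    for s, a in avail.items():
        total = sum(v for (i, src), v in draws.items() if src == s)
        if total > a and total > 0.0:
            scale = a / total
            for k in list(draws):
                if k[1] == s:
                    draws[k] *= scale
    result = RestorationResult()
    flows = ConversionFlows()
    for i, (name, to_type, sources, target) in enumerate(demands):
        got = 0.0
        for s in sources:
            amount = draws.get((i, s), 0.0)
            if amount <= 0.0:
                continue
            disp = dispositions.get((s, to_type),
                                    dispositions.get(("*", "*"), ALL_DECAY))
            flows += conversion_carbon(state, region, ownership, s, to_type,
                                       amount, disp)
            got += amount
        result.realized[name] = result.realized.get(name, 0.0) + got
        short = target - got
        if short > 1e-9:
            result.shortfall[name] = result.shortfall.get(name, 0.0) + short
    return result, flows


def conversion_carbon(
    state: CarbonState,
    region: str,
    ownership: str,
    from_type: str,
    to_type: str,
    area: float,
    disposition: ConversionDisposition,
) -> ConversionFlows:
    """Move ``area`` ha between land types, bookkeeping the carbon.

    The moved area carries the source's soil carbon into the destination's
    area-weighted soil density. Non-soil pools on the moved area are split
    by the disposition into burn / rapid decay / wood products; the
    retained remainder is carried into the destination's matching pools
    where its mask allows (otherwise it decays). Mass balance closes
    exactly: source loss = destination gain + returned flows.
    """
    if from_type == to_type or area == 0.0:
        return ConversionFlows()
    if area < 0.0:
        raise LandStateError("negative conversion area")
    df = state.df
    src_key = (region, ownership, from_type)
    dst_key = (region, ownership, to_type)
    if src_key not in df.index or dst_key not in df.index:
        raise LandStateError(f"unknown category in conversion {src_key}->{dst_key}")
    src_area = float(df.at[src_key, "area_ha"])
    if area > src_area * (1 + 1e-9):
        raise LandStateError(
            f"conversion area {area} exceeds source area {src_area} for {src_key}")
    area = min(area, src_area)
    dst_mask = state.mask_for(to_type)
    flows = ConversionFlows()
    incoming = {p: 0.0 for p in POOLS}  # Mg C arriving on the moved area
    for pool in POOLS:
        dens = float(df.at[src_key, pool])
        if dens == 0.0:
            continue
        mass = area * dens
        if pool == "soil":
            if "soil" in dst_mask:
                incoming["soil"] = mass
            else:
                flows.decayed += mass
            continue
        flows.burned += mass * disposition.burn_frac
        flows.decayed += mass * disposition.decay_frac
        flows.to_products += mass * disposition.product_frac
        retained = mass * disposition.retained_frac
        if retained > 0.0:
            if pool in dst_mask:
                incoming[pool] += retained
            else:
                flows.decayed += retained
    # source: area shrinks, densities unchanged
    df.at[src_key, "area_ha"] = src_area - area
    # destination: area-weighted merge of existing stock and incoming mass
    dst_area = float(df.at[dst_key, "area_ha"])
    new_area = dst_area + area
    for pool in POOLS:
        mass = dst_area * float(df.at[dst_key, pool]) + incoming[pool]
        df.at[dst_key, pool] = mass / new_area if new_area > 0 else 0.0
    df.at[dst_key, "area_ha"] = new_area
    return flows


def urban_forest_area(urban_area: float, fraction: float) -> float:
    """Urban forest area (ha) = canopy fraction x Urban land area."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("urban forest fraction outside [0,1]")
    if urban_area < 0.0:
        raise ValueError("negative urban area")
    return fraction * urban_area
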