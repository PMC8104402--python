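# Methods

This note documents the model's assumptions, the parameters that matter,
the synthetic-input generator, and the numerical and design choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Model structure and assumptions

The simulation unit is the land category — one region × ownership ×
land-type cell holding a single representative area and carbon-density
vector. There is no spatial adjacency, parcel tracking, or sub-annual
timestep. Region and ownership boundaries never change; only land-type
areas within a region-ownership move, and only in the conversion step.
Management acts on sub-areas whose effects are folded back into the
category by an area-weighted average; this means repeated treatments hit
the evolving category-average density rather than the density of untouched
stands, a structural approximation whose magnitude users can gauge by
comparing practices with identical parameters but different prescribed
areas (their per-area effects should nearly coincide).

Carbon is tracked internally in Mg C everywhere; conversion to species
masses (CO₂ ×44/12, CH₄ ×16/12, black carbon as elemental C) and to
CO₂-equivalent happens only in the GHG-accounting module, so there is a
single conversion point. Positive CO₂eq is an emission; sequestration is
negative.

The annual process order is a contract: (1) net ecosystem exchange then
mortality, (2) management, (3) wildfire, (4) conversion, with state
committed after each. Reordering the processes changes results; the
non-regeneration area computed in step 3 is executed in step 4 of the same
year. Within process 1 the model applies accumulation before mortality;
the alternative ordering (mortality first) would shift a one-year sliver
of biomass between live and dead pools and was fixed by choice, not data.

## Carbon pools and masks

Each land type carries a fixed subset of {soil, above-ground main canopy,
root, understory, standing dead, down dead, litter}. Water, ice, fresh
marsh, and seagrass are soil-only; barren and sparse add a main canopy;
tidal marsh, cultivated, and urban carry soil plus an above-ground canopy;
the upland woody and herbaceous types carry all seven. Masked pools are
structurally zero and checked after every simulated year. Fresh marsh
starts with zero area and zero carbon and exists only through restoration.

Urban above-ground carbon is interpreted as a whole-area average density,
with the urban-forest fraction (default 14.4 % of urban area) scaling the
urban vegetation accumulation rate proportionally when an expansion
schedule raises it. The alternative reading — densities defined only on
the urban-forest fraction — would rescale both density and rate by the
same factor and leave mass fluxes unchanged, so the choice affects
reported densities, not budgets.

## Key parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| GWP CH₄ / BC | 25 / 900 | — | 100-year horizon; BC counted as CO₂ by default |
| Severity start (high/med/low) | 0.26 / 0.29 / 0.45 | — | 2010 values |
| High-severity trend | +0.0027 | yr⁻¹ | low severity absorbs the change |
| Slash burn fraction | 0.25 (1.0 for prescribed burn) | — | remainder decays rapidly |
| Growth/severity effect window | 20 | yr | per-practice durations are data |
| Mortality doubling window | 2015–2024 | yr | emulates elevated die-off |
| Non-regeneration fraction | 0.3 (fixture) | — | of high-severity forest burn |
| Landfill decay rate | 0.03 | yr⁻¹ | landfill CH₄ share 0.5 (fixture) |
| Product half-lives | 10 / 50 (fixture) | yr | two in-use classes |
| Uncertainty cases | densities ∓1 SD, rates ±1 SD | — | paired low/high emission |

Vegetation-accumulation allocation across live pools (0.7/0.2/0.1
above/root/understory where present) and mortality routing (above→standing
dead, root→down dead, understory→litter) are parameter tables, not code;
the main-text literature for such models holds them in technical
documentation, so the package makes them data with those defaults. Dead
pools have no intrinsic turnover by default — wildfire and management are
their only exits unless a decay table is configured.

## Management mechanics

A practice removes per-pool fractions from its treated area; above-ground
removals split into harvest (to products/bioenergy) and slash, while
understory/dead/litter removals are all slash. Slash collection (for
utilization variants) is taken before the burn/decay split; "decays
rapidly" is implemented as same-year CO₂ emission. Bioenergy carbon is
emitted in the combustion year with no fossil-offset credit.

Multi-year effects live in a ledger of (category, practice, year, area)
entries. An entry applied in year *y* is active in years *y*+1 … *y*+D.
Growth and mortality multipliers are diluted to the category scale by the
entry's treated-area share before composing multiplicatively across
entries; severity reductions add with the same weighting. The dilution is
a deliberate design choice: an undiluted product of per-entry multipliers
would compound a 20-year backlog of annual treatments into implausible
rate inflation on large categories, whereas area-share dilution makes the
category-level effect equal the effect on the treated fraction. A single
entry covering the whole category contributes its full multiplier.

Soil practices (e.g. compost amendment) add a per-hectare soil-rate delta
on the treated area for a configurable number of years starting the year
after application.

## Wildfire

Burn areas are exogenous per region-ownership (constant under historical
climate); each year they are distributed across forest, woodland, savanna,
shrubland, and grassland in proportion to current areas and capped at the
burnable total. Severity fractions evolve linearly; because only the
high-severity trend is specified by the driving literature, the model
holds medium constant and lets low severity absorb the change,
renormalizing at the bounds. Management shifts the high fraction down by
the area-weighted sum of active severity reductions. Non-regeneration is
reduced to a single interior-burn fraction of high-severity forest area —
the categorical model has no burn-perimeter geometry from which to compute
an edge-distance criterion.

## Land conversion

Baseline deltas are validated at load (zero Ice delta; region-ownership
sums near zero, with declared non-conserving types such as Water exempt,
tolerance 0.1 % of region-ownership area). Within a region-ownership,
shrinking types supply growing types proportionally to the gains; losses
exceeding a category's remaining area are floored at zero and simply
forgone. Residual imbalances enter or leave the land base bare (gains) or
with their carbon routed to decay (losses), keeping the ledger closed.

Avoided conversion scales urban gains by a year-interpolated multiplier
and returns the foregone gain to source types in proportion to their
baseline losses — the redistribution rule is a declared choice since only
resulting areas, not the rule, are typically published. Restoration
demands draw from their source types proportionally to availability;
oversubscribed sources are shared among competing demands in proportion to
their draws, which yields equal splits for equal demands. Restored area
never reverts because restored types are never listed as sources.

Converted land carries its soil carbon into the destination's
area-weighted soil density; non-soil carbon follows a per-(from, to)
disposition among burning, rapid decay, wood products, and carry-over,
with carried carbon landing in matching destination pools (or decaying if
the destination mask lacks the pool). Incoming land otherwise starts bare
and builds carbon through subsequent accumulation.

## Uncertainty and diagnostics

The three-case suite shares scenario and seed and differs only in
materialized parameters: the low-emission case pairs low initial densities
with high accumulation, the high-emission case the reverse; densities are
floored at zero while accumulation rates may go negative (fluxes can be
sources). In undisturbed runs the cumulative-emission cases order
high ≥ mean ≥ low; interactions in managed scenarios can break the
ordering, and the zero-density clamp can make envelopes asymmetric.

Scenario effects are elementwise differences of aligned emission series.
Per-area annual effects divide the cumulative benefit by (cumulative
implementation area × implementation years); an annual-area mode divides
the annual average benefit by the annual area, appropriate for practices
whose benefits do not outlast the treatment year. The divergence-year
procedure reads each scenario's envelope as ±1 SD (averaging the upper and
lower half-widths because envelopes may be asymmetric), draws 5000 values
per year from the implied normal, discretizes to a 1 MMT CO₂eq grid
(nearest grid point), and applies a two-sample Z test at α = 0.05;
"divergence" is the first year from which significance persists through
the end of the run. With identical zero-variance inputs the test reports
no divergence. Because the test operates at α = 0.05, years in which two
scenarios truly coincide are flagged ~5 % of the time; constructed
validation series therefore keep their pre-change envelopes below half the
grid interval, which the discretization rounds to zero variance.

## The synthetic-input generator

Fixtures emulate the input shapes of a statewide parameterization at
reduced geography (default 2 × 2 × 8 categories): positive densities and
areas drawn log-normally around literature-scale means with ~30 % SDs, net
fluxes normal (sources allowed), the severity schedule and slash splits at
their standard values, two LULCC options (a land-use-driven table moving
area into urban, and a remote-sensing-style table with large
shrubland-to-grassland movement), and a practice set spanning a
clearcut-like, a thinning-like with 20-year growth/severity effects, a
prescribed burn, a soil amendment, and three restoration types. Magnitudes
are scaled so landscape totals are of order 1–100 MMT CO₂eq, keeping the
1-MMT divergence grid meaningful. A `scarce_grassland` knob shrinks the
shared restoration source to force land competition.

What fixtures do **not** reproduce: the real statewide parameter database
(thousands of values), realistic covariance between densities and rates,
climate-scenario burn trajectories, or N₂O (the model tracks carbon only).
Passing tests therefore demonstrate the bookkeeping — conservation,
ordering, interaction detection, arithmetic — not the calibration of any
real landscape.

## Numerical choices

- Carbon balance tolerance 10⁻⁶ relative per year (measured residuals are
  at rounding level, ~10⁻¹⁵); violations abort the run with year and
  process.
- Negative-density decrements clamp at zero and reduce reported uptake
  rather than creating carbon.
- Mortality and other fractional rates cap at 1 after doubling or
  multiplier effects.
- Elementary-operation tests compare against brute-force ledgers at 10⁻⁹
  relative.
- The core loop is deterministic; randomness exists only in fixture
  generation and divergence sampling, both seeded.
- Default span 2010–2051 (41 years of dynamics); runs are calendar-
  labelled with state at year start and permitted through 2100.

## Known limitations

- Category-average densities understate the depletion seen by repeated
  treatment of the same stands and overstate it for newly treated stands.
- Proportional burn allocation ignores fuel-load differences among types
  within a region-ownership.
- The single-fraction non-regeneration proxy cannot respond to fire size
  or shape.
- Wood products use two half-life classes and a single landfill pool; no
  market or merchantability structure.
- Scenario effects are only as meaningful as the chosen baseline; the
  package computes differences but cannot validate baseline choice.
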