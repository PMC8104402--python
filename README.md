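# landghg

An annual-timestep bookkeeping model of landscape carbon and greenhouse-gas
dynamics for categorical land bases, in the tradition of regional natural-
and-working-lands carbon accounting models. It is built for analysts who
need to estimate the *effect of land management* — forest treatments,
restoration, soil amendments, avoided urban conversion — on a landscape's
net GHG balance, relative to a baseline, together with honest uncertainty
envelopes around those estimates.

## The model

The landscape is partitioned into **land categories**: region × ownership ×
land-type cells, each a single unit with a representative area $A$ (ha) and
a carbon-density vector $d_p$ (Mg C ha⁻¹) over up to seven pools (soil,
main-canopy above-ground and root, understory, standing dead, down dead,
litter; each land type carries only the pools in its mask). Each simulated
year applies four processes in fixed order, committing state after each:

1. **Net ecosystem exchange and mortality.** Empirical net vegetation and
   soil accumulation rates (Mg C ha⁻¹ yr⁻¹, mean ± SD) are scaled by
   optional climate scalars and by management growth multipliers, allocated
   across live pools, and added to densities; mortality transfers a
   fraction of live biomass to dead pools.
2. **Management.** Prescribed practice areas are distributed proportionally
   over eligible categories; per-pool removal fractions act on the treated
   sub-area, which is merged back by area-weighted average. Removals split
   into harvest and slash; slash partitions into in-situ burning (25 % by
   default, 100 % for prescribed burn), rapid decay, and optional
   collection; harvested and collected carbon flows to wood products (with
   first-order half-life decay to a landfill pool emitting CO₂/CH₄) and
   bioenergy. Practices leave multi-year growth, mortality, and
   fire-severity effects in a rolling ledger (20-year default windows).
3. **Wildfire.** Prescribed region-ownership burn areas are distributed
   proportionally over the five burnable types. Severity fractions start at
   0.26/0.29/0.45 (high/medium/low) and the high fraction rises 0.0027 yr⁻¹,
   reduced by recent fuel treatment; severity- and pool-specific fractions
   of carbon are combusted (speciated into CO₂, CH₄, and black carbon) or
   transferred live→dead. A fraction of high-severity burned forest fails
   to regenerate and converts to shrubland.
4. **Land conversion.** Exogenous annual area deltas (land-use-driven or
   remote-sensing option), avoided-conversion scaling of urban growth,
   restoration with proportional competition for scarce source land, and
   execution of non-regeneration. Converted land carries its soil carbon;
   standing biomass follows a per-pair disposition (burn / decay /
   products / carry).

Fluxes are speciated and aggregated to CO₂-equivalent with 100-year GWPs
(CO₂ 1, CH₄ 25, BC 900 or counted as CO₂). Every year the model verifies

$$\Delta(\text{ecosystem C} + \text{product C}) + \text{net emitted C} = 0$$

to 10⁻⁶ relative and aborts on violation. Scenario effects are computed by
differencing a baseline's emission series; input uncertainty is bracketed
by paired low/high cases (densities ∓1 SD with accumulation ±1 SD) and a
Z-test procedure locates the year two scenarios' envelopes durably diverge.

## Worked example

Everything runs from synthetic inputs generated at reduced geography
(2 regions × 2 ownerships × 8 land types), so no data download is needed:

```sh
landghg fixtures --seed 3 --out fx
landghg run --params fx/params --scenario fx/scenarios/bau_all.yaml \
    --start 2010 --end 2021 --seed 3 --out fx/run_bau
landghg run --params fx/params --scenario fx/scenarios/baseline.yaml \
    --start 2010 --end 2021 --seed 3 --out fx/run_base
landghg diff --alt fx/run_bau --base fx/run_base --out fx/diff
```

prints

```
bau_all: 11 years -> fx/run_bau
final ecosystem C: 2.94e+08 Mg C; net CO2eq (final year): -4.095e+06 Mg
baseline: 11 years -> fx/run_base
final ecosystem C: 2.949e+08 Mg C; net CO2eq (final year): -4.293e+06 Mg
cumulative difference: 2.00543e+06 Mg CO2eq
```

The landscape is a net sink (≈ −4.1 MMT CO₂eq yr⁻¹ under management), but
management *raises* cumulative emissions by ≈ 2.0 MMT CO₂eq over 11 years
relative to the no-management baseline — the kind of relative estimate the
model is designed to make robustly even when the absolute sign of the
landscape budget is uncertain. Envelope metrics are available directly:

```sh
landghg metrics --low 687 --mean 1080 --high 1494
{"relative_uncertainty_pct": 74.72222222222223}
```

i.e. an envelope of 687–1494 MMT CO₂eq spans ~75 % of its 1080 MMT mean.

The same workflow is available as a library: `generate_params` /
`generate_scenarios`, `load_parameters` / `load_scenario`, `run_scenario` /
`run_uncertainty_suite`, and the `diagnostics` module
(`scenario_difference`, `summed_vs_simultaneous`, `divergence_year`,
`per_area_annual_effect`, `relative_uncertainty`).

## Layout

- `src/landghg/land_state.py` — categories, pool masks, area-weighted merge
- `src/landghg/ecosystem_flux.py` — NEE, climate scalars, mortality
- `src/landghg/management.py` — practices, slash, wood products, effect ledger
- `src/landghg/wildfire.py` — burn allocation, severity, combustion, non-regeneration
- `src/landghg/lulcc.py` — baseline deltas, restoration, avoided conversion
- `src/landghg/ghg_accounting.py` — speciation, GWPs, aggregation
- `src/landghg/engine.py` — the annual loop and uncertainty suite
- `src/landghg/diagnostics.py` — differencing, Z-test divergence, metrics
- `src/landghg/fixtures.py` — seeded synthetic-input generator
- `src/landghg/params_io.py`, `src/landghg/cli.py` — formats and CLI

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
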