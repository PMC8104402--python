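"""Post-processing: scenario differencing and uncertainty metrics.

Management effects are isolated by differencing a baseline run's emission
series from an alternative run's (negative = benefit). Per-area annual
effects normalise a cumulative benefit by implementation area and period.
Summed-versus-simultaneous comparison quantifies interaction effects among
practices. The divergence-year procedure treats each scenario's uncertainty
envelope as +-1 SD of a normal distribution, samples it on a fixed
CO2eq grid, and finds the first year from which a two-sample Z test stays
significant through the end of the run. Relative uncertainty expresses an
envelope width as a percentage of a reference value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

Z_CRITICAL_95 = 1.959963984540054  # two-sided alpha = 0.05


@dataclass
class EmissionSeries:
    """Aligned annual/cumulative CO2eq series with optional envelope."""

    years: np.ndarray
    annual: np.ndarray
    cumulative: np.ndarray | None = None
    low: np.ndarray | None = None   # cumulative lower envelope
    high: np.ndarray | None = None  # cumulative upper envelope

    def __post_init__(self):
        self.years = np.asarray(self.years)
        self.annual = np.asarray(self.annual, dtype=float)
        if self.cumulative is None:
            self.cumulative = np.cumsum(self.annual)
        else:
            self.cumulative = np.asarray(self.cumulative, dtype=float)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, column: str = "annual_co2eq_Mg"
                   ) -> "EmissionSeries":
        return cls(df.index.to_numpy(), df[column].to_numpy())


def scenario_difference(alt: EmissionSeries, baseline: EmissionSeries
                        ) -> EmissionSeries:
    """Elementwise alt - baseline (annual and cumulative); negative = benefit."""
    if not np.array_equal(alt.years, baseline.years):
        raise ValueError("scenario years are not aligned")
    return EmissionSeries(
        alt.years,
        alt.annual - baseline.annual,
        alt.cumulative - baseline.cumulative,
    )


def per_area_annual_effect(
    cumulative_benefit: float,
    annual_area_ha: float,
    years: int,
    mode: str = "cumulative_area",
) -> float:
    """Average annual per-area effect, Mg CO2eq ha^-1 yr^-1.

    ``cumulative_area`` mode divides the cumulative benefit by the product
    of the cumulative implementation area (annual area x years) and the
    number of implementation years — appropriate for practices with lasting
    effects. ``annual_area`` mode divides the annual average benefit by the
    annual area — appropriate when benefits do not outlast the treatment
    year (e.g. cultivated soil conservation).
    """
    if annual_area_ha <= 0:
        raise ValueError("annual area must be positive")
    if years < 1:
        raise ValueError("need at least one implementation year")
    if mode == "cumulative_area":
        return cumulative_benefit / ((annual_area_ha * years) * years)
    if mode == "annual_area":
        return (cumulative_benefit / years) / annual_area_ha
    raise ValueError(f"unknown mode {mode!r}")


def summed_vs_simultaneous(
    individual: list[EmissionSeries], integrated: EmissionSeries
) -> pd.DataFrame:
    """Compare the sum of individual-practice effects with the integrated run.

    Returns a frame with the summed series, the integrated series, and
    their difference (summed - integrated), annually and cumulatively. A
    nonzero difference is the interaction effect of simultaneous practices.
    """
    years = integrated.years
    summed_annual = np.zeros_like(integrated.annual)
    for s in individual:
        if not np.array_equal(s.years, years):
            raise ValueError("scenario years are not aligned")
        summed_annual = summed_annual + s.annual
    out = pd.DataFrame(
        {
            "summed_annual": summed_annual,
            "integrated_annual": integrated.annual,
            "difference_annual": summed_annual - integrated.annual,
        },
        index=pd.Index(years, name="year"),
    )
    out["summed_cumulative"] = out["summed_annual"].cumsum()
    out["integrated_cumulative"] = out["integrated_annual"].cumsum()
    out["difference_cumulative"] = (
        out["summed_cumulative"] - out["integrated_cumulative"])
    return out


def divergence_year(
    mean_a: np.ndarray,
    env_a: tuple[np.ndarray, np.ndarray],
    mean_b: np.ndarray,
    env_b: tuple[np.ndarray, np.ndarray],
    years: np.ndarray | None = None,
    n: int = 5000,
    interval: float = 1e6,
    alpha: float = 0.05,
    seed: int = 0,
) -> int | None:
    """First year from which two scenarios stay significantly different.

    Each scenario's envelope (low, high cumulative series) is read as
    +-1 SD about its mean; the per-year SD is the average of the upper and
    lower half-widths (envelopes are slightly asymmetric). ``n`` values per
    scenario are drawn from the implied normal, discretised to the nearest
    ``interval`` grid point (default 1 MMT when series are in Mg), and
    compared with a two-sample Z test. Returns the first year that is
    significant in every year through the end, or None.
    """
    from scipy.stats import norm

    mean_a = np.asarray(mean_a, float)
    mean_b = np.asarray(mean_b, float)
    sd_a = 0.5 * (np.abs(np.asarray(env_a[1], float) - mean_a)
                  + np.abs(mean_a - np.asarray(env_a[0], float)))
    sd_b = 0.5 * (np.abs(np.asarray(env_b[1], float) - mean_b)
                  + np.abs(mean_b - np.asarray(env_b[0], float)))
    z_crit = norm.ppf(1.0 - alpha / 2.0)
    rng = np.random.default_rng(seed)
    n_years = len(mean_a)
    significant = np.zeros(n_years, dtype=bool)
    for i in range(n_years):
        if sd_a[i] == 0.0 and sd_b[i] == 0.0:
            significant[i] = False  # degenerate: no sampling variance
            continue
        xa = np.round(rng.normal(mean_a[i], sd_a[i], n) / interval) * interval
        xb = np.round(rng.normal(mean_b[i], sd_b[i], n) / interval) * interval
        va, vb = xa.var(ddof=1), xb.var(ddof=1)
        denom = np.sqrt(va / n + vb / n)
        if denom == 0.0:
            significant[i] = xa.mean() != xb.mean()
            continue
        z = (xa.mean() - xb.mean()) / denom
        significant[i] = abs(z) > z_crit
    # sustained significance: significant from some year through the end
    sustained_from = None
    for i in range(n_years - 1, -1, -1):
        if significant[i]:
            sustained_from = i
        else:
            break
    if sustained_from is None:
        return None
    if years is not None:
        return int(np.asarray(years)[sustained_from])
    return int(sustained_from)


def relative_uncertainty(
    low: float, reference: float, high: float, mode: str = "of_mean"
) -> float:
    """Envelope width as a percent of a reference magnitude.

    ``of_mean`` uses the supplied reference (typically the mean-case value);
    ``of_midpoint`` ignores it and uses (low + high) / 2. Scale-invariant;
    sign-insensitive in the reference.
    """
    if high < low:
        raise ValueError("high must be >= low")
    if mode == "of_midpoint":
        reference = (low + high) / 2.0
    elif mode != "of_mean":
        raise ValueError(f"unknown mode {mode!r}")
    if reference == 0.0:
        raise ValueError("zero reference value")
    return 100.0 * (high - low) / abs(reference)
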