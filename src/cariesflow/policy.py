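"""Tiered SSB excise schedule, price pass-through and policy scenarios.

The Thai tiered excise levies a specific (per-litre) tax that depends on the
sugar content of the beverage (g/100 ml) and escalates in steps through the
simulation horizon.  Three named scenarios are modelled:

* ``base_case`` — no tax, all behaviour unchanged (the pre-tax reference);
* ``ssb_tax`` — the tiered tax from 2018 onward, transmitted to consumers
  through price pass-through and to products through reformulation;
* ``aggressive`` — the tax plus an 80% reduction of non-SSB sugar intake and
  a 50% boost of the dental-service uptake rate, both from 2018.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TaxSchedule",
    "PriceResponse",
    "Scenario",
    "make_scenario",
    "relative_price_change",
    "reformulated_content",
    "DEFAULT_TAX_SCHEDULE",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("base_case", "ssb_tax", "aggressive")

# tier upper bounds in g/100 ml (closed on top; last tier is unbounded)
_TIER_UPPER = (5.99, 8.0, 10.0, 14.0, 18.0, np.inf)
# period start years; the first period opens at policy start (2018) and the
# last runs to the end of the horizon
_PERIOD_STARTS = (2018, 2021, 2023, 2025)
# Baht per litre, rows = tiers, columns = periods
_RATES = np.array(
    [
        [0.0, 0.0, 0.0, 0.0],
        [0.1, 0.1, 0.3, 1.0],
        [0.3, 0.3, 1.0, 3.0],
        [0.5, 1.0, 3.0, 5.0],
        [1.0, 3.0, 5.0, 5.0],
        [1.0, 5.0, 5.0, 5.0],
    ]
)


@dataclass(frozen=True)
class TaxSchedule:
    """Specific tax (Baht/litre) by sugar-content tier and calendar period.

    Tier intervals are closed on top (8.0 g/100 ml belongs to the 6.0-8.0
    tier) and partition [0, inf).  The first-tier boundary is effectively
    6.0: the printed 0-5.99 label leaves (5.99, 6.0) unassigned, which is
    resolved by extending the untaxed tier up to (but excluding) 6.0.
    Rates are non-negative and non-decreasing over periods within each tier.
    """

    tier_upper: tuple = _TIER_UPPER
    period_starts: tuple = _PERIOD_STARTS
    rates: np.ndarray = field(default_factory=lambda: _RATES.copy())
    start_year: int = 2018

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        if rates.shape != (len(self.tier_upper), len(self.period_starts)):
            raise ValueError("rates must be (n_tiers, n_periods)")
        if np.any(rates < 0):
            raise ValueError("tax rates must be non-negative")
        if np.any(np.diff(rates, axis=1) < 0):
            raise ValueError("tax rates must be non-decreasing across periods")
        object.__setattr__(self, "rates", rates)

    def tier_index(self, sugar_content: float) -> int:
        """Index of the tier containing a sugar content (g/100 ml)."""
        if sugar_content < 0:
            raise ValueError("sugar content cannot be negative")
        # first tier extends up to (but excluding) the next tier's lower
        # bound; remaining tiers are closed on top
        if sugar_content < 6.0:
            return 0
        for i, ub in enumerate(self.tier_upper[1:-1], start=1):
            if sugar_content <= ub:
                return i
        return len(self.tier_upper) - 1

    def tax_rate(self, sugar_content: float, year: float) -> float:
        """Specific tax (Baht/litre) for a sugar content and calendar year."""
        if year < self.period_starts[0]:
            return 0.0
        period = int(np.searchsorted(self.period_starts, year, side="right") - 1)
        return float(self.rates[self.tier_index(sugar_content), period])

    def max_rate(self, sugar_content: float) -> float:
        """Fully escalated (final-period) rate for a sugar content."""
        return float(self.rates[self.tier_index(sugar_content), -1])

    @classmethod
    def from_csv(cls, path: str | Path, start_year: int = 2018) -> "TaxSchedule":
        """Load a schedule from CSV with columns
        (tier_low_g_per_100ml, tier_high_g_per_100ml, year_start, year_end, baht).
        """
        df = pd.read_csv(path)
        need = {"tier_low_g_per_100ml", "tier_high_g_per_100ml", "year_start", "year_end", "baht"}
        if not need.issubset(df.columns):
            raise ValueError(f"schedule CSV must have columns {sorted(need)}")
        uppers = tuple(sorted(df["tier_high_g_per_100ml"].unique()))
        uppers = tuple(np.inf if u >= 1e9 else u for u in uppers)
        starts = tuple(sorted(df["year_start"].unique()))
        rates = np.zeros((len(uppers), len(starts)))
        for _, row in df.iterrows():
            hi = np.inf if row.tier_high_g_per_100ml >= 1e9 else row.tier_high_g_per_100ml
            i = uppers.index(hi)
            j = starts.index(row.year_start)
            rates[i, j] = row.baht
        return cls(tier_upper=uppers, period_starts=starts, rates=rates,
                   start_year=int(min(starts)))


DEFAULT_TAX_SCHEDULE = TaxSchedule()


@dataclass(frozen=True)
class PriceResponse:
    """How the specific tax reaches consumers and products.

    passthrough
        Fraction of the tax passed into the consumer price (1.0 = full).
    reference_price
        Pre-tax average SSB price, Baht/litre; only relative price changes
        enter the demand response.
    percent_reduce_ssb_sugar
        Proportional sugar-content reduction achieved by products that
        reformulate (0.8 by default).
    reformulating_fraction
        Market share of products that reformulate in response to the tiered
        incentive; the average content falls by
        ``percent_reduce * reformulating_fraction`` at full phase-in.
    ad_valorem_extra
        Optional additional fractional price increment representing the ad
        valorem tax component (0 by default; only the specific component is
        modelled explicitly).
    """

    passthrough: float = 1.0
    reference_price: float = 20.0
    percent_reduce_ssb_sugar: float = 0.8
    reformulating_fraction: float = 0.5
    ad_valorem_extra: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.passthrough <= 1.5:
            raise ValueError("passthrough must lie in [0, 1.5]")
        if self.reference_price <= 0:
            raise ValueError("reference price must be positive")
        if not 0.0 <= self.percent_reduce_ssb_sugar <= 1.0:
            raise ValueError("percent_reduce_ssb_sugar must lie in [0,1]")
        if not 0.0 <= self.reformulating_fraction <= 1.0:
            raise ValueError("reformulating_fraction must lie in [0,1]")
        if self.ad_valorem_extra < 0:
            raise ValueError("ad_valorem_extra must be non-negative")


@dataclass(frozen=True)
class Scenario:
    """A named policy package."""

    name: str
    tax_on: bool
    nonssb_reduction: float = 0.0
    uptake_boost: float = 1.0
    start_year: int = 2018

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonssb_reduction <= 1.0:
            raise ValueError("nonssb_reduction must lie in [0,1]")
        if self.uptake_boost < 1.0:
            raise ValueError("uptake_boost must be >= 1")


def make_scenario(name: str) -> Scenario:
    """Construct one of the three named scenarios."""
    if name == "base_case":
        return Scenario("base_case", tax_on=False, nonssb_reduction=0.0, uptake_boost=1.0)
    if name == "ssb_tax":
        return Scenario("ssb_tax", tax_on=True, nonssb_reduction=0.0, uptake_boost=1.0)
    if name == "aggressive":
        return Scenario("aggressive", tax_on=True, nonssb_reduction=0.80,
                        uptake_boost=1.5, start_year=2018)
    raise KeyError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")


def relative_price_change(tax: float, response: PriceResponse) -> float:
    """Fractional consumer price change implied by a specific tax.

    ``passthrough * tax / reference_price`` plus any configured ad valorem
    increment while a tax applies; exactly 0 when the tax is 0.
    """
    if response.reference_price <= 0:
        raise ValueError("reference price must be positive")
    if tax < 0:
        raise ValueError("tax must be non-negative")
    if tax == 0.0:
        return 0.0
    return response.passthrough * tax / response.reference_price + response.ad_valorem_extra


def reformulated_content(
    base_content: float,
    response: PriceResponse,
    year: float,
    schedule: TaxSchedule = DEFAULT_TAX_SCHEDULE,
) -> float:
    """Average SSB sugar content (kg/litre) after reformulation phase-in.

    The tiered tax is designed to push producers to cut sugar content; the
    average content falls by ``percent_reduce * reformulating_fraction``
    scaled by a phase-in factor equal to the schedule's escalation at the
    *base* content (current rate / fully escalated rate).  Content never
    increases while the tax escalates, and is unchanged before the policy
    start or when the base content sits in the untaxed tier.
    """
    if base_content <= 0:
        raise ValueError("base content must be positive")
    if year < schedule.start_year:
        return base_content
    g_per_100ml = base_content * 100.0  # kg/litre -> g/100 ml
    full = schedule.max_rate(g_per_100ml)
    if full <= 0:
        return base_content
    phase = schedule.tax_rate(g_per_100ml, year) / full
    cut = response.percent_reduce_ssb_sugar * response.reformulating_fraction * phase
    return base_content * (1.0 - cut)
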