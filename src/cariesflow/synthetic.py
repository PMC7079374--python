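"""Synthetic exogenous inputs: demography, prices, and sugar consumption.

No public microdata accompany the model, so every exogenous series the
simulator consumes is generated here from printed anchors:

* a 15+ population trajectory through anchor totals (monotone piecewise-cubic
  interpolation), decomposed into entrants and deaths with a two-band
  bookkeeping model so the balance identity holds by construction;
* non-SSB sugar consumption per income group through the printed 2018/2040
  anchors (constant-growth reported history, extended by a 4-year
  percent-change moving average);
* initial SSB consumption per income group calibrated so the population-level
  SSB share of total sugar matches the national 2000/2015 anchors;
* an SSB reference price series (constant real price unless supplied).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .series import AnnualSeries, extrapolate_pct_change_ma

__all__ = [
    "SugarAnchors",
    "ExogenousInputs",
    "build_population_trajectory",
    "build_nonssb_series",
    "calibrate_initial_ssb",
    "default_inputs",
    "DEFAULT_POPULATION_ANCHORS",
    "NONSSB_ANCHORS",
    "DEFAULT_SUGAR_ANCHORS",
]

# Population anchor totals (persons): reference projection column sums.
DEFAULT_POPULATION_ANCHORS: dict[int, float] = {
    2010: 50.40e6,
    2020: 53.37e6,
    2030: 54.10e6,
    2040: 52.62e6,
}

# Non-SSB (other) sugar consumption anchors, kg/person/year, by income group.
NONSSB_ANCHORS: dict[str, dict[int, float]] = {
    "low": {2018: 22.35, 2040: 28.04},
    "high": {2018: 33.01, 2040: 43.15},
}

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class SugarAnchors:
    """National total-sugar and SSB-share anchors (per-person averages)."""

    total_sugar_2000: float = 76.19   # g/person/day
    total_sugar_2015: float = 104.46  # g/person/day
    ssb_share_2000: float = 0.15
    ssb_share_2015: float = 0.21

    def __post_init__(self) -> None:
        if self.total_sugar_2000 <= 0 or self.total_sugar_2015 <= 0:
            raise ValueError("total sugar anchors must be positive")
        for s in (self.ssb_share_2000, self.ssb_share_2015):
            if not 0.0 <= s <= 1.0:
                raise ValueError("SSB shares must lie in [0,1]")


@dataclass
class ExogenousInputs:
    """Bundle of exogenous series consumed by the simulator."""

    population_total: AnnualSeries
    entrants: AnnualSeries
    deaths: AnnualSeries
    mortality_35plus: float
    band35_fraction: float
    ssb_price: AnnualSeries
    nonssb_sugar: dict[str, AnnualSeries]
    initial_ssb_litres: dict[str, float]

    def balance_residuals(self) -> np.ndarray:
        """population(y) - population(y-1) - entrants(y) + deaths(y) per year."""
        p = self.population_total.values
        e = self.entrants.values
        d = self.deaths.values
        return p[1:] - p[:-1] - e[1:] + d[1:]


def build_population_trajectory(
    anchor_years: list[int] | dict[int, float],
    anchor_totals: list[float] | None = None,
    mortality_config: dict | None = None,
    seed: int | None = None,
) -> ExogenousInputs:
    """Generate a population trajectory plus consistent entrants and deaths.

    The total passes through the anchors via monotone piecewise-cubic
    (PCHIP) interpolation, which cannot overshoot between anchors.  A
    two-band bookkeeping model (15-34 / 35+, aging hazard 1/20 per year,
    deaths acting on the 35+ band) back-solves the annual entrant flow so
    that ``population(y) = population(y-1) + entrants(y) - deaths(y)``
    holds exactly.

    Only the demographic fields of the returned :class:`ExogenousInputs`
    are populated; price and sugar fields carry neutral placeholders.
    ``seed`` is accepted for interface uniformity (the default generator is
    deterministic and draws nothing).
    """
    if isinstance(anchor_years, dict):
        anchors = dict(sorted(anchor_years.items()))
    else:
        if anchor_totals is None or len(anchor_totals) != len(anchor_years):
            raise ValueError("anchor_years and anchor_totals must align")
        anchors = dict(sorted(zip(anchor_years, anchor_totals)))
    if len(anchors) < 2:
        raise ValueError("at least 2 population anchors are required")
    if any(v <= 0 for v in anchors.values()):
        raise ValueError("anchor totals must be positive")

    cfg = {"mortality_35plus": 0.015, "band35_fraction": 0.6, "mortality_15_34": 0.0}
    cfg.update(mortality_config or {})
    m_old = float(cfg["mortality_35plus"])
    m_young = float(cfg["mortality_15_34"])
    f_old = float(cfg["band35_fraction"])
    aging = 1.0 / 20.0

    years = np.arange(min(anchors), max(anchors) + 1)
    interp = PchipInterpolator(list(anchors), list(anchors.values()))
    totals = np.asarray(interp(years), dtype=float)

    young = totals[0] * (1.0 - f_old)
    old = totals[0] * f_old
    entrants = [0.0]
    deaths = [0.0]
    for k in range(1, len(years)):
        die = m_old * old + m_young * young
        age_flow = aging * young
        e = totals[k] - totals[k - 1] + die
        if e < 0:
            # a shrinking population beyond what deaths explain: absorb the
            # residual as additional (age-spread) deaths instead of removals
            die -= e
            e = 0.0
        young = young + e - age_flow - m_young * young
        old = totals[k] - young  # balance closes exactly by construction
        entrants.append(e)
        deaths.append(die)

    start = int(years[0])
    neutral = AnnualSeries(start, np.full(len(years), 20.0), units="Baht/litre")
    return ExogenousInputs(
        population_total=AnnualSeries(start, totals, units="persons"),
        entrants=AnnualSeries(start, np.asarray(entrants), units="persons/year"),
        deaths=AnnualSeries(start, np.asarray(deaths), units="persons/year"),
        mortality_35plus=m_old,
        band35_fraction=f_old,
        ssb_price=neutral,
        nonssb_sugar={},
        initial_ssb_litres={},
    )


def build_nonssb_series(
    income_group: str,
    anchors: dict[int, float] | None = None,
    seed: int | None = None,
    start_year: int = 2000,
    horizon_end: int = 2040,
    reported_end: int = 2018,
) -> AnnualSeries:
    """Non-SSB sugar consumption series (kg/person/year) for one income group.

    The reported segment (``start_year``..``reported_end``) grows at the
    constant rate implied by the two anchors; beyond the reported segment the
    series is extended with the 4-year percent-change moving average, which
    for a constant-growth history continues the same rate and therefore
    passes through the late anchor exactly.
    """
    if anchors is None:
        if income_group not in NONSSB_ANCHORS:
            raise ValueError(f"unknown income group {income_group!r}")
        anchors = NONSSB_ANCHORS[income_group]
    ys = sorted(anchors)
    if len(ys) < 2:
        raise ValueError("need anchors at two years (early and late)")
    y0, y1 = ys[0], ys[-1]
    v0, v1 = float(anchors[y0]), float(anchors[y1])
    if v0 < 0 or v1 < 0:
        raise ValueError("anchor values must be non-negative")
    if v0 == 0.0:
        vals = np.zeros(reported_end - start_year + 1)
    else:
        g = (v1 / v0) ** (1.0 / (y1 - y0)) if v1 > 0 else 1.0
        yrs = np.arange(start_year, reported_end + 1)
        vals = v0 * g ** (yrs - y0)
        if v1 == 0.0:
            vals[:] = v0
    reported = AnnualSeries(start_year, vals, units="kg/person/year")
    return extrapolate_pct_change_ma(reported, window=4, horizon_end=horizon_end)


def calibrate_initial_ssb(
    anchors: SugarAnchors,
    sugar_content: float = 0.15,
    income_mix: dict[str, float] | None = None,
    high_to_low_ratio: float = 1.5,
    at_year: int = 2010,
) -> dict[str, float]:
    """Back out initial SSB consumption (litres/person/year) per income group.

    The national anchors state the per-person SSB share of total sugar in
    2000 and 2015; converting each to litres via the average sugar content
    and interpolating linearly to ``at_year`` gives the population-average
    initial quantity, which is then split across income groups by a fixed
    high:low consumption ratio (higher-income individuals consume more SSB).
    """
    if sugar_content <= 0:
        raise ValueError("sugar content must be positive")
    if high_to_low_ratio < 1.0:
        raise ValueError("high-income SSB consumption must be >= low-income")
    mix = income_mix or {"low": 0.5, "high": 0.5}
    if not np.isclose(sum(mix.values()), 1.0, atol=1e-9):
        raise ValueError("income mix shares must sum to 1")

    def litres(total_g_day: float, share: float) -> float:
        kg_year = share * total_g_day * DAYS_PER_YEAR / 1000.0
        return kg_year / sugar_content

    l2000 = litres(anchors.total_sugar_2000, anchors.ssb_share_2000)
    l2015 = litres(anchors.total_sugar_2015, anchors.ssb_share_2015)
    w = (at_year - 2000) / 15.0
    avg = (1.0 - w) * l2000 + w * l2015
    avg = max(avg, 0.0)
    low = avg / (mix["low"] + mix["high"] * high_to_low_ratio)
    return {"low": low, "high": low * high_to_low_ratio}


def default_inputs(
    seed: int = 0,
    price_baht_per_litre: float = 20.0,
    sugar_content: float = 0.15,
    anchors: SugarAnchors | None = None,
    population_anchors: dict[int, float] | None = None,
    mortality_config: dict | None = None,
) -> ExogenousInputs:
    """Assemble the full default exogenous-input bundle for 2010-2040."""
    anchors = anchors or SugarAnchors()
    pop_anchors = population_anchors or DEFAULT_POPULATION_ANCHORS
    inputs = build_population_trajectory(pop_anchors, mortality_config=mortality_config, seed=seed)
    n = len(inputs.population_total)
    inputs.ssb_price = AnnualSeries(
        inputs.population_total.start_year,
        np.full(n, float(price_baht_per_litre)),
        units="Baht/litre",
    )
    inputs.nonssb_sugar = {
        g: build_nonssb_series(g, horizon_end=inputs.population_total.end_year)
        for g in ("low", "high")
    }
    inputs.initial_ssb_litres = calibrate_initial_ssb(
        anchors, sugar_content=sugar_content, at_year=inputs.population_total.start_year
    )
    return inputs
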