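"""Population stock state and caries-severity classification.

The caries prevalence sub-model tracks person counts in a 5-way cross
classification: WHO DMFT severity band (VL < L < M < H), treatment status
(untreated / treated), age band (15-34 / 35+), sex and income group.  The
state is a dense ``(4, 2, 2, 2, 2)`` float array with named axes; flows in
the simulator operate on it with plain numpy broadcasting.

Severity bands follow the WHO criteria for caries experience: the child
(12-year) DMFT thresholds are applied to ages 15-34 and the adult (35-44)
thresholds to ages 35+, with interval lower bounds inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "TREATMENT",
    "AGE_BANDS",
    "SEXES",
    "INCOMES",
    "classify_dmft",
    "StockState",
    "ProgressionRates",
    "CareParams",
    "DemographyParams",
    "build_initial_state",
    "REFERENCE_PROJECTIONS_M",
    "REFERENCE_CATEGORY_SHARES_2010",
]

CATEGORIES = ("VL", "L", "M", "H")
TREATMENT = ("untreated", "treated")
AGE_BANDS = ("15-34", "35+")
SEXES = ("female", "male")
INCOMES = ("low", "high")

# axis order of StockState.counts
AXES = ("category", "treatment", "age_band", "sex", "income")

# DMFT thresholds (teeth/person): lower bound of L, M, H per age band.
# Child (12 y) criteria are used for 15-34, adult (35-44 y) criteria for 35+.
_DMFT_CUTS = {
    "15-34": (1.2, 2.7, 4.5),
    "35+": (5.0, 9.0, 14.0),
}

# Reference projection of the Thai population 15+ by DMFT severity
# (millions of persons, central values), by scenario and calendar year.
# These anchor the synthetic demography and the default calibration targets.
REFERENCE_PROJECTIONS_M: dict[str, dict[int, dict[str, float]]] = {
    "base_case": {
        2010: {"VL": 19.52, "L": 9.95, "M": 8.37, "H": 12.56},
        2020: {"VL": 17.70, "L": 10.94, "M": 9.52, "H": 15.21},
        2030: {"VL": 15.52, "L": 10.73, "M": 10.09, "H": 17.76},
        2040: {"VL": 13.20, "L": 9.76, "M": 9.87, "H": 19.79},
    },
    "ssb_tax": {
        2010: {"VL": 19.52, "L": 9.95, "M": 8.37, "H": 12.56},
        2020: {"VL": 17.70, "L": 10.94, "M": 9.52, "H": 15.20},
        2030: {"VL": 15.73, "L": 10.76, "M": 10.06, "H": 17.54},
        2040: {"VL": 13.65, "L": 9.88, "M": 9.83, "H": 19.24},
    },
    "aggressive": {
        2010: {"VL": 19.52, "L": 9.95, "M": 8.37, "H": 12.56},
        2020: {"VL": 18.86, "L": 10.91, "M": 9.34, "H": 14.26},
        2030: {"VL": 20.91, "L": 11.46, "M": 9.37, "H": 12.35},
        2040: {"VL": 21.49, "L": 11.48, "M": 8.92, "H": 10.70},
    },
}

_t2010 = REFERENCE_PROJECTIONS_M["base_case"][2010]
_total2010 = sum(_t2010.values())
#: 2010 severity-category shares implied by the reference projection.
REFERENCE_CATEGORY_SHARES_2010 = {c: _t2010[c] / _total2010 for c in CATEGORIES}


def classify_dmft(dmft: float, age_band: str) -> str:
    """Map a DMFT count to its WHO severity category for an age band.

    Lower bounds are inclusive: DMFT 1.2 at ages 15-34 is Low, DMFT 5.0 at
    ages 35+ is Low, DMFT 14.0 at 35+ is High.
    """
    if dmft < 0:
        raise ValueError("DMFT cannot be negative")
    if age_band not in _DMFT_CUTS:
        raise ValueError(f"unknown age band {age_band!r}; expected one of {AGE_BANDS}")
    lo_l, lo_m, lo_h = _DMFT_CUTS[age_band]
    if dmft < lo_l:
        return "VL"
    if dmft < lo_m:
        return "L"
    if dmft < lo_h:
        return "M"
    return "H"


@dataclass
class StockState:
    """Person counts by (category, treatment, age band, sex, income).

    ``counts`` has shape ``(4, 2, 2, 2, 2)`` with axis order
    (category VL/L/M/H, untreated/treated, 15-34/35+, female/male, low/high).
    """

    year: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.shape != (4, 2, 2, 2, 2):
            raise ValueError(f"counts must have shape (4,2,2,2,2), got {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("stock counts must be non-negative")
        self.counts = arr

    # -- aggregates ---------------------------------------------------------
    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def category_totals(self) -> dict[str, float]:
        sums = self.counts.sum(axis=(1, 2, 3, 4))
        return {c: float(s) for c, s in zip(CATEGORIES, sums)}

    def band_total(self, age_band: str) -> float:
        a = AGE_BANDS.index(age_band)
        return float(self.counts[:, :, a].sum())

    def category_band_totals(self, age_band: str) -> dict[str, float]:
        a = AGE_BANDS.index(age_band)
        sums = self.counts[:, :, a].sum(axis=(1, 2, 3))
        return {c: float(s) for c, s in zip(CATEGORIES, sums)}

    def treated_split(self, category: str) -> tuple[float, float]:
        """(untreated, treated) totals within a severity category."""
        c = CATEGORIES.index(category)
        untreated = float(self.counts[c, 0].sum())
        treated = float(self.counts[c, 1].sum())
        return untreated, treated

    def copy(self) -> "StockState":
        return StockState(self.year, self.counts.copy())

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view of the state."""
        rows = []
        for ic, cat in enumerate(CATEGORIES):
            for it, tr in enumerate(TREATMENT):
                for ia, ab in enumerate(AGE_BANDS):
                    for isx, sx in enumerate(SEXES):
                        for ii, inc in enumerate(INCOMES):
                            rows.append(
                                (self.year, cat, tr, ab, sx, inc,
                                 self.counts[ic, it, ia, isx, ii])
                            )
        return pd.DataFrame(
            rows,
            columns=["year", "category", "treatment_status", "age_band",
                     "sex", "income", "persons"],
        )


@dataclass(frozen=True)
class ProgressionRates:
    """Forward severity transition hazards (1/year); no backward rates exist."""

    vl_to_l: float = 0.063
    l_to_m: float = 0.066
    m_to_h: float = 0.063

    def __post_init__(self) -> None:
        if min(self.vl_to_l, self.l_to_m, self.m_to_h) < 0:
            raise ValueError("progression rates must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.vl_to_l, self.l_to_m, self.m_to_h])


def _rvf_default() -> np.ndarray:
    # regular dental visit fraction, axes (category, sex, age_band)
    return np.array(
        [
            [[0.229, 0.148], [0.191, 0.170]],  # VL  [female, male] x [15-34, 35+]
            [[0.306, 0.357], [0.308, 0.385]],  # L
            [[0.521, 0.643], [0.462, 0.333]],  # M
            [[0.571, 0.332], [0.583, 0.215]],  # H
        ]
    )


def _t2u_default() -> np.ndarray:
    # treated -> untreated base hazard, axes (category, age_band)
    return np.array(
        [
            [0.40, 0.70],  # VL
            [0.78, 0.58],  # L
            [0.78, 0.34],  # M
            [0.70, 0.75],  # H
        ]
    )


@dataclass(frozen=True)
class CareParams:
    """Relapse-side care parameters.

    ``regular_visit_fraction`` (category x sex x age band) is the fraction
    making a dental visit within the past year; regular visitors are assumed
    not to relapse, so the treated->untreated hazard is
    ``treated_to_untreated * (1 - regular_visit_fraction)``.
    """

    regular_visit_fraction: np.ndarray = field(default_factory=_rvf_default)
    treated_to_untreated: np.ndarray = field(default_factory=_t2u_default)

    def __post_init__(self) -> None:
        rvf = np.asarray(self.regular_visit_fraction, dtype=float)
        t2u = np.asarray(self.treated_to_untreated, dtype=float)
        if rvf.shape != (4, 2, 2) or t2u.shape != (4, 2):
            raise ValueError("regular_visit_fraction must be (4,2,2); "
                             "treated_to_untreated must be (4,2)")
        if np.any(rvf < 0) or np.any(rvf > 1) or np.any(t2u < 0):
            raise ValueError("care parameters out of admissible range")
        object.__setattr__(self, "regular_visit_fraction", rvf)
        object.__setattr__(self, "treated_to_untreated", t2u)


def _entrant_default() -> np.ndarray:
    return np.array([REFERENCE_CATEGORY_SHARES_2010[c] for c in CATEGORIES])


@dataclass(frozen=True)
class DemographyParams:
    """Entry, aging and death parameters for the stock model.

    entrant_distribution
        Share of 15-year-old entrants arriving in each severity category;
        defaults to the 2010 category shares of the reference projection.
    aging_rate
        Constant hazard from the 15-34 band to 35+; 1/20 per year is the
        uniform-residence approximation of the 20-year band.
    mortality_35plus
        Death hazard applied to the 35+ band (deaths act only there by
        default; the young-band hazard is configurable).
    """

    entrant_distribution: np.ndarray = field(default_factory=_entrant_default)
    aging_rate: float = 1.0 / 20.0
    mortality_35plus: float = 0.015
    mortality_15_34: float = 0.0
    entrant_treated_fraction: float = 0.0

    def __post_init__(self) -> None:
        dist = np.asarray(self.entrant_distribution, dtype=float)
        if dist.shape != (4,) or np.any(dist < 0):
            raise ValueError("entrant_distribution must be 4 non-negative shares")
        if not np.isclose(dist.sum(), 1.0, atol=1e-9):
            raise ValueError("entrant_distribution must sum to 1")
        if self.aging_rate < 0 or self.mortality_35plus < 0 or self.mortality_15_34 < 0:
            raise ValueError("demographic rates must be non-negative")
        if not 0 <= self.entrant_treated_fraction <= 1:
            raise ValueError("entrant_treated_fraction must lie in [0,1]")
        object.__setattr__(self, "entrant_distribution", dist)


def build_initial_state(
    total: float = _total2010 * 1e6,
    category_shares: dict[str, float] | None = None,
    treated_fraction: float | dict[str, float] = 0.09,
    band35_fraction: float = 0.6,
    year: float = 2010.0,
) -> StockState:
    """Distribute an initial population across the full stratification.

    Category shares default to the 2010 reference projection; within each
    category the population is split 9% treated / 91% untreated (the level
    that keeps the untreated fraction near its observed ~91%), 60% into the
    35+ band, and equally by sex and income (the surveys report no joint
    distribution, so the splits are configurable).
    """
    if total <= 0:
        raise ValueError("total population must be positive")
    shares = category_shares or REFERENCE_CATEGORY_SHARES_2010
    if not np.isclose(sum(shares.values()), 1.0, atol=1e-6):
        raise ValueError("category shares must sum to 1")
    if isinstance(treated_fraction, (int, float)):
        tf = {c: float(treated_fraction) for c in CATEGORIES}
    else:
        tf = {c: float(treated_fraction[c]) for c in CATEGORIES}
    counts = np.zeros((4, 2, 2, 2, 2))
    band = np.array([1.0 - band35_fraction, band35_fraction])
    for ic, cat in enumerate(CATEGORIES):
        cat_pop = total * shares[cat]
        for it, frac_t in enumerate((1.0 - tf[cat], tf[cat])):
            counts[ic, it] = cat_pop * frac_t * band[:, None, None] * 0.25
    return StockState(year=year, counts=counts)
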