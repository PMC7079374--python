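"""Dental-service utilization sub-model: uptake rates with goal-gap adjustment.

The uptake rate of dental treatment is a stock per severity category (and
income group, because affordability differs by income): it adjusts toward an
*indicated* uptake — the initial survey rate scaled by access and
affordability multipliers and any scenario boost — over a fixed adjustment
time, the classic first-order goal-gap structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .policy import Scenario

__all__ = [
    "UptakeParams",
    "UptakeState",
    "indicated_uptake",
    "update_uptake",
    "apply_uptake_boost",
]

#: initial treatment uptake rate per severity category (survey-based)
INITIAL_UPTAKE = {"VL": 0.384, "L": 0.066, "M": 0.041, "H": 0.075}
_CATS = ("VL", "L", "M", "H")


@dataclass(frozen=True)
class UptakeParams:
    """Access, affordability and adjustment-time settings.

    The access multiplier proxies the population-per-dental-personnel ratio
    (a policy lever; constant 1.0 by default).  Affordability differs by
    income: low-income individuals face out-of-pocket barriers (0.9) while
    high-income individuals do not (1.0).
    """

    base_uptake: dict = field(default_factory=lambda: dict(INITIAL_UPTAKE))
    time_to_adjust: float = 1.0  # years
    access_multiplier: float = 1.0
    affordability_multiplier: dict = field(
        default_factory=lambda: {"low": 0.9, "high": 1.0}
    )

    def __post_init__(self) -> None:
        if self.time_to_adjust <= 0:
            raise ValueError("time_to_adjust must be positive")
        if self.access_multiplier <= 0:
            raise ValueError("access multiplier must be positive")
        for g, m in self.affordability_multiplier.items():
            if m <= 0:
                raise ValueError(f"affordability multiplier for {g!r} must be positive")
        for c, u in self.base_uptake.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"base uptake for {c!r} must lie in [0,1]")


@dataclass
class UptakeState:
    """Current uptake rates, shape (category, income) = (4, 2)."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.rates, dtype=float)
        if arr.shape != (4, 2):
            raise ValueError("uptake rates must have shape (4, 2)")
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("uptake rates must lie in [0,1]")
        self.rates = arr

    @classmethod
    def initial(cls, params: UptakeParams) -> "UptakeState":
        base = np.array([params.base_uptake[c] for c in _CATS])
        return cls(np.repeat(base[:, None], 2, axis=1))

    def aggregate(self, weights: np.ndarray | None = None) -> float:
        """Population-weighted (or simple) mean uptake, for reporting only."""
        if weights is None:
            return float(self.rates.mean())
        w = np.asarray(weights, dtype=float)
        return float((self.rates * w).sum() / w.sum())


def indicated_uptake(
    base_uptake: float, access_multiplier: float, affordability_multiplier: float
) -> float:
    """Target uptake implied by access and affordability, clamped to [0,1]."""
    if not 0.0 <= base_uptake <= 1.0:
        raise ValueError("base uptake must lie in [0,1]")
    if access_multiplier <= 0 or affordability_multiplier <= 0:
        raise ValueError("multipliers must be positive")
    return min(1.0, base_uptake * access_multiplier * affordability_multiplier)


def update_uptake(current: float, indicated: float, time_to_adjust: float, dt: float) -> float:
    """One goal-gap step: ``current + dt * (indicated - current) / tta``."""
    if not (0.0 <= current <= 1.0 and 0.0 <= indicated <= 1.0):
        raise ValueError("uptake rates must lie in [0,1]")
    if dt > time_to_adjust:
        raise ValueError("integration step dt must not exceed time_to_adjust")
    return current + dt * (indicated - current) / time_to_adjust


def apply_uptake_boost(indicated: float, scenario: Scenario, year: float) -> float:
    """Scale the indicated uptake by the scenario boost from its start year."""
    if year >= scenario.start_year and scenario.uptake_boost != 1.0:
        return min(1.0, indicated * scenario.uptake_boost)
    return min(1.0, indicated)


def step_uptake_state(
    state: UptakeState,
    params: UptakeParams,
    scenario: Scenario,
    year: float,
    dt: float,
) -> UptakeState:
    """Advance all (category, income) uptake stocks by one step."""
    new = np.empty_like(state.rates)
    for ic, cat in enumerate(_CATS):
        for ii, grp in enumerate(("low", "high")):
            ind = indicated_uptake(
                params.base_uptake[cat],
                params.access_multiplier,
                params.affordability_multiplier[grp],
            )
            ind = apply_uptake_boost(ind, scenario, year)
            new[ic, ii] = update_uptake(
                state.rates[ic, ii], ind, params.time_to_adjust, dt
            )
    return UptakeState(new)
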