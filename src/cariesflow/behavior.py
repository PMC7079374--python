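"""Oral-health behavior sub-model: awareness, self-care and sugar intake.

Three mechanisms live here:

* goal-gap stocks for oral-health awareness and self-care practice (the
  fraction brushing at least twice daily with fluoride toothpaste), each
  drawn toward a maximum by promotion and eroded by a loss rate;
* the SSB demand response to price by income group, via constant own-price
  elasticities applied to the cumulative price change against the pre-tax
  reference (recomputed each year rather than compounded per step, so the
  response carries no integration-step path dependence);
* sugar-intake accounting: SSB sugar = litres x average content, total sugar
  relative to its initial level, and a power-law multiplier with exponent
  equal to the "elasticity of sugar consumption" that scales the caries
  progression hazards (relative sugar of 1 leaves progression untouched).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BehaviorParams",
    "BehaviorState",
    "update_ssb_demand",
    "sugar_from_ssb",
    "relative_sugar",
    "sugar_progression_multiplier",
    "update_goal_gap_stock",
    "behavior_progression_modifier",
]

INCOME_GROUPS = ("low", "high")


@dataclass(frozen=True)
class BehaviorParams:
    """Behavioral parameters of the oral-health sub-model.

    demand_elasticity
        Own-price elasticity of SSB demand per income group; the tax bites
        harder in the low-income group (-1.46 vs -0.39).
    sugar_elasticity
        Exponent linking relative sugar consumption to caries progression.
    awareness / self-care goal-gap settings
        With the default zero promotion and loss rates both stocks hold
        their initial levels, leaving the progression modifier at exactly 1
        (the behavior channel is a policy lever, not part of the base case).
    modifier_cap, modifier_weights
        Maximum proportional reduction of progression attributable to
        behavior, and the split between the self-care and awareness terms.
    """

    demand_elasticity: dict = field(
        default_factory=lambda: {"low": -1.46, "high": -0.39}
    )
    sugar_elasticity: float = 0.6
    initial_awareness: float = 0.5
    max_awareness: float = 0.8
    awareness_promotion_rate: float = 0.0
    awareness_loss_rate: float = 0.0
    initial_self_care: float = 0.529
    max_self_care: float = 0.8
    self_care_promotion_rate: float = 0.0
    self_care_loss_rate: float = 0.0
    modifier_cap: float = 0.2
    modifier_weights: tuple = (0.75, 0.25)  # (self-care, awareness)

    def __post_init__(self) -> None:
        for g, e in self.demand_elasticity.items():
            if e > 0:
                raise ValueError(f"demand elasticity for {g!r} must be <= 0")
        if self.sugar_elasticity < 0:
            raise ValueError("sugar elasticity must be >= 0")
        for name in ("initial_awareness", "max_awareness",
                     "initial_self_care", "max_self_care"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if not 0.0 <= self.modifier_cap <= 1.0:
            raise ValueError("modifier_cap must lie in [0,1]")
        if min(self.modifier_weights) < 0 or not np.isclose(sum(self.modifier_weights), 1.0):
            raise ValueError("modifier weights must be non-negative and sum to 1")


@dataclass
class BehaviorState:
    """Time-varying behavioral quantities carried through the simulation."""

    awareness: float
    self_care: float
    ssb_litres: dict      # litres/person/year per income group
    ssb_sugar_content: float  # kg/litre
    nonssb_sugar: dict    # kg/person/year per income group
    initial_total_sugar: dict  # kg/person/year per income group

    def total_sugar(self, group: str) -> float:
        return sugar_from_ssb(self.ssb_litres[group], self.ssb_sugar_content) \
            + self.nonssb_sugar[group]


def update_ssb_demand(prev_litres: float, pct_price_change: float, elasticity: float) -> float:
    """Constant-elasticity demand response, floored at zero.

    ``new = prev * (1 + elasticity * pct_price_change)``.
    """
    if prev_litres < 0:
        raise ValueError("SSB quantity cannot be negative")
    return max(0.0, prev_litres * (1.0 + elasticity * pct_price_change))


def sugar_from_ssb(ssb_litres: float, content_kg_per_litre: float) -> float:
    """Sugar from SSB (kg/person/year): quantity times average content."""
    if ssb_litres < 0 or content_kg_per_litre < 0:
        raise ValueError("SSB quantity and sugar content must be non-negative")
    return ssb_litres * content_kg_per_litre


def relative_sugar(current_total: float, initial_total: float) -> float:
    """Current total sugar consumption relative to its initial level."""
    if initial_total <= 0:
        raise ValueError("initial total sugar must be positive")
    if current_total < 0:
        raise ValueError("current total sugar cannot be negative")
    return current_total / initial_total


def sugar_progression_multiplier(rel_sugar: float, sugar_elasticity: float) -> float:
    """Power-law multiplier on severity progression: ``rel_sugar ** elasticity``.

    Equals 1 when consumption is at its initial level; strictly increasing
    in relative sugar for positive elasticity.
    """
    if rel_sugar <= 0:
        raise ValueError("relative sugar must be positive")
    return float(rel_sugar ** sugar_elasticity)


def update_goal_gap_stock(
    current: float, maximum: float, inflow_rate: float, loss_rate: float, dt: float
) -> float:
    """One Euler step of a first-order goal-gap stock on [0,1].

    ``new = current + dt * (inflow_rate * (maximum - current)
    - loss_rate * current)``, clamped to [0,1].  With constant rates the
    stock approaches the loss-adjusted equilibrium
    ``inflow * maximum / (inflow + loss)`` along a discrete exponential.
    """
    if not (0.0 <= current <= 1.0 and 0.0 <= maximum <= 1.0):
        raise ValueError("goal-gap stock and maximum must lie in [0,1]")
    if inflow_rate < 0 or loss_rate < 0 or dt <= 0:
        raise ValueError("rates must be non-negative and dt positive")
    new = current + dt * (inflow_rate * (maximum - current) - loss_rate * current)
    return float(min(1.0, max(0.0, new)))


def behavior_progression_modifier(
    awareness: float, self_care: float, params: BehaviorParams
) -> float:
    """Multiplier on caries progression from behavioral improvement.

    Linear in the normalized gains of self-care and awareness above their
    initial (base-year) levels, with a total cap on the achievable
    reduction; anchored so the base-year levels give exactly 1, and clamped
    to ``[1 - cap, 1]`` (behavioral decline cannot accelerate progression
    beyond the calibrated base rates).
    """
    if not (0.0 <= awareness <= 1.0 and 0.0 <= self_care <= 1.0):
        raise ValueError("awareness and self-care must lie in [0,1]")
    w_sc, w_aw = params.modifier_weights

    def gain(value: float, initial: float, maximum: float) -> float:
        span = maximum - initial
        if span <= 0:
            return 0.0
        return max(0.0, value - initial) / span

    reduction = params.modifier_cap * (
        w_sc * gain(self_care, params.initial_self_care, params.max_self_care)
        + w_aw * gain(awareness, params.initial_awareness, params.max_awareness)
    )
    return float(min(1.0, max(1.0 - params.modifier_cap, 1.0 - reduction)))
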