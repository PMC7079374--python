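"""The caries stock-and-flow model and its simulation results.

:class:`CariesModel` couples three sub-models in the style of a fitted
statistical model object:

* severity progression (SM1): unidirectional flows VL->L->M->H, modulated by
  the sugar and behavior multipliers, with bidirectional treated/untreated
  flows, entrants, aging and deaths;
* service utilization (SM2): goal-gap uptake stocks per severity category
  and income group;
* behavior (SM3): price-driven SSB demand, sugar accounting and goal-gap
  awareness / self-care stocks.

Integration is explicit Euler with all flows evaluated simultaneously from
the start-of-step state (standard system-dynamics semantics); outflows from
a cell are capped at the cell's stock by proportional scaling, which keeps
every stock non-negative and preserves the population balance exactly.

``CariesModel.simulate`` returns a :class:`SimulationResults`;
``CariesModel.fit`` (in :mod:`cariesflow.calibration`) recovers the
progression rates from trajectory targets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import services as svc
from .policy import (DEFAULT_TAX_SCHEDULE, PriceResponse, Scenario,
                     TaxSchedule, make_scenario, reformulated_content,
                     relative_price_change)
from .state import (AGE_BANDS, CATEGORIES, CareParams, DemographyParams,
                    ProgressionRates, StockState, build_initial_state)
from .synthetic import ExogenousInputs, default_inputs

__all__ = ["CariesModel", "SimulationResults", "YearContext"]

_INCOMES = ("low", "high")


@dataclass
class YearContext:
    """Exogenous and behavioral signals resolved for one calendar year."""

    year: int
    price_change: float
    sugar_content: float            # kg/litre, after reformulation
    ssb_litres: dict                # per income group
    nonssb_sugar: dict              # per income group, after any reduction
    relative_sugar: dict            # per income group
    sugar_multiplier: np.ndarray    # shape (2,), per income group
    awareness: float
    self_care: float
    behavior_multiplier: float
    entrants_rate: float            # persons/year
    deaths_rate: float | None       # persons/year prescribed by the demography
    uptake: np.ndarray              # shape (4, 2): category x income


@dataclass
class CariesModel:
    """System-dynamics model of dental caries under SSB taxation.

    Parameters are grouped into the sub-model parameter objects; all have
    defaults reproducing the published parameterization.  Construct, then
    call :meth:`simulate` for a scenario trajectory or :meth:`fit` to
    calibrate the progression rates against targets.
    """

    inputs: ExogenousInputs = None  # type: ignore[assignment]
    rates: ProgressionRates = field(default_factory=ProgressionRates)
    care: CareParams = field(default_factory=CareParams)
    demography: DemographyParams = field(default_factory=DemographyParams)
    behavior: bhv.BehaviorParams = field(default_factory=bhv.BehaviorParams)
    uptake: svc.UptakeParams = field(default_factory=svc.UptakeParams)
    price_response: PriceResponse = field(default_factory=PriceResponse)
    tax_schedule: TaxSchedule = field(default_factory=lambda: DEFAULT_TAX_SCHEDULE)
    base_sugar_content: float = 0.15  # kg/litre before reformulation
    initial_state: StockState = None  # type: ignore[assignment]
    start: int = 2010
    end: int = 2040
    dt: float = 0.25

    def __post_init__(self) -> None:
        if self.inputs is None:
            self.inputs = default_inputs()
        if self.initial_state is None:
            self.initial_state = build_initial_state(
                total=self.inputs.population_total[self.start], year=self.start
            )
        steps = 1.0 / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("dt must divide one year evenly (e.g. 1, 0.5, 0.25)")
        if self.end <= self.start:
            raise ValueError("simulation end must follow start")

    # ------------------------------------------------------------------
    @classmethod
    def default(cls, **kwargs) -> "CariesModel":
        return cls(**kwargs)

    def with_params(self, **overrides) -> "CariesModel":
        """Copy of the model with named scalar parameters replaced.

        Recognized names: vl_to_l, l_to_m, m_to_h, demand_elasticity_low,
        demand_elasticity_high, sugar_content, sugar_elasticity,
        percent_reduce_ssb_sugar, plus any top-level field of the model.
        """
        m = dataclasses.replace(self)
        rate_kw = {k: v for k, v in overrides.items()
                   if k in ("vl_to_l", "l_to_m", "m_to_h")}
        if rate_kw:
            m.rates = replace(m.rates, **rate_kw)
        el = dict(m.behavior.demand_elasticity)
        bp_kw = {}
        if "demand_elasticity_low" in overrides:
            el["low"] = overrides["demand_elasticity_low"]
        if "demand_elasticity_high" in overrides:
            el["high"] = overrides["demand_elasticity_high"]
        if el != m.behavior.demand_elasticity:
            bp_kw["demand_elasticity"] = el
        if "sugar_elasticity" in overrides:
            bp_kw["sugar_elasticity"] = overrides["sugar_elasticity"]
        if bp_kw:
            m.behavior = replace(m.behavior, **bp_kw)
        if "percent_reduce_ssb_sugar" in overrides:
            m.price_response = replace(
                m.price_response,
                percent_reduce_ssb_sugar=overrides["percent_reduce_ssb_sugar"],
            )
        if "sugar_content" in overrides:
            m.base_sugar_content = float(overrides["sugar_content"])
        known = {"vl_to_l", "l_to_m", "m_to_h", "demand_elasticity_low",
                 "demand_elasticity_high", "sugar_content", "sugar_elasticity",
                 "percent_reduce_ssb_sugar"}
        for k, v in overrides.items():
            if k in known:
                continue
            if not hasattr(m, k):
                raise KeyError(f"unknown parameter {k!r}")
            setattr(m, k, v)
        return m

    # ------------------------------------------------------------------
    def _initial_total_sugar(self) -> dict:
        out = {}
        for g in _INCOMES:
            ssb = self.inputs.initial_ssb_litres.get(g, 0.0) * self.base_sugar_content
            non = self.inputs.nonssb_sugar[g][self.start] if self.inputs.nonssb_sugar else 0.0
            out[g] = ssb + non
        return out

    def year_context(
        self,
        year: int,
        scenario: Scenario,
        awareness: float,
        self_care: float,
        uptake_rates: np.ndarray,
        initial_total_sugar: dict,
    ) -> YearContext:
        """Resolve all per-year signals entering the stock flows."""
        if scenario.tax_on and year >= scenario.start_year:
            content = reformulated_content(
                self.base_sugar_content, self.price_response, year, self.tax_schedule
            )
            ref = self.inputs.ssb_price[year] if self.inputs.ssb_price else \
                self.price_response.reference_price
            resp = replace(self.price_response, reference_price=ref)
            tax = self.tax_schedule.tax_rate(content * 100.0, year)
            pc = relative_price_change(tax, resp)
        else:
            content = self.base_sugar_content
            pc = 0.0

        litres, nonssb, rel = {}, {}, {}
        mult = np.ones(2)
        for ii, g in enumerate(_INCOMES):
            litres[g] = bhv.update_ssb_demand(
                self.inputs.initial_ssb_litres.get(g, 0.0),
                pc,
                self.behavior.demand_elasticity[g],
            )
            base_non = self.inputs.nonssb_sugar[g][year] if self.inputs.nonssb_sugar else 0.0
            if year >= scenario.start_year:
                base_non *= 1.0 - scenario.nonssb_reduction
            nonssb[g] = base_non
            total = bhv.sugar_from_ssb(litres[g], content) + nonssb[g]
            init = initial_total_sugar[g]
            rel[g] = bhv.relative_sugar(total, init) if init > 0 else 1.0
            mult[ii] = bhv.sugar_progression_multiplier(
                max(rel[g], 1e-12), self.behavior.sugar_elasticity
            )
        b_mult = bhv.behavior_progression_modifier(awareness, self_care, self.behavior)
        return YearContext(
            year=year,
            price_change=pc,
            sugar_content=content,
            ssb_litres=litres,
            nonssb_sugar=nonssb,
            relative_sugar=rel,
            sugar_multiplier=mult,
            awareness=awareness,
            self_care=self_care,
            behavior_multiplier=b_mult,
            # the annual series book entrants/deaths as the flow *into* a
            # year; the flow over [year, year+1) is therefore indexed year+1
            entrants_rate=self.inputs.entrants[year + 1],
            deaths_rate=(self.inputs.deaths[year + 1] if len(self.inputs.deaths) > 1 else None),
            uptake=uptake_rates,
        )

    # ------------------------------------------------------------------
    def step(self, state: StockState, ctx: YearContext, dt: float | None = None
             ) -> tuple[StockState, float, float]:
        """One Euler step; returns (new_state, entrants_added, deaths_removed).

        All flows are computed simultaneously from the start-of-step state;
        per-cell outflows are proportionally capped at the available stock.
        """
        dt = self.dt if dt is None else dt
        S = state.counts
        r = self.rates.as_array()
        demo = self.demography

        # hazards per cell, 1/year -------------------------------------
        prog_h = np.zeros((4, 2, 2, 2, 2))
        smult = ctx.sugar_multiplier  # (income,)
        for c in range(3):
            prog_h[c] = r[c] * ctx.behavior_multiplier * smult[None, None, None, :]
        treat_h = np.zeros_like(S)
        # untreated -> treated: uptake (category, income)
        treat_h[:, 0] = ctx.uptake[:, None, None, :]
        # treated -> untreated: base * (1 - regular visit fraction)
        rvf = self.care.regular_visit_fraction.transpose(0, 2, 1)  # (cat, age, sex)
        relapse = self.care.treated_to_untreated[:, :, None] * (1.0 - rvf)
        treat_h[:, 1] = relapse[:, :, :, None]
        aging_h = np.zeros_like(S)
        aging_h[:, :, 0] = demo.aging_rate
        death_h = np.zeros_like(S)
        if ctx.deaths_rate is not None:
            # deaths prescribed by the synthetic demography: allocate the
            # annual count proportionally across the 35+ stocks so the
            # simulated total tracks the synthetic trajectory exactly
            old_total = S[:, :, 1].sum()
            if old_total > 0:
                death_h[:, :, 1] = ctx.deaths_rate / old_total
        else:
            death_h[:, :, 0] = demo.mortality_15_34
            death_h[:, :, 1] = demo.mortality_35plus

        out_h = prog_h + treat_h + aging_h + death_h
        scale = np.ones_like(S)
        over = out_h * dt > 1.0
        if np.any(over):
            scale[over] = 1.0 / (out_h[over] * dt)

        prog_f = prog_h * S * dt * scale
        treat_f = treat_h * S * dt * scale
        aging_f = aging_h * S * dt * scale
        death_f = death_h * S * dt * scale

        new = S - (prog_f + treat_f + aging_f + death_f)
        # progression inflows (severity shifts by one, keeps other indices)
        new[1:] += prog_f[:3]
        # treatment status swaps within category
        new[:, 1] += treat_f[:, 0]
        new[:, 0] += treat_f[:, 1]
        # aging into the 35+ band
        new[:, :, 1] += aging_f[:, :, 0]
        # entrants into the 15-34 band
        entrants = ctx.entrants_rate * dt
        tf = demo.entrant_treated_fraction
        ent_cell = entrants * demo.entrant_distribution[:, None] * \
            np.array([1.0 - tf, tf])[None, :] * 0.25
        new[:, :, 0] += ent_cell[:, :, None, None]

        deaths = float(death_f.sum())
        new = np.maximum(new, 0.0)
        return StockState(state.year + dt, new), entrants, deaths

    # ------------------------------------------------------------------
    def simulate(
        self,
        scenario: str | Scenario = "base_case",
        start: int | None = None,
        end: int | None = None,
        dt: float | None = None,
    ) -> "SimulationResults":
        """Run the model for a scenario and return annual trajectories."""
        if isinstance(scenario, str):
            scenario = make_scenario(scenario)
        start = self.start if start is None else start
        end = self.end if end is None else end
        dt = self.dt if dt is None else dt
        if end <= start:
            raise ValueError("simulation horizon is empty")
        if scenario.tax_on and not (start <= scenario.start_year <= end):
            raise ValueError("horizon must cover the policy start year")
        steps_per_year = round(1.0 / dt)
        if abs(1.0 / dt - steps_per_year) > 1e-9:
            raise ValueError("dt must divide one year evenly")

        state = self.initial_state.copy()
        state.year = float(start)
        init_sugar = self._initial_total_sugar()
        aware = self.behavior.initial_awareness
        care = self.behavior.initial_self_care
        up = svc.UptakeState.initial(self.uptake)

        states = [state.copy()]
        contexts = []
        max_resid = 0.0
        bp = self.behavior
        for year in range(start, end):
            ctx = self.year_context(year, scenario, aware, care, up.rates, init_sugar)
            contexts.append(ctx)
            for _ in range(steps_per_year):
                prev_total = state.total
                state, ent, dth = self.step(state, ctx, dt)
                resid = abs(state.total - prev_total - (ent - dth))
                max_resid = max(max_resid, resid / max(prev_total, 1.0))
                # goal-gap stocks advance within the year at the same dt
                aware = bhv.update_goal_gap_stock(
                    aware, bp.max_awareness, bp.awareness_promotion_rate,
                    bp.awareness_loss_rate, dt)
                care = bhv.update_goal_gap_stock(
                    care, bp.max_self_care, bp.self_care_promotion_rate,
                    bp.self_care_loss_rate, dt)
                up = svc.step_uptake_state(up, self.uptake, scenario, year, dt)
            states.append(state.copy())
        # context for the final year (reporting)
        contexts.append(
            self.year_context(end, scenario, aware, care, up.rates, init_sugar)
        )
        return SimulationResults(
            model=self,
            scenario=scenario,
            years=np.arange(start, end + 1),
            states=states,
            contexts=contexts,
            dt=dt,
            max_conservation_residual=max_resid,
        )

    def fit(self, targets=None, **kwargs):
        """Calibrate progression rates; see :func:`cariesflow.calibration.calibrate`."""
        from .calibration import calibrate

        return calibrate(self, targets=targets, **kwargs)


@dataclass
class SimulationResults:
    """Annual trajectories, behavioral series and diagnostics of one run."""

    model: CariesModel
    scenario: Scenario
    years: np.ndarray
    states: list
    contexts: list
    dt: float
    max_conservation_residual: float

    # -- accessors -----------------------------------------------------
    def state_at(self, year: int) -> StockState:
        idx = int(year) - int(self.years[0])
        if not 0 <= idx < len(self.states):
            raise KeyError(f"year {year} outside simulated horizon")
        return self.states[idx]

    def prevalence(self, year: int | None = None):
        """Caries prevalence: share of the population in bands L, M or H."""
        from .reporting import prevalence

        if year is not None:
            return prevalence(self.state_at(year))
        return pd.Series(
            [prevalence(s) for s in self.states], index=self.years, name="prevalence"
        )

    def category_populations(self) -> pd.DataFrame:
        rows = {c: [] for c in CATEGORIES}
        for s in self.states:
            tot = s.category_totals()
            for c in CATEGORIES:
                rows[c].append(tot[c])
        return pd.DataFrame(rows, index=self.years)

    def untreated_fraction(self, category: str, year: int) -> float:
        from .reporting import untreated_fraction

        return untreated_fraction(self.state_at(year), category)

    def total_sugar(self, year: int) -> float:
        """Population-average total sugar consumption (kg/person/year)."""
        ctx = self.contexts[int(year) - int(self.years[0])]
        return 0.5 * sum(
            bhv.sugar_from_ssb(ctx.ssb_litres[g], ctx.sugar_content) + ctx.nonssb_sugar[g]
            for g in _INCOMES
        )

    def behavior_frame(self) -> pd.DataFrame:
        rows = []
        for ctx in self.contexts:
            rows.append(
                dict(
                    year=ctx.year,
                    price_change=ctx.price_change,
                    sugar_content=ctx.sugar_content,
                    ssb_litres_low=ctx.ssb_litres["low"],
                    ssb_litres_high=ctx.ssb_litres["high"],
                    nonssb_low=ctx.nonssb_sugar["low"],
                    nonssb_high=ctx.nonssb_sugar["high"],
                    relative_sugar_low=ctx.relative_sugar["low"],
                    relative_sugar_high=ctx.relative_sugar["high"],
                    awareness=ctx.awareness,
                    self_care=ctx.self_care,
                    behavior_multiplier=ctx.behavior_multiplier,
                )
            )
        return pd.DataFrame(rows)

    def uptake_frame(self) -> pd.DataFrame:
        rows = []
        for ctx in self.contexts:
            for ic, cat in enumerate(CATEGORIES):
                for ii, grp in enumerate(_INCOMES):
                    rows.append(dict(year=ctx.year, category=cat, income=grp,
                                     uptake=ctx.uptake[ic, ii]))
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format stock trajectory (annual)."""
        frames = [s.to_frame() for s in self.states]
        df = pd.concat(frames, ignore_index=True)
        df.insert(0, "scenario", self.scenario.name)
        return df

    # -- presentation ----------------------------------------------------
    def summary(self) -> str:
        from .reporting import percent_change

        first, last = self.states[0], self.states[-1]
        y0, y1 = int(self.years[0]), int(self.years[-1])
        lines = [
            f"Caries simulation: scenario={self.scenario.name}, "
            f"{y0}-{y1}, dt={self.dt} y",
            f"{'':14s}{y0:>12d}{y1:>12d}{'% change':>12s}",
        ]
        t0, t1 = first.category_totals(), last.category_totals()
        for c in CATEGORIES:
            chg = percent_change(t1[c], t0[c])
            lines.append(f"{c + ' (millions)':14s}{t0[c] / 1e6:12.2f}"
                         f"{t1[c] / 1e6:12.2f}{chg:12.0f}")
        p0, p1 = self.prevalence(y0), self.prevalence(y1)
        lines.append(f"{'prevalence':14s}{p0 * 100:11.1f}%{p1 * 100:11.1f}%"
                     f"{percent_change(p1, p0):12.1f}")
        lines.append(
            f"max conservation residual: {self.max_conservation_residual:.2e}"
        )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Category populations over time (millions)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.category_populations() / 1e6
        for c in CATEGORIES:
            ax.plot(self.years, df[c], label=c)
        ax.set_xlabel("year")
        ax.set_ylabel("population (millions)")
        ax.set_title(f"DMFT severity trajectories — {self.scenario.name}")
        ax.legend()
        return ax
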