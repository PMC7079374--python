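"""Calibration of free model parameters by trajectory matching.

The severity progression rates are not observable directly; they are
recovered by adjusting them until the simulated category populations match
reference targets (by default the reference projection at 2010/2020/2030/
2040).  The loss is a weighted sum of squared *relative* errors so targets
on different scales (counts in millions, fractions) can be mixed; the
search is a derivative-free multi-start Nelder-Mead over a bounded box,
with Latin-hypercube starting points so the result is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .state import CATEGORIES, REFERENCE_PROJECTIONS_M

__all__ = [
    "CalibrationTarget",
    "CalibrationResults",
    "default_targets",
    "objective",
    "calibrate",
]

_FREE_PARAMS = ("vl_to_l", "l_to_m", "m_to_h")
_DEFAULT_BOUNDS = {"vl_to_l": (0.001, 0.2), "l_to_m": (0.001, 0.2), "m_to_h": (0.001, 0.2)}


@dataclass(frozen=True)
class CalibrationTarget:
    """One matching target for the calibration loss.

    quantity is one of ``category_counts`` (value = persons in ``scope``,
    a severity category), ``prevalence`` (fraction in L/M/H) or
    ``mean_dmft`` (scope = age band, requires representative values).
    """

    year: int
    quantity: str
    scope: str
    value: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("target weights must be non-negative")
        if self.quantity not in ("category_counts", "prevalence", "mean_dmft"):
            raise ValueError(f"unknown target quantity {self.quantity!r}")
        if self.value == 0:
            raise ValueError("relative-error targets require a nonzero value")


def default_targets(scenario: str = "base_case") -> list[CalibrationTarget]:
    """Category-count targets from the reference projection (persons)."""
    table = REFERENCE_PROJECTIONS_M[scenario]
    return [
        CalibrationTarget(year=y, quantity="category_counts", scope=c,
                          value=table[y][c] * 1e6)
        for y in sorted(table)
        for c in CATEGORIES
    ]


def targets_from_results(results, years: list[int]) -> list[CalibrationTarget]:
    """Build self-consistent targets from an existing simulation run."""
    out = []
    for y in years:
        tot = results.state_at(y).category_totals()
        out.extend(
            CalibrationTarget(year=y, quantity="category_counts", scope=c, value=tot[c])
            for c in CATEGORIES
        )
    return out


def load_targets(path: str | Path) -> list[CalibrationTarget]:
    """Read targets from CSV with columns (year, quantity, scope, value, weight)."""
    df = pd.read_csv(path)
    return [
        CalibrationTarget(int(r.year), str(r.quantity), str(r.scope),
                          float(r.value), float(getattr(r, "weight", 1.0)))
        for r in df.itertuples()
    ]


def _measure(results, target: CalibrationTarget) -> float:
    state = results.state_at(target.year)
    if target.quantity == "category_counts":
        return state.category_totals()[target.scope]
    if target.quantity == "prevalence":
        from .reporting import prevalence

        return prevalence(state)
    from .reporting import RepresentativeDmft, mean_dmft

    return mean_dmft(state, RepresentativeDmft.calibrated(results.states[0]), target.scope)


def objective(params: dict, targets: list[CalibrationTarget], model, scenario: str = "base_case") -> float:
    """Weighted sum of squared relative errors between run and targets."""
    if not targets:
        raise ValueError("at least one calibration target is required")
    try:
        results = model.with_params(**params).simulate(scenario)
    except Exception as exc:  # propagate with parameter context
        raise RuntimeError(f"simulation failed at params {params}: {exc}") from exc
    total = 0.0
    for t in targets:
        sim = _measure(results, t)
        total += t.weight * ((sim - t.value) / t.value) ** 2
    return total


@dataclass
class CalibrationResults:
    """Fitted parameters and diagnostics from :func:`calibrate`."""

    params: dict
    objective: float
    converged: bool
    n_evals: int
    n_starts: int
    start_objectives: list = field(default_factory=list)
    model: object = None

    def fitted_model(self):
        return self.model.with_params(**self.params)

    def summary(self) -> str:
        lines = [
            "Calibration by trajectory matching (multi-start Nelder-Mead)",
            f"  converged: {self.converged}   evaluations: {self.n_evals}"
            f"   starts: {self.n_starts}",
            f"  objective (weighted sum of squared relative errors): "
            f"{self.objective:.3e}",
        ]
        for k, v in self.params.items():
            lines.append(f"  {k:10s} = {v:.6f} /year")
        return "\n".join(lines)


def calibrate(
    model,
    targets: list[CalibrationTarget] | None = None,
    scenario: str = "base_case",
    free: tuple = _FREE_PARAMS,
    bounds: dict | None = None,
    seed: int = 0,
    n_starts: int = 8,
    max_evals: int = 4000,
    tol: float = 1e-8,
) -> CalibrationResults:
    """Recover free parameters by bounded multi-start simplex search.

    Deterministic given ``seed`` (Latin-hypercube starting points).  The
    convergence flag is set when the best objective improves by less than
    ``tol`` over a full restart, or reaches (near) zero.
    """
    targets = targets if targets is not None else default_targets(scenario)
    bounds = {**_DEFAULT_BOUNDS, **(bounds or {})}
    lo = np.array([bounds[p][0] for p in free])
    hi = np.array([bounds[p][1] for p in free])
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise ValueError("calibration bounds must be finite")

    evals = 0

    def fun(x: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        return objective(dict(zip(free, x)), targets, model, scenario)

    if np.allclose(lo, hi):
        val = fun(lo)
        return CalibrationResults(dict(zip(free, lo)), val, True, evals, 1,
                                  [val], model)

    sampler = qmc.LatinHypercube(d=len(free), seed=seed)
    starts = qmc.scale(sampler.random(n=n_starts), lo, hi)

    best_x, best_f = None, np.inf
    per_start_best: list[float] = []
    converged = False
    for x0 in starts:
        budget = max_evals - evals
        if budget <= 10:
            break
        res = minimize(
            fun, x0, method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"xatol": 1e-9, "fatol": 1e-14,
                     "maxfev": min(budget, 800), "maxiter": min(budget, 800)},
        )
        per_start_best.append(float(res.fun))
        if res.fun < best_f - tol:
            # real improvement this restart
            improved = True
        else:
            improved = False
        if res.fun < best_f:
            best_f, best_x = float(res.fun), np.asarray(res.x)
        if not improved and per_start_best.index(min(per_start_best)) < len(per_start_best) - 1:
            converged = True  # a full restart failed to improve the best
        if best_f < 1e-12:
            converged = True
            break
    params = dict(zip(free, best_x))
    return CalibrationResults(params, best_f, converged, evals, len(per_start_best),
                              per_start_best, model)
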