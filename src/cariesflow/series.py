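"""Annual time series container and extrapolation rules.

Exogenous model inputs (population, beverage prices, non-SSB sugar
consumption) are annual series on contiguous calendar years.  The container
is deliberately small: a start year plus a 1-D float array, with the
operations the generators need (indexing by calendar year, slicing,
moving-average extrapolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AnnualSeries", "extrapolate_pct_change_ma"]


@dataclass(frozen=True)
class AnnualSeries:
    """A non-negative annual series on contiguous calendar years.

    Parameters
    ----------
    start_year : int
        Calendar year of the first value.
    values : array-like of float
        One value per year, all non-negative.
    units : str, optional
        Free-text units label carried through to tidy output
        (e.g. ``"persons"``, ``"Baht/litre"``, ``"kg/person/year"``).
    """

    start_year: int
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("AnnualSeries requires a 1-D series of length >= 1")
        if np.any(vals < 0):
            raise ValueError("AnnualSeries values must be non-negative")
        object.__setattr__(self, "values", vals)

    @property
    def end_year(self) -> int:
        return self.start_year + len(self.values) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, year: int) -> float:
        """Value at a calendar year (clamped to the series ends)."""
        idx = int(year) - self.start_year
        idx = min(max(idx, 0), len(self.values) - 1)
        return float(self.values[idx])

    def at(self, year: int, *, clamp: bool = True) -> float:
        if not clamp and not (self.start_year <= year <= self.end_year):
            raise KeyError(f"year {year} outside [{self.start_year}, {self.end_year}]")
        return self[year]

    def to_frame(self, name: str = "value") -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, name: self.values})


def extrapolate_pct_change_ma(
    series: AnnualSeries, window: int = 4, horizon_end: int | None = None
) -> AnnualSeries:
    """Extend a series with a rolling moving average of annual percent changes.

    Each extrapolated value equals the previous value times
    ``1 + mean(last `window` annual percent changes)``, with the percent
    changes recomputed rolling forward so the extrapolated years feed back
    into the window.

    Parameters
    ----------
    series : AnnualSeries
        Reported history; must contain at least ``window + 1`` values so
        that ``window`` percent changes exist.
    window : int
        Number of trailing annual percent changes averaged (simple mean).
    horizon_end : int
        Last calendar year of the extended series.

    Returns
    -------
    AnnualSeries
        The input series extended through ``horizon_end`` (returned
        unchanged if ``horizon_end`` does not exceed the series end).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(series) < window + 1:
        raise ValueError(
            f"series of length {len(series)} too short for a {window}-year "
            "percent-change moving average (need window + 1 values)"
        )
    if horizon_end is None or horizon_end <= series.end_year:
        return series

    vals = list(series.values)
    # percent changes; a zero value followed by zero counts as 0% change
    def pct(a: float, b: float) -> float:
        if a == 0.0:
            return 0.0
        return (b - a) / a

    changes = [pct(vals[i - 1], vals[i]) for i in range(1, len(vals))]
    for _ in range(horizon_end - series.end_year):
        ma = float(np.mean(changes[-window:]))
        nxt = vals[-1] * (1.0 + ma)
        nxt = max(nxt, 0.0)
        changes.append(pct(vals[-1], nxt))
        vals.append(nxt)
    return AnnualSeries(series.start_year, np.asarray(vals), units=series.units)
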