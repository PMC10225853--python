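"""Seasonal climate predictors: aggregation, standardization, trends, counterfactuals.

The demographic model consumes five seasonal predictors on a regular grid:

========  =============================================  ==========
id        variable                                       season
========  =============================================  ==========
``T_br``  mean temperature, breeding season              Apr-Jul
``P_br``  total precipitation, breeding season           Apr-Jul
``T_at``  mean temperature, autumn                       Sep-Nov
``T_wn``  minimum temperature, winter                    Dec-Feb
``P_wn``  total precipitation, winter                    Dec-Feb
========  =============================================  ==========

Winter spans the calendar-year boundary: the winter assigned to year *y*
combines December of *y-1* with January and February of *y*.

Predictors enter the demographic link functions standardized (z-scores).
Standardization pools over all cells and all reference years, one mean and
standard deviation per predictor, so spatial gradients are preserved in
z-units and a single demography-climate relationship can be shared across
the landscape.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: canonical predictor order used throughout the package
PREDICTORS = ("T_br", "P_br", "T_at", "T_wn", "P_wn")

#: season definitions (months, aggregation statistic) per predictor
SEASONS = {
    "T_br": ((4, 5, 6, 7), "mean"),
    "P_br": ((4, 5, 6, 7), "mean"),
    "T_at": ((9, 10, 11), "mean"),
    "T_wn": ((12, 1, 2), "mean"),  # monthly layers are already monthly minima
    "P_wn": ((12, 1, 2), "mean"),
}


@dataclass(frozen=True)
class StdRecord:
    """Pooled mean/sd used to standardize one predictor, kept for the inverse."""

    mean: float
    sd: float
    reference_years: tuple[int, ...]


@dataclass
class ClimateStack:
    """Year-indexed grids for each of the five seasonal predictors.

    ``data[pred]`` has shape ``(n_years, rows, cols)``.  ``std`` is ``None``
    for raw stacks and holds one :class:`StdRecord` per predictor once the
    stack has been standardized.
    """

    years: np.ndarray
    data: dict[str, np.ndarray]
    std: dict[str, StdRecord] | None = None
    cell_km: float = 1.0

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if self.years.ndim != 1 or len(self.years) < 1:
            raise ValueError("years must be a non-empty 1-d sequence")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        shapes = {v.shape for v in self.data.values()}
        if len(shapes) != 1:
            raise ValueError("all predictor arrays must share one shape")
        shape = shapes.pop()
        if shape[0] != len(self.years):
            raise ValueError("leading axis of each predictor must match years")

    @property
    def shape(self) -> tuple[int, int]:
        arr = next(iter(self.data.values()))
        return arr.shape[1:]

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_index(self, year: int) -> int:
        idx = np.nonzero(self.years == year)[0]
        if len(idx) == 0:
            raise KeyError(f"year {year} not in stack ({self.years[0]}..{self.years[-1]})")
        return int(idx[0])

    def landscape_mean(self, predictor: str) -> np.ndarray:
        """Spatial mean per year, shape ``(n_years,)``."""
        return self.data[predictor].reshape(self.n_years, -1).mean(axis=1)

    def copy(self) -> "ClimateStack":
        return ClimateStack(
            years=self.years.copy(),
            data={k: v.copy() for k, v in self.data.items()},
            std=dict(self.std) if self.std is not None else None,
            cell_km=self.cell_km,
        )


@dataclass(frozen=True)
class TrendRecord:
    """Per-predictor linear temporal trend of the landscape-mean series."""

    slope: dict[str, float]
    intercept: dict[str, float]
    first_year: int
    last_year: int

    @property
    def span_years(self) -> int:
        return self.last_year - self.first_year

    @property
    def accumulated(self) -> dict[str, float]:
        """Total change accumulated over the year span, slope x span."""
        return {k: v * self.span_years for k, v in self.slope.items()}


def aggregate_season(
    monthly: dict[tuple[int, int], np.ndarray],
    year: int,
    months: tuple[int, ...],
    statistic: str = "mean",
) -> np.ndarray:
    """Aggregate monthly layers into one seasonal grid for ``year``.

    ``monthly`` maps ``(year, month)`` to a 2-d grid.  If the month sequence
    wraps past December (e.g. ``(12, 1, 2)``), the months before the wrap are
    taken from ``year - 1``.  ``statistic`` is ``mean``, ``min`` or ``sum``.
    """
    months = tuple(months)
    if not months:
        raise ValueError("months must be non-empty")
    # a decrease in the month sequence marks the calendar-year wrap:
    # months before the wrap belong to year-1 (e.g. Dec 1999 for winter 2000)
    wrap_at = len(months)
    for i in range(1, len(months)):
        if months[i] < months[i - 1]:
            wrap_at = i
            break
    layers = []
    for i, m in enumerate(months):
        y = year - 1 if (wrap_at < len(months) and i < wrap_at) else year
        key = (y, m)
        if key not in monthly:
            raise KeyError(f"missing monthly layer {key}")
        layers.append(np.asarray(monthly[key], dtype=float))
    stack = np.stack(layers)
    if statistic == "mean":
        return stack.mean(axis=0)
    if statistic == "min":
        return stack.min(axis=0)
    if statistic == "sum":
        return stack.sum(axis=0)
    raise ValueError(f"unknown statistic {statistic!r}")


def build_stack_from_monthly(
    monthly: dict[str, dict[tuple[int, int], np.ndarray]],
    years: np.ndarray,
    cell_km: float = 1.0,
) -> ClimateStack:
    """Assemble a raw :class:`ClimateStack` from per-variable monthly layers.

    ``monthly`` maps predictor id to its ``(year, month) -> grid`` mapping
    (the T_wn mapping should hold monthly-minimum layers).
    """
    years = np.asarray(years, dtype=int)
    data = {}
    for pred in PREDICTORS:
        months, stat = SEASONS[pred]
        data[pred] = np.stack(
            [aggregate_season(monthly[pred], int(y), months, stat) for y in years]
        )
    return ClimateStack(years=years, data=data, cell_km=cell_km)


def standardize(stack: ClimateStack, reference_years=None) -> ClimateStack:
    """Standardize each predictor with a global mean/sd pooled over cells and years.

    ``reference_years`` defaults to all years in the stack; it must be a
    subset of them.  Raises ``ValueError`` on zero pooled standard deviation.
    """
    if reference_years is None:
        reference_years = stack.years
    reference_years = np.asarray(reference_years, dtype=int)
    missing = set(reference_years) - set(stack.years.tolist())
    if missing:
        raise ValueError(f"reference years not in stack: {sorted(missing)}")
    ref_idx = np.isin(stack.years, reference_years)
    records, data = {}, {}
    for pred, arr in stack.data.items():
        ref = arr[ref_idx]
        m = float(ref.mean())
        s = float(ref.std())
        if s <= 0.0:
            raise ValueError(f"zero pooled sd for predictor {pred}; cannot standardize")
        records[pred] = StdRecord(mean=m, sd=s, reference_years=tuple(int(y) for y in reference_years))
        data[pred] = (arr - m) / s
    return ClimateStack(years=stack.years.copy(), data=data, std=records, cell_km=stack.cell_km)


def apply_standardization(stack: ClimateStack, records: dict[str, StdRecord]) -> ClimateStack:
    """Standardize ``stack`` using an existing record (e.g. the factual one
    when preparing a counterfactual stack)."""
    data = {p: (stack.data[p] - r.mean) / r.sd for p, r in records.items()}
    return ClimateStack(years=stack.years.copy(), data=data, std=dict(records), cell_km=stack.cell_km)


def unstandardize(stack: ClimateStack) -> ClimateStack:
    """Inverse of :func:`standardize`; requires the stack's records."""
    if stack.std is None:
        raise ValueError("stack carries no standardization record")
    data = {p: stack.data[p] * r.sd + r.mean for p, r in stack.std.items()}
    return ClimateStack(years=stack.years.copy(), data=data, std=None, cell_km=stack.cell_km)


def fit_trend(stack: ClimateStack) -> TrendRecord:
    """OLS linear trend of each predictor's landscape-mean series vs year."""
    if stack.n_years < 3:
        raise ValueError("need at least 3 years to fit a trend")
    slopes, intercepts = {}, {}
    x = stack.years.astype(float)
    for pred in stack.data:
        y = stack.landscape_mean(pred)
        b, a = np.polyfit(x, y, 1)
        slopes[pred] = float(b)
        intercepts[pred] = float(a)
    return TrendRecord(
        slope=slopes,
        intercept=intercepts,
        first_year=int(stack.years[0]),
        last_year=int(stack.years[-1]),
    )


def detrend(stack: ClimateStack, trend: TrendRecord, anchor_year: int | None = None) -> ClimateStack:
    """Remove the fitted linear trend, holding the ``anchor_year`` layer fixed.

    This is the counterfactual "stationary climate" construction: each year's
    grid becomes ``grid - slope * (year - anchor_year)``, so climate stays at
    start-of-period conditions (the default anchor is the first year).
    """
    if anchor_year is None:
        anchor_year = int(stack.years[0])
    if anchor_year not in stack.years:
        raise ValueError(f"anchor year {anchor_year} outside stack years")
    dt = (stack.years - anchor_year).astype(float)
    data = {}
    for pred, arr in stack.data.items():
        data[pred] = arr - trend.slope[pred] * dt[:, None, None]
    return ClimateStack(years=stack.years.copy(), data=data, std=None, cell_km=stack.cell_km)


def check_collinearity(stack: ClimateStack, threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise Pearson correlation between predictors over all cell-years.

    Returns a table with columns ``pred_i, pred_j, r, flagged``; a pair is
    flagged when ``|r| >= threshold`` (candidates for exclusion, as done for
    the winter-minimum-temperature effect on juvenile survival).
    """
    preds = list(stack.data)
    if len(preds) < 2:
        raise ValueError("need at least two predictors")
    flat = {p: stack.data[p].ravel() for p in preds}
    rows = []
    for a, b in itertools.combinations(preds, 2):
        r = float(np.corrcoef(flat[a], flat[b])[0, 1])
        rows.append({"pred_i": a, "pred_j": b, "r": r, "flagged": bool(abs(r) >= threshold)})
    return pd.DataFrame(rows)
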