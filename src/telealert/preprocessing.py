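"""Adherence accounting and causal gap imputation.

Daily home measurements arrive intermittently.  Before an alert index can be
computed on a daily grid, interior gaps are filled by linear interpolation
between the bracketing observations — emulating a real-time system that
retro-fills a gap the moment the later observation arrives.  No value is ever
imputed from the future relative to the day it is used on: an index evaluated
"as of" an observed day t only consumes grid values whose bracketing
observations are dated <= t.

Adherence is counted on observed values only; imputed days never count.
"""

from __future__ import annotations

import dataclasses
from datetime import date, timedelta

import numpy as np

from .data_model import MeasurementSeries

__all__ = ["PreparedSeries", "prepare_series", "weekly_adherence", "is_adherent"]

# status codes on the daily grid
MISSING, OBSERVED, IMPUTED = 0, 1, 2


@dataclasses.dataclass
class PreparedSeries:
    """A measurement series regularized onto a contiguous daily grid.

    ``values[i]`` is the value on ``start + i`` days; ``status[i]`` is one of
    OBSERVED, IMPUTED, MISSING.  The grid runs from the first to the last
    observation, so every interior day is observed or imputed.
    """

    series: MeasurementSeries
    start: date
    values: np.ndarray
    status: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    @property
    def end(self) -> date:
        return self.start + timedelta(days=len(self.values) - 1)

    def grid_dates(self) -> list:
        return [self.start + timedelta(days=i) for i in range(len(self.values))]

    def observed_mask(self) -> np.ndarray:
        return self.status == OBSERVED

    def position(self, d: date) -> int:
        return (d - self.start).days


def prepare_series(series: MeasurementSeries) -> PreparedSeries:
    """Regularize a series onto its daily grid with linear gap imputation.

    Each interior gap between two observations is filled linearly; the imputed
    value for a gap day depends only on its two bracketing observations, so it
    is reproducible from any data snapshot taken at or after the later
    bracketing observation (the causality contract).  Raises on empty input.
    """
    if len(series) == 0:
        raise ValueError("cannot prepare an empty series")
    day0 = series.dates[0]
    n = (series.dates[-1] - day0).days + 1
    values = np.full(n, np.nan)
    status = np.full(n, MISSING, dtype=np.uint8)
    pos = np.array([(d - day0).days for d in series.dates], dtype=np.int64)
    vals = series.values_array()
    values[pos] = vals
    status[pos] = OBSERVED
    for (p0, v0), (p1, v1) in zip(zip(pos, vals), zip(pos[1:], vals[1:])):
        if p1 - p0 > 1:
            slope = (v1 - v0) / (p1 - p0)
            for g in range(p0 + 1, p1):
                values[g] = v0 + slope * (g - p0)
                status[g] = IMPUTED
    return PreparedSeries(series, day0, values, status)


def weekly_adherence(series: MeasurementSeries, start: date, end: date) -> tuple:
    """Observed-measurement counts in each 7-day half of a 14-day window.

    The window is end-inclusive and must span exactly 14 days.  Only actual
    observations count — days that would be imputed do not.
    """
    if (end - start).days + 1 != 14:
        raise ValueError("adherence window must span exactly 14 days")
    mid = start + timedelta(days=7)
    first = sum(1 for d in series.dates if start <= d < mid)
    second = sum(1 for d in series.dates if mid <= d <= end)
    return first, second


def is_adherent(
    series: MeasurementSeries,
    start: date,
    end: date,
    min_per_week: int = 3,
    mode: str = "per_week",
) -> bool:
    """Whether a 14-day window meets the minimum-measurement rule.

    ``per_week`` (default, strict reading): each 7-day half needs at least
    ``min_per_week`` observed values.  ``per_fortnight`` (lenient): the 14-day
    total must reach ``2 * min_per_week``.
    """
    c1, c2 = weekly_adherence(series, start, end)
    if mode == "per_week":
        return c1 >= min_per_week and c2 >= min_per_week
    if mode == "per_fortnight":
        return c1 + c2 >= 2 * min_per_week
    raise ValueError(f"unknown adherence mode {mode!r}")
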