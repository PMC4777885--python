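"""Output-index alert algorithms: RoT, MACD, CUSUM, and guideline rules.

Each algorithm maps a prepared (daily-grid, gap-imputed) series to a scalar
*output index* per day; an alert fires when the index crosses a threshold in
the direction of clinical concern (weight rises and log-NITTI falls as
thoracic fluid accumulates).

* RoT (rule of thumb): the raw difference between today's value and the value
  d days earlier.  Fast but noisy — a single aberrant reading moves it.
* MACD (moving average convergence divergence): short minus long trailing
  simple moving average.  Slower, smoother, bidirectional trend follower.
* CUSUM: one-sided cumulative sum of standardized deviations beyond an
  allowance c, clamped at zero; accumulates evidence of sustained drift and
  produces long-lasting alerts.

Window statistics consume imputed grid values, but index entries are emitted
on observed days only, so every reported value is computable in real time
from observations dated on or before its own day.
"""

from __future__ import annotations

import dataclasses
import warnings
from datetime import date, timedelta
from typing import Optional

import numpy as np

from .data_model import LBS_TO_KG, MeasurementSeries, Modality, PatientRecord
from .preprocessing import OBSERVED, PreparedSeries, prepare_series

__all__ = [
    "RoTParams",
    "MACDParams",
    "CUSUMParams",
    "OutputIndexSeries",
    "rot_index",
    "macd_index",
    "cusum_index",
    "compute_index",
    "compute_record_index",
    "threshold_alerts",
    "GuidelineRule",
    "guideline_alerts",
    "GUIDELINE_PRESETS",
    "OPTIMAL_PRESETS",
    "SIGMA_FLOOR",
]

#: Floor on the trailing SD in CUSUM standardization (measurement units),
#: guarding against division by zero on locally constant windows.
SIGMA_FLOOR = 1e-6


@dataclasses.dataclass(frozen=True)
class RoTParams:
    """Rule-of-thumb lag: index(t) = x(t) - x(t - d)."""

    d: int

    def complexity(self) -> float:
        return float(self.d)


@dataclasses.dataclass(frozen=True)
class MACDParams:
    """Short/long trailing simple-moving-average windows, in days."""

    n_short: int
    n_long: int

    def complexity(self) -> float:
        return float(self.n_short + self.n_long)


@dataclasses.dataclass(frozen=True)
class CUSUMParams:
    """Running-statistics window ``d`` (days) and allowance ``c`` per step."""

    d: int
    c: float

    def complexity(self) -> float:
        return float(self.d + self.c)


@dataclasses.dataclass
class OutputIndexSeries:
    """Dated output-index values of one algorithm on one patient series.

    Entries sit on observed measurement days (a subset of the daily grid);
    the first ``warmup`` grid days of each monitoring block carry no value.
    """

    patient_id: str
    algorithm: str
    modality: Modality
    direction: str  # 'increase' | 'decrease'
    dates: tuple
    values: np.ndarray
    warmup: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.direction not in ("increase", "decrease"):
            raise ValueError(f"bad direction {self.direction!r}")
        if len(self.dates) != len(self.values):
            raise ValueError("dates/values length mismatch")

    def __len__(self) -> int:
        return len(self.values)

    def day_numbers(self) -> np.ndarray:
        return np.array([d.toordinal() for d in self.dates], dtype=np.int64)

    def values_in(self, start: date, end: date) -> np.ndarray:
        mask = [start <= d <= end for d in self.dates]
        return self.values[np.asarray(mask, dtype=bool)] if self.dates else self.values[:0]

    def peak(self, start: date, end: date) -> Optional[float]:
        """Most extreme value in a window: max for increase, min for decrease."""
        vals = self.values_in(start, end)
        if len(vals) == 0:
            return None
        return float(vals.max() if self.direction == "increase" else vals.min())


def _default_direction(modality: Modality, direction: Optional[str]) -> str:
    return direction if direction is not None else Modality(modality).direction


def _emit(prepared: PreparedSeries, grid_index: np.ndarray, defined: np.ndarray,
          name: str, direction: str, warmup: int) -> OutputIndexSeries:
    """Keep grid positions that are defined *and* observed."""
    keep = defined & (prepared.status == OBSERVED)
    pos = np.nonzero(keep)[0]
    dates = tuple(prepared.start + timedelta(days=int(i)) for i in pos)
    return OutputIndexSeries(
        prepared.series.patient_id,
        name,
        prepared.series.modality,
        direction,
        dates,
        grid_index[pos],
        warmup,
    )


def rot_index(
    prepared: PreparedSeries, params: RoTParams, direction: Optional[str] = None
) -> OutputIndexSeries:
    """Difference index x(t) − x(t−d) on the imputed daily grid; warmup d days."""
    if params.d < 1:
        raise ValueError("RoT lag d must be >= 1")
    direction = _default_direction(prepared.series.modality, direction)
    v = prepared.values
    n = len(v)
    idx = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    if n > params.d:
        idx[params.d:] = v[params.d:] - v[:-params.d]
        defined[params.d:] = True
    return _emit(prepared, idx, defined, "RoT", direction, params.d)


def _trailing_sma(v: np.ndarray, n: int) -> np.ndarray:
    """Trailing simple moving average; defined from position n-1 onward."""
    out = np.full(len(v), np.nan)
    if len(v) >= n:
        c = np.concatenate(([0.0], np.cumsum(v)))
        out[n - 1:] = (c[n:] - c[:-n]) / n
    return out


def macd_index(
    prepared: PreparedSeries, params: MACDParams, direction: Optional[str] = None
) -> OutputIndexSeries:
    """SMA(N_s) − SMA(N_l) trend index; warmup N_l − 1 days."""
    if not (1 <= params.n_short < params.n_long):
        raise ValueError("MACD requires 1 <= n_short < n_long")
    direction = _default_direction(prepared.series.modality, direction)
    v = prepared.values
    idx = _trailing_sma(v, params.n_short) - _trailing_sma(v, params.n_long)
    defined = ~np.isnan(idx)
    return _emit(prepared, idx, defined, "MACD", direction, params.n_long - 1)


def cusum_index(
    prepared: PreparedSeries, params: CUSUMParams, direction: Optional[str] = None
) -> OutputIndexSeries:
    """One-sided standardized CUSUM with allowance c, clamped at zero.

    With mu_t, sigma_t the mean and sample SD over the previous ``d`` grid
    days (excluding day t) and z_t = (x_t − mu_t) / max(sigma_t, SIGMA_FLOOR):

    * decrease direction:  S_t = min(0, S_{t−1} + z_t + c)   (S ≤ 0)
    * increase direction:  S_t = max(0, S_{t−1} + z_t − c)   (S ≥ 0)

    S is 0 at warmup end; the sum is never reset within a monitoring block.
    """
    if params.d < 2:
        raise ValueError("CUSUM window d must be >= 2")
    if params.c < 0:
        raise ValueError("CUSUM allowance c must be >= 0")
    direction = _default_direction(prepared.series.modality, direction)
    v = prepared.values
    n = len(v)
    idx = np.full(n, np.nan)
    defined = np.zeros(n, dtype=bool)
    d = params.d
    if n > d:
        windows = np.lib.stride_tricks.sliding_window_view(v, d)  # windows[i] = v[i:i+d]
        mu = windows.mean(axis=1)
        sd = windows.std(axis=1, ddof=1)
        s = 0.0
        c = params.c
        for t in range(d, n):
            z = (v[t] - mu[t - d]) / max(sd[t - d], SIGMA_FLOOR)
            if direction == "decrease":
                s = min(0.0, s + z + c)
            else:
                s = max(0.0, s + z - c)
            idx[t] = s
            defined[t] = True
    return _emit(prepared, idx, defined, "CUSUM", direction, d)


_INDEX_FUNCS = {
    "rot": (rot_index, RoTParams),
    "macd": (macd_index, MACDParams),
    "cusum": (cusum_index, CUSUMParams),
}


def compute_index(prepared: PreparedSeries, algorithm: str, params,
                  direction: Optional[str] = None) -> OutputIndexSeries:
    """Dispatch by algorithm name ('rot' | 'macd' | 'cusum')."""
    func, _ = _INDEX_FUNCS[algorithm.lower()]
    return func(prepared, params, direction)


def _monitoring_blocks(record: PatientRecord, pause_days: int = 7):
    """Contiguous monitoring intervals, split at hospitalizations.

    Each block ends at an admission date (or monitoring end); monitoring
    pauses for ``pause_days`` after any admission (the hospital stay), so the
    next block starts ``pause_days + 1`` days after admission.  An admission
    falling inside a previous pause does not split a block.  Yields
    ``(start, end, event_or_None)`` with the block's terminal event.
    """
    blocks = []
    start = record.monitoring_start
    for ev in record.events:
        if ev.admission_date < start:
            continue  # admission during a previous pause: no 2-week division fits
        blocks.append((start, ev.admission_date, ev))
        start = ev.admission_date + timedelta(days=pause_days + 1)
    if start <= record.monitoring_end:
        blocks.append((start, record.monitoring_end, None))
    return blocks


def compute_record_index(
    record: PatientRecord,
    modality: Modality,
    algorithm: str,
    params,
    direction: Optional[str] = None,
    pause_days: int = 7,
) -> OutputIndexSeries:
    """Compute an index over a whole record, restarting at each block.

    The index (including the CUSUM sum and all trailing windows) is reset at
    monitoring start and after each hospitalization discharge, so data from
    before an admission never leaks across the hospital-stay pause.
    """
    modality = Modality(modality)
    series = record.series.get(modality)
    if series is None or len(series) == 0:
        raise ValueError(f"record {record.patient_id} has no {modality.value} data")
    direction = _default_direction(modality, direction)
    func, _ = _INDEX_FUNCS[algorithm.lower()]
    all_dates, all_values = [], []
    warmup = 0
    for start, end, _ev in _monitoring_blocks(record, pause_days):
        sub = series.window(start, end)
        if len(sub) < 2:
            continue
        part = func(prepare_series(sub), params, direction)
        warmup = part.warmup
        all_dates.extend(part.dates)
        all_values.extend(part.values)
    return OutputIndexSeries(
        record.patient_id,
        {"rot": "RoT", "macd": "MACD", "cusum": "CUSUM"}[algorithm.lower()],
        modality,
        direction,
        tuple(all_dates),
        np.asarray(all_values, dtype=float),
        warmup,
    )


def threshold_alerts(
    index: OutputIndexSeries, threshold: float, direction: Optional[str] = None
):
    """Boolean alert per index day: fires beyond ``threshold`` in ``direction``.

    Increase direction fires when index > threshold; decrease when
    index < threshold (thresholds for falling signals are negative).  A
    threshold whose sign contradicts the direction triggers a warning only.
    """
    if not np.isfinite(threshold) and not np.isinf(threshold):
        raise ValueError("threshold must be finite or infinite, not NaN")
    direction = direction or index.direction
    if direction == "increase":
        if threshold < 0 and np.isfinite(threshold):
            warnings.warn("negative threshold with increase direction", stacklevel=2)
        flags = index.values > threshold
    else:
        if threshold > 0 and np.isfinite(threshold):
            warnings.warn("positive threshold with decrease direction", stacklevel=2)
        flags = index.values < threshold
    return index.dates, flags


@dataclasses.dataclass(frozen=True)
class GuidelineRule:
    """A published weight-gain alert rule.

    ``clauses`` are (threshold_kg, over_n_days) pairs combined by OR, each
    evaluated as a RoT difference; a rule may instead (or additionally) carry
    an ``macd`` clause (n_short, n_long, threshold_kg).
    """

    label: str
    clauses: tuple = ()
    macd: Optional[tuple] = None

    def __post_init__(self):
        for thr, n in self.clauses:
            if thr <= 0 or n < 1:
                raise ValueError("rule thresholds must be positive, lags >= 1")


def _lbs(x: float) -> float:
    return round(x * LBS_TO_KG, 10)


#: Guideline and literature weight rules (thresholds in kg; pound-based rules
#: converted at 0.45 kg/lb).  Keys are addressable CLI preset names.
GUIDELINE_PRESETS = {
    "hfsa_2lb_1d": GuidelineRule(">2 lbs in 1 day", ((_lbs(2), 1),)),
    "esc_2kg_3d": GuidelineRule(">2 kg in 3 days", ((2.0, 3),)),
    "hfsa_4lb_1wk": GuidelineRule(">4 lbs in 1 week", ((_lbs(4), 7),)),
    "abraham_2lb1d_3lb3d": GuidelineRule(
        ">2 lbs in 1 day or >3 lbs in 3 days", ((_lbs(2), 1), (_lbs(3), 3))
    ),
    "abraham_2lb1d_5lb3d": GuidelineRule(
        ">2 lbs in 1 day or >5 lbs in 3 days", ((_lbs(2), 1), (_lbs(5), 3))
    ),
    "abraham_3lb1d_5lb3d": GuidelineRule(
        ">3 lbs in 1 day or >5 lbs in 3 days", ((_lbs(3), 1), (_lbs(5), 3))
    ),
    "abraham_3lb1d_7lb3d": GuidelineRule(
        ">3 lbs in 1 day or >7 lbs in 3 days", ((_lbs(3), 1), (_lbs(7), 3))
    ),
    "abraham_4lb1d_7lb3d": GuidelineRule(
        ">4 lbs in 1 day or >7 lbs in 3 days", ((_lbs(4), 1), (_lbs(7), 3))
    ),
    "abraham_4lb1d_9lb3d": GuidelineRule(
        ">4 lbs in 1 day or >9 lbs in 3 days", ((_lbs(4), 1), (_lbs(9), 3))
    ),
    "abraham_5lb1d_9lb3d": GuidelineRule(
        ">5 lbs in 1 day or >9 lbs in 3 days", ((_lbs(5), 1), (_lbs(9), 3))
    ),
    "chaudhry_2lb_1wk": GuidelineRule(">2 lbs in 1 week", ((_lbs(2), 7),)),
    "chaudhry_5lb_1wk": GuidelineRule(">5 lbs in 1 week", ((_lbs(5), 7),)),
    "zhang_macd": GuidelineRule(
        ">4 lbs in a 5 to 80 days MACD", (), macd=(5, 80, _lbs(4))
    ),
}

#: Whole-dataset optimal parameter/threshold presets for each algorithm and
#: modality (thresholds in kg for weight, log-ohm for NITTI).
OPTIMAL_PRESETS = {
    "weight_rot": {"params": RoTParams(17), "threshold": 2.7},
    "weight_macd": {"params": MACDParams(9, 20), "threshold": 0.62},
    "weight_cusum": {"params": CUSUMParams(10, 0.75), "threshold": 8.7},
    "nitti_rot": {"params": RoTParams(21), "threshold": -0.27},
    "nitti_macd": {"params": MACDParams(9, 35), "threshold": -0.059},
    "nitti_cusum": {"params": CUSUMParams(20, 0.75), "threshold": -7.8},
}


def guideline_alerts(prepared: PreparedSeries, rule: GuidelineRule):
    """Daily boolean alerts for a weight rule: OR over its clauses.

    Each (threshold, n-day) clause fires where the n-day RoT difference
    exceeds the threshold; an MACD clause fires where the MACD index does.
    Returns (dates, flags) on the observed-day index grid.
    """
    dates = None
    combined = None
    for thr, n in rule.clauses:
        idx = rot_index(prepared, RoTParams(n), direction="increase")
        _, flags = threshold_alerts(idx, thr)
        full = _align(prepared, idx, flags)
        combined = full if combined is None else (combined | full)
    if rule.macd is not None:
        ns, nl, thr = rule.macd
        idx = macd_index(prepared, MACDParams(ns, nl), direction="increase")
        _, flags = threshold_alerts(idx, thr)
        full = _align(prepared, idx, flags)
        combined = full if combined is None else (combined | full)
    obs_pos = np.nonzero(prepared.observed_mask())[0]
    obs_dates = tuple(prepared.start + timedelta(days=int(i)) for i in obs_pos)
    if combined is None:
        combined = np.zeros(len(prepared), dtype=bool)
    return obs_dates, combined[obs_pos]


def _align(prepared: PreparedSeries, idx: OutputIndexSeries, flags: np.ndarray):
    """Scatter per-index-day flags back onto the full grid (False elsewhere)."""
    full = np.zeros(len(prepared), dtype=bool)
    for d, f in zip(idx.dates, flags):
        full[prepared.position(d)] = bool(f)
    return full
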