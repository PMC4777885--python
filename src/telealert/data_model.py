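"""Core data types and CSV I/O for home-telemonitoring cohorts.

A cohort is a set of patients, each carrying daily (but intermittent)
measurement series for one or both modalities — body weight in kilograms and
noninvasive transthoracic bio-impedance (NITTI) — together with adjudicated
hospitalization events and a monitoring interval.  NITTI is stored after a
log transform (natural log by default) to correct the right skew of raw
impedance in ohms; all downstream trend statistics operate on the log scale.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "MeasurementSeries",
    "HospitalizationEvent",
    "PatientRecord",
    "Cohort",
    "load_cohort",
    "write_cohort",
    "LBS_TO_KG",
]

#: Conversion used when expanding guideline rules stated in pounds.
LBS_TO_KG = 0.45


class Modality(str, enum.Enum):
    """Measurement modality of a daily series (stored units)."""

    WEIGHT = "weight_kg"
    NITTI = "nitti_log_ohm"

    @property
    def direction(self) -> str:
        """Alerting direction: fluid overload raises weight, lowers NITTI."""
        return "increase" if self is Modality.WEIGHT else "decrease"


#: Raw CSV modality labels accepted on load.  ``nitti_ohm`` is log-transformed;
#: ``nitti_log_ohm`` is passed through unchanged (idempotence guard: data that
#: is already on the log scale is never transformed twice).
_RAW_MODALITIES = {
    "weight_kg": Modality.WEIGHT,
    "nitti_ohm": Modality.NITTI,
    "nitti_log_ohm": Modality.NITTI,
}


def _as_date(x) -> date:
    if isinstance(x, date):
        return x
    return pd.Timestamp(x).date()


@dataclasses.dataclass(frozen=True)
class MeasurementSeries:
    """One patient's dated daily values for a single modality.

    Dates are strictly increasing with at most one entry per calendar day;
    values are finite, and weights are strictly positive.
    """

    patient_id: str
    modality: Modality
    dates: tuple
    values: tuple

    def __post_init__(self):
        object.__setattr__(self, "dates", tuple(self.dates))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        object.__setattr__(self, "modality", Modality(self.modality))
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values must have equal length")
        for d0, d1 in zip(self.dates, self.dates[1:]):
            if d1 <= d0:
                raise ValueError(
                    f"dates must be strictly increasing for patient "
                    f"{self.patient_id}: {d0} -> {d1}"
                )
        for v in self.values:
            if not math.isfinite(v):
                raise ValueError(f"non-finite value in series for {self.patient_id}")
            if self.modality is Modality.WEIGHT and v <= 0:
                raise ValueError(f"nonpositive weight for {self.patient_id}: {v}")

    def __len__(self) -> int:
        return len(self.dates)

    def day_numbers(self) -> np.ndarray:
        """Dates as proleptic-Gregorian ordinals (int array)."""
        return np.array([d.toordinal() for d in self.dates], dtype=np.int64)

    def values_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def truncated(self, last_date: date) -> "MeasurementSeries":
        """Sub-series containing only entries dated on or before ``last_date``."""
        keep = [i for i, d in enumerate(self.dates) if d <= last_date]
        return MeasurementSeries(
            self.patient_id,
            self.modality,
            tuple(self.dates[i] for i in keep),
            tuple(self.values[i] for i in keep),
        )

    def window(self, start: date, end: date) -> "MeasurementSeries":
        """Sub-series restricted to ``start <= date <= end`` (inclusive)."""
        keep = [i for i, d in enumerate(self.dates) if start <= d <= end]
        return MeasurementSeries(
            self.patient_id,
            self.modality,
            tuple(self.dates[i] for i in keep),
            tuple(self.values[i] for i in keep),
        )


@dataclasses.dataclass(frozen=True, order=True)
class HospitalizationEvent:
    """A hospitalization, flagged when adjudicated as decompensated HF."""

    patient_id: str = dataclasses.field(compare=False)
    admission_date: date = dataclasses.field(compare=True)
    hf_adjudicated: bool = dataclasses.field(compare=False, default=True)


@dataclasses.dataclass(frozen=True)
class PatientRecord:
    """Measurement series, events and the monitoring interval of one patient."""

    patient_id: str
    monitoring_start: date
    monitoring_end: date
    series: Mapping[Modality, MeasurementSeries]
    events: tuple = ()

    def __post_init__(self):
        object.__setattr__(
            self, "series", {Modality(k): v for k, v in dict(self.series).items()}
        )
        object.__setattr__(
            self, "events", tuple(sorted(self.events, key=lambda e: e.admission_date))
        )
        if self.monitoring_start > self.monitoring_end:
            raise ValueError(f"empty monitoring interval for {self.patient_id}")
        for mod, s in self.series.items():
            if s.modality is not mod:
                raise ValueError("series filed under wrong modality key")
            if len(s) and not (
                self.monitoring_start <= s.dates[0] <= s.dates[-1] <= self.monitoring_end
            ):
                raise ValueError(
                    f"measurements outside monitoring interval for {self.patient_id}"
                )
        for e in self.events:
            if not (self.monitoring_start <= e.admission_date <= self.monitoring_end):
                raise ValueError(
                    f"event on {e.admission_date} outside monitoring interval "
                    f"[{self.monitoring_start}, {self.monitoring_end}] "
                    f"for patient {self.patient_id}"
                )

    @property
    def monitored_days(self) -> int:
        return (self.monitoring_end - self.monitoring_start).days + 1

    def hf_events(self) -> tuple:
        return tuple(e for e in self.events if e.hf_adjudicated)

    def __eq__(self, other):
        if not isinstance(other, PatientRecord):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.monitoring_start == other.monitoring_start
            and self.monitoring_end == other.monitoring_end
            and dict(self.series) == dict(other.series)
            and self.events == other.events
        )


@dataclasses.dataclass(frozen=True)
class Cohort:
    """A collection of patient records with unique patient ids."""

    records: tuple
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids in cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def record(self, patient_id: str) -> PatientRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)

    def n_events(self, hf_only: bool = True) -> int:
        return sum(
            len(r.hf_events() if hf_only else r.events) for r in self.records
        )

    def __eq__(self, other):
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.records == other.records


def _log(values: np.ndarray, log_base: str) -> np.ndarray:
    if log_base == "natural":
        return np.log(values)
    if log_base in ("10", "log10"):
        return np.log10(values)
    raise ValueError(f"unknown log base {log_base!r}")


def load_cohort(
    measurements_path,
    events_path,
    monitoring_path=None,
    log_base: str = "natural",
) -> Cohort:
    """Read a cohort from long-format CSV files.

    ``measurements.csv`` has columns ``patient_id,date,modality,value`` with
    modality in {weight_kg, nitti_ohm, nitti_log_ohm}; raw impedance
    (``nitti_ohm``) is log-transformed on load.  ``events.csv`` has columns
    ``patient_id,admission_date,hf_adjudicated``.  The optional
    ``monitoring.csv`` (``patient_id,monitoring_start,monitoring_end``) pins
    monitoring intervals; without it the interval is the span of the patient's
    measurements.

    Raises ``ValueError`` on duplicate (patient, date, modality) rows,
    nonpositive weight or raw impedance, or an event outside the monitoring
    interval.
    """
    meas = pd.read_csv(measurements_path, float_precision="round_trip")
    required = {"patient_id", "date", "modality", "value"}
    if not required.issubset(meas.columns):
        raise ValueError(f"measurements file must have columns {sorted(required)}")
    meas = meas.copy()
    meas["patient_id"] = meas["patient_id"].astype(str)
    meas["date"] = pd.to_datetime(meas["date"]).dt.date

    dup = meas.duplicated(subset=["patient_id", "date", "modality"], keep=False)
    if dup.any():
        row = meas[dup].iloc[0]
        raise ValueError(
            "duplicate measurement row: patient "
            f"{row['patient_id']}, {row['date']}, {row['modality']}"
        )
    unknown = set(meas["modality"]) - set(_RAW_MODALITIES)
    if unknown:
        raise ValueError(f"unknown modalities: {sorted(unknown)}")
    bad = meas[
        meas["modality"].isin(["weight_kg", "nitti_ohm"]) & (meas["value"] <= 0)
    ]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"nonpositive {row['modality']} value {row['value']} for patient "
            f"{row['patient_id']} on {row['date']}"
        )

    try:
        ev = pd.read_csv(events_path)
    except pd.errors.EmptyDataError:
        ev = pd.DataFrame(columns=["patient_id", "admission_date", "hf_adjudicated"])
    if len(ev):
        ev = ev.copy()
        ev["patient_id"] = ev["patient_id"].astype(str)
        ev["admission_date"] = pd.to_datetime(ev["admission_date"]).dt.date
        ev["hf_adjudicated"] = ev["hf_adjudicated"].astype(bool)

    intervals = {}
    if monitoring_path is not None:
        mon = pd.read_csv(monitoring_path)
        mon["patient_id"] = mon["patient_id"].astype(str)
        for _, row in mon.iterrows():
            intervals[row["patient_id"]] = (
                _as_date(row["monitoring_start"]),
                _as_date(row["monitoring_end"]),
            )

    records = []
    for pid, grp in meas.groupby("patient_id", sort=True):
        series = {}
        for raw_mod, sub in grp.groupby("modality"):
            mod = _RAW_MODALITIES[raw_mod]
            sub = sub.sort_values("date")
            vals = sub["value"].to_numpy(dtype=float)
            if raw_mod == "nitti_ohm":
                vals = _log(vals, log_base)
            series[mod] = MeasurementSeries(
                pid, mod, tuple(sub["date"]), tuple(vals)
            )
        if pid in intervals:
            start, end = intervals[pid]
        else:
            all_dates = sorted(grp["date"])
            start, end = all_dates[0], all_dates[-1]
        pid_events = []
        if len(ev):
            for _, row in ev[ev["patient_id"] == pid].iterrows():
                pid_events.append(
                    HospitalizationEvent(
                        pid, row["admission_date"], bool(row["hf_adjudicated"])
                    )
                )
        records.append(
            PatientRecord(pid, start, end, series, tuple(pid_events))
        )

    known = {r.patient_id for r in records}
    if len(ev):
        orphans = set(ev["patient_id"]) - known
        if orphans:
            raise ValueError(f"events for unknown patients: {sorted(orphans)}")
    return Cohort(tuple(records), provenance=str(measurements_path))


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write a cohort to ``measurements.csv``, ``events.csv``, ``monitoring.csv``.

    NITTI is written as stored (modality ``nitti_log_ohm``, log-ohm values), so
    ``load_cohort(**write_cohort(c))`` reproduces the cohort exactly; gaps are
    preserved and nothing is imputed at I/O time.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mrows, erows, nrows = [], [], []
    for rec in cohort:
        for mod, s in sorted(rec.series.items(), key=lambda kv: kv[0].value):
            for d, v in zip(s.dates, s.values):
                mrows.append((rec.patient_id, d.isoformat(), mod.value, repr(v)))
        for e in rec.events:
            erows.append(
                (rec.patient_id, e.admission_date.isoformat(), e.hf_adjudicated)
            )
        nrows.append(
            (
                rec.patient_id,
                rec.monitoring_start.isoformat(),
                rec.monitoring_end.isoformat(),
            )
        )
    paths = {
        "measurements_path": out / "measurements.csv",
        "events_path": out / "events.csv",
        "monitoring_path": out / "monitoring.csv",
    }
    pd.DataFrame(mrows, columns=["patient_id", "date", "modality", "value"]).to_csv(
        paths["measurements_path"], index=False
    )
    pd.DataFrame(
        erows, columns=["patient_id", "admission_date", "hf_adjudicated"]
    ).to_csv(paths["events_path"], index=False)
    pd.DataFrame(
        nrows, columns=["patient_id", "monitoring_start", "monitoring_end"]
    ).to_csv(paths["monitoring_path"], index=False)
    return paths
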