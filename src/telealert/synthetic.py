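"""Synthetic telemonitoring cohort generator.

Emulates the statistical structure of an observational home-telemonitoring
study of chronic heart-failure patients: roughly 91 patients followed for
about ten months, daily-but-intermittent weight and bio-impedance
measurements, and sporadic decompensation hospitalizations preceded by a
2–3 week prodrome in which weight drifts up and log-NITTI drifts down.

Defaults mirror the emulated study conditions: baseline weight N(84, 19^2) kg,
baseline log-NITTI N(3.4, 0.3^2) log-ohm, ~80% per-day measurement adherence,
and a per-patient-day event hazard tuned so a 91-patient, ~300-day cohort
yields ~24 HF hospitalizations.  Prodrome trends are linear ramps (the
simplest monotone drift; the true pre-event dynamics are unknown) adding a
total ``weight_rise`` kg / subtracting ``nitti_fall`` log-ohm by admission
day.  Monitoring pauses for 7 days after each admission (hospital stay) and
resumes at the patient's baseline.
"""

from __future__ import annotations

import dataclasses
import warnings
from datetime import date, timedelta
from typing import Optional

import numpy as np

from .data_model import (
    Cohort,
    HospitalizationEvent,
    MeasurementSeries,
    Modality,
    PatientRecord,
)

__all__ = [
    "CohortConfig",
    "ProdromeSpec",
    "generate_cohort",
    "inject_event",
    "example_series",
]


@dataclasses.dataclass
class CohortConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_patients: int = 91
    monitoring_days_mean: float = 300.0
    monitoring_days_sd: float = 60.0
    weight_baseline_mean: float = 84.0
    weight_baseline_sd: float = 19.0
    nitti_baseline_mean: float = 3.4
    nitti_baseline_sd: float = 0.3
    daily_noise_weight: float = 0.6
    daily_noise_nitti: float = 0.06
    adherence_prob: float = 0.8
    #: per-patient-day HF hospitalization probability;
    #: 24 events / (91 patients * 300 days) ~= 8.8e-4
    event_hazard: float = 8.8e-4
    prodrome_days: int = 14
    weight_rise: float = 2.5
    nitti_fall: float = 0.4
    pause_days: int = 7
    #: optional burst missingness: per-day probability of starting a run of
    #: ``burst_days_mean`` consecutive skipped days (models vacations /
    #: equipment trouble, reproducing realistic adherence-exclusion rates)
    burst_prob: float = 0.0
    burst_days_mean: float = 7.0
    start_date: date = date(2009, 1, 1)
    start_jitter_days: int = 365
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "monitoring_days_sd", "weight_baseline_sd", "nitti_baseline_sd",
            "daily_noise_weight", "daily_noise_nitti",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("adherence_prob", "burst_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.event_hazard < 0 or self.event_hazard > 1:
            raise ValueError("event_hazard implies more than one expected event per day")
        if self.prodrome_days < 1:
            raise ValueError("prodrome_days must be >= 1")


@dataclasses.dataclass(frozen=True)
class ProdromeSpec:
    """Deterministic pre-event drift added on top of noise."""

    prodrome_days: int = 14
    weight_rise: float = 2.5
    nitti_fall: float = 0.4


def _prodrome_trends(
    n_days: int, admission_offsets, spec: ProdromeSpec
) -> tuple:
    """Linear ramp trends (weight up, log-NITTI down) before each admission.

    Day ``adm - prodrome_days + j`` (j = 1..prodrome_days) carries fraction
    j/prodrome_days of the full excursion, so the admission day carries it all.
    """
    tw = np.zeros(n_days)
    tn = np.zeros(n_days)
    for adm in admission_offsets:
        for j in range(1, spec.prodrome_days + 1):
            t = adm - spec.prodrome_days + j
            if 0 <= t < n_days:
                frac = j / spec.prodrome_days
                tw[t] += spec.weight_rise * frac
                tn[t] -= spec.nitti_fall * frac
    return tw, tn


def generate_cohort(config: CohortConfig, seed: Optional[int] = None) -> Cohort:
    """Draw a reproducible synthetic cohort from ``config``.

    Per patient: monitoring length ~ N(mean, sd) clipped to >= 28 days,
    patient baselines drawn once, events drawn day-by-day from the hazard
    (suppressed during post-admission pauses), linear prodrome drift added
    before each event, i.i.d. Gaussian daily noise, and per-day/per-modality
    Bernoulli adherence thinning (plus optional burst dropouts).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        n_days = int(
            np.clip(
                rng.normal(config.monitoring_days_mean, config.monitoring_days_sd),
                28,
                None,
            )
        )
        start = config.start_date + timedelta(
            days=int(rng.integers(0, config.start_jitter_days + 1))
        )
        end = start + timedelta(days=n_days - 1)
        weight_b = max(35.0, rng.normal(config.weight_baseline_mean, config.weight_baseline_sd))
        nitti_b = rng.normal(config.nitti_baseline_mean, config.nitti_baseline_sd)

        # events: daily hazard draw, suppressed while hospitalized
        admissions = []
        pause_until = -1
        u = rng.random(n_days)
        for t in range(n_days):
            if t <= pause_until:
                continue
            if u[t] < config.event_hazard:
                admissions.append(t)
                pause_until = t + config.pause_days

        spec = ProdromeSpec(config.prodrome_days, config.weight_rise, config.nitti_fall)
        trend_w, trend_n = _prodrome_trends(n_days, admissions, spec)

        in_pause = np.zeros(n_days, dtype=bool)
        for adm in admissions:
            in_pause[adm + 1: adm + 1 + config.pause_days] = True

        series = {}
        for mod, baseline, trend, noise_sd in (
            (Modality.WEIGHT, weight_b, trend_w, config.daily_noise_weight),
            (Modality.NITTI, nitti_b, trend_n, config.daily_noise_nitti),
        ):
            vals = baseline + trend + rng.normal(0.0, noise_sd, n_days)
            observed = rng.random(n_days) < config.adherence_prob
            if config.burst_prob > 0:
                burst_u = rng.random(n_days)
                t = 0
                while t < n_days:
                    if burst_u[t] < config.burst_prob:
                        length = max(1, int(rng.exponential(config.burst_days_mean)))
                        observed[t: t + length] = False
                        t += length
                    else:
                        t += 1
            observed &= ~in_pause
            if not observed.any():
                observed[0] = True  # keep every record analyzable
            if mod is Modality.WEIGHT:
                vals = np.maximum(vals, 1.0)
            days = np.nonzero(observed)[0]
            series[mod] = MeasurementSeries(
                pid,
                mod,
                tuple(start + timedelta(days=int(t)) for t in days),
                tuple(vals[days]),
            )
        events = tuple(
            HospitalizationEvent(pid, start + timedelta(days=int(t)), True)
            for t in admissions
        )
        records.append(PatientRecord(pid, start, end, series, events))
    return Cohort(
        tuple(records),
        provenance=f"synthetic seed={config.seed if seed is None else seed}",
    )


def inject_event(
    record: PatientRecord,
    admission_date: date,
    spec: ProdromeSpec = ProdromeSpec(),
) -> PatientRecord:
    """Add a deterministic prodrome trend plus an HF event to a record.

    The trend is superimposed on existing entries in the prodrome window;
    noise is untouched.  A prodrome extending before monitoring start is
    truncated with a warning.
    """
    if not (record.monitoring_start <= admission_date <= record.monitoring_end):
        raise ValueError("admission_date outside monitoring interval")
    window_start = admission_date - timedelta(days=spec.prodrome_days - 1)
    if window_start < record.monitoring_start:
        warnings.warn(
            "prodrome extends before monitoring start; truncated", stacklevel=2
        )
    new_series = {}
    for mod, s in record.series.items():
        excursion = spec.weight_rise if mod is Modality.WEIGHT else -spec.nitti_fall
        vals = list(s.values)
        for k, d in enumerate(s.dates):
            offset = (d - admission_date).days  # in [-(prodrome-1), 0] inside window
            if -spec.prodrome_days < offset <= 0:
                frac = (offset + spec.prodrome_days) / spec.prodrome_days
                vals[k] += excursion * frac
        new_series[mod] = MeasurementSeries(s.patient_id, mod, s.dates, tuple(vals))
    events = record.events + (
        HospitalizationEvent(record.patient_id, admission_date, True),
    )
    return PatientRecord(
        record.patient_id,
        record.monitoring_start,
        record.monitoring_end,
        new_series,
        events,
    )


def example_series(seed: int = 20) -> MeasurementSeries:
    """A deterministic demo log-NITTI series for qualitative comparison.

    150 daily observations: stable baseline (3.4 log-ohm, small noise), a
    congestion episode falling 0.5 log-ohm over days 80–100, then a sustained
    low plateau.  On this series RoT responds fastest but noisiest, MACD
    traces the trend smoothly in both directions, and CUSUM accumulates into
    a long sustained alert.
    """
    rng = np.random.default_rng(seed)
    n = 150
    base = 3.4
    trend = np.zeros(n)
    trend[80:101] = -0.5 * np.arange(1, 22) / 21.0
    trend[101:] = -0.5
    vals = base + trend + rng.normal(0.0, 0.02, n)
    start = date(2009, 3, 1)
    return MeasurementSeries(
        "example",
        Modality.NITTI,
        tuple(start + timedelta(days=i) for i in range(n)),
        tuple(vals),
    )
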