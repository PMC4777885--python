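from datetime import date, timedelta

import numpy as np
import pytest

from telealert import (
    HospitalizationEvent,
    MeasurementSeries,
    Modality,
    PatientRecord,
)

D0 = date(2009, 1, 1)


def make_series(values, pid="P1", modality=Modality.WEIGHT, start=D0, dates=None):
    """Series from a value list; ``dates`` as day offsets enables gaps."""
    if dates is None:
        dates = range(len(values))
    return MeasurementSeries(
        pid,
        modality,
        tuple(start + timedelta(days=int(d)) for d in dates),
        tuple(float(v) for v in values),
    )


def make_record(
    values=None,
    pid="P1",
    modality=Modality.WEIGHT,
    start=D0,
    n_days=60,
    event_days=(),
    dates=None,
):
    """One-modality record with optional HF events at given day offsets."""
    if values is None:
        values = [80.0] * n_days
    series = make_series(values, pid, modality, start, dates)
    end = start + timedelta(days=max(n_days, len(values)) - 1)
    events = tuple(
        HospitalizationEvent(pid, start + timedelta(days=int(d)), True)
        for d in event_days
    )
    return PatientRecord(pid, start, end, {modality: series}, events)


def random_gapped_series(rng, n_days=100, p_obs=0.8, modality=Modality.WEIGHT):
    """Random-walk-ish series with Bernoulli-thinned days (first day kept)."""
    obs = rng.random(n_days) < p_obs
    obs[0] = True
    days = np.nonzero(obs)[0]
    base = 80.0 if modality is Modality.WEIGHT else 3.4
    vals = base + np.cumsum(rng.normal(0, 0.3, len(days)))
    if modality is Modality.WEIGHT:
        vals = np.maximum(vals, 1.0)
    return make_series(vals, modality=modality, dates=days)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
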