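"""Window segmentation, alarm labeling, ROC analysis and summary metrics.

Monitoring data are divided into 14-day evaluation periods such that a
period containing a decompensated-HF hospitalization ends on the admission
day.  An alarm inside the two weeks preceding a hospitalization is a true
positive; an alarm in any other period is a false positive.  Periods failing
the measurement-adherence rule (fewer than 3 observed values in either week)
are excluded from analysis, as are periods where the algorithm's warmup
leaves no index value.  Per-period scoring uses the window's *peak* index —
the most extreme value in the alerting direction — which is equivalent to
"any alert day in the window" for every monotone threshold and therefore
supports ROC threshold sweeps with one score per period.
"""

from __future__ import annotations

import dataclasses
import warnings
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

import numpy as np

from .algorithms import (
    GuidelineRule,
    OutputIndexSeries,
    _monitoring_blocks,
    guideline_alerts,
)
from .data_model import Modality, PatientRecord
from .preprocessing import is_adherent, prepare_series

__all__ = [
    "PERIOD_DAYS",
    "EvaluationPeriod",
    "ConfusionCounts",
    "ROCCurve",
    "segment_periods",
    "label_periods",
    "confusion_at_threshold",
    "roc_curve",
    "partial_auc",
    "youden_threshold",
    "false_alarm_rate",
    "evaluate_guideline_rule",
    "compare_period_means",
]

PERIOD_DAYS = 14


@dataclasses.dataclass
class EvaluationPeriod:
    """A labeled 14-day window (end-inclusive)."""

    patient_id: str
    start: date
    end: date
    is_event: bool
    event: Optional[object] = None
    peak_index: Optional[float] = None
    #: start of the monitoring block the window belongs to, used to check
    #: that an algorithm's warmup is complete before the window begins
    block_start: Optional[date] = None

    def __post_init__(self):
        if (self.end - self.start).days + 1 != PERIOD_DAYS:
            raise ValueError("evaluation periods span exactly 14 days")


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> Optional[float]:
        n = self.tp + self.fn
        return self.tp / n if n else None

    @property
    def specificity(self) -> Optional[float]:
        n = self.tn + self.fp
        return self.tn / n if n else None

    @property
    def ppv(self) -> Optional[float]:
        n = self.tp + self.fp
        return self.tp / n if n else None

    @property
    def npv(self) -> Optional[float]:
        n = self.tn + self.fn
        return self.tn / n if n else None


def segment_periods(record: PatientRecord, pause_days: int = 7):
    """Tile a record's monitoring blocks into 14-day evaluation periods.

    Within a block ending at a decompensated-HF admission, windows are tiled
    *backward* from the admission date (which ends the event period) and the
    leftover partial window at the block start is discarded.  Blocks ending
    at a non-HF admission or at monitoring end are tiled *forward* from the
    block start, discarding the trailing partial window.  Blocks shorter than
    14 days yield nothing.  Exactly one event-ending period exists per HF
    hospitalization that fits a 2-week division.
    """
    periods = []
    for start, end, ev in _monitoring_blocks(record, pause_days):
        n_windows = ((end - start).days + 1) // PERIOD_DAYS
        if ev is not None and ev.hf_adjudicated:
            for i in range(n_windows):
                pe = end - timedelta(days=PERIOD_DAYS * i)
                periods.append(
                    EvaluationPeriod(
                        record.patient_id,
                        pe - timedelta(days=PERIOD_DAYS - 1),
                        pe,
                        is_event=(i == 0),
                        event=ev if i == 0 else None,
                        block_start=start,
                    )
                )
        else:
            for i in range(n_windows):
                ps = start + timedelta(days=PERIOD_DAYS * i)
                periods.append(
                    EvaluationPeriod(
                        record.patient_id,
                        ps,
                        ps + timedelta(days=PERIOD_DAYS - 1),
                        is_event=False,
                        block_start=start,
                    )
                )
    periods.sort(key=lambda p: p.start)
    return periods


def label_periods(
    periods,
    index: OutputIndexSeries,
    record: PatientRecord,
    min_per_week: int = 3,
    adherence_mode: str = "per_week",
):
    """Attach peak index values; drop inadherent or index-free periods.

    A period is kept only if (a) the raw series of the index's modality meets
    the adherence rule inside the window, (b) the algorithm's warmup is
    complete before the window begins (a window too close to its block start
    gives a long-memory algorithm no fair baseline — the reason a long-window
    CUSUM evaluates slightly fewer events), and (c) at least one index value
    exists inside the window.  Excluded event periods are not counted as
    false negatives.
    """
    series = record.series.get(index.modality)
    out = []
    for p in periods:
        if series is None or not is_adherent(
            series, p.start, p.end, min_per_week, adherence_mode
        ):
            continue
        if (
            p.block_start is not None
            and (p.start - p.block_start).days < index.warmup
        ):
            continue
        peak = index.peak(p.start, p.end)
        if peak is None:
            continue
        out.append(dataclasses.replace(p, peak_index=peak))
    return out


def _beyond(peaks: np.ndarray, threshold: float, direction: str) -> np.ndarray:
    return peaks > threshold if direction == "increase" else peaks < threshold


def confusion_at_threshold(
    periods, threshold: float, direction: str
) -> ConfusionCounts:
    """Count TP/FP/TN/FN over labeled periods at a fixed threshold."""
    peaks = np.array([p.peak_index for p in periods], dtype=float)
    labels = np.array([p.is_event for p in periods], dtype=bool)
    fired = _beyond(peaks, threshold, direction)
    return ConfusionCounts(
        tp=int(np.sum(fired & labels)),
        fp=int(np.sum(fired & ~labels)),
        tn=int(np.sum(~fired & ~labels)),
        fn=int(np.sum(~fired & labels)),
    )


@dataclasses.dataclass
class ROCCurve:
    """Threshold sweep over all distinct period peaks.

    ``thresholds`` are in native index units; alerts fire beyond the
    threshold in ``direction``.  Includes the degenerate endpoints
    (sens 0, spec 1) and (sens 1, spec 0).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    direction: str

    def __len__(self) -> int:
        return len(self.thresholds)


def roc_curve(periods, direction: str) -> ROCCurve:
    """ROC over period peak scores; requires both classes present."""
    peaks = np.array([p.peak_index for p in periods], dtype=float)
    labels = np.array([p.is_event for p in periods], dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one period of each class")
    # orient scores so that larger = more alarming
    scores = peaks if direction == "increase" else -peaks
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.r_[distinct, len(s_sorted) - 1]
    tp = np.cumsum(l_sorted)[cut]
    fp = np.cumsum(~l_sorted)[cut]
    sens = np.r_[0.0, tp / n_pos]
    spec = np.r_[1.0, 1.0 - fp / n_neg]
    # thresholds realizing each swept set under the *strict* firing rule
    # score > threshold: midpoints between consecutive distinct scores, with
    # +inf (fire nothing) and lowest-score - 1 (fire everything) endpoints.
    s_distinct = s_sorted[cut]
    mids = np.empty_like(s_distinct)
    mids[:-1] = 0.5 * (s_distinct[:-1] + s_distinct[1:])
    mids[-1] = s_distinct[-1] - 1.0
    thr_scores = np.r_[np.inf, mids]
    thresholds = thr_scores if direction == "increase" else -thr_scores
    return ROCCurve(thresholds, sens, spec, direction)


def partial_auc(roc: ROCCurve, spec_min: float) -> float:
    """Normalized trapezoid area over specificity in [spec_min, 1].

    The ROC staircase is integrated in false-positive-rate coordinates up to
    1 − spec_min and divided by that width, so a perfect curve scores 1 and a
    chance curve 0.5 regardless of the specificity floor.
    """
    if not 0.0 <= spec_min < 1.0:
        raise ValueError("spec_min must be in [0, 1)")
    fpr = 1.0 - roc.specificity
    tpr = roc.sensitivity
    fmax = 1.0 - spec_min
    # clip the curve at fpr = fmax, interpolating on the crossing segment
    keep = fpr <= fmax
    f = fpr[keep]
    t = tpr[keep]
    if f[-1] < fmax:
        j = int(np.searchsorted(fpr, fmax, side="right"))
        if j < len(fpr):
            frac = (fmax - fpr[j - 1]) / (fpr[j] - fpr[j - 1])
            f = np.r_[f, fmax]
            t = np.r_[t, tpr[j - 1] + frac * (tpr[j] - tpr[j - 1])]
        else:
            f = np.r_[f, fmax]
            t = np.r_[t, tpr[-1]]
    return float(np.trapezoid(t, f) / fmax)


def youden_threshold(roc: ROCCurve, spec_min: float = 0.90) -> float:
    """Threshold maximizing sensitivity + specificity − 1 at high specificity.

    Only curve points with specificity strictly greater than ``spec_min``
    compete; ties go to the higher-specificity point.  If no point clears the
    floor, the most specific point is returned with a warning.
    """
    eligible = roc.specificity > spec_min
    if not eligible.any():
        warnings.warn(
            "no ROC point exceeds the specificity floor; returning the most "
            "specific point",
            stacklevel=2,
        )
        eligible = roc.specificity == roc.specificity.max()
    j = roc.sensitivity + roc.specificity - 1.0
    j_masked = np.where(eligible, j, -np.inf)
    best = j_masked.max()
    cand = np.nonzero(j_masked == best)[0]
    pick = cand[np.argmax(roc.specificity[cand])]
    return float(roc.thresholds[pick])


def alert_episodes(dates, flags) -> list:
    """Merge strictly consecutive alert days into (onset, last_day) episodes."""
    episodes = []
    onset = prev = None
    for d, f in zip(dates, flags):
        if not f:
            continue
        if prev is not None and (d - prev).days == 1:
            prev = d
        else:
            if onset is not None:
                episodes.append((onset, prev))
            onset = prev = d
    if onset is not None:
        episodes.append((onset, prev))
    return episodes


def false_alarm_rate(
    alerts_by_patient: dict,
    records,
    grace_days: int = 14,
) -> float:
    """False alert episodes per patient-year of monitoring.

    ``alerts_by_patient`` maps patient_id -> (dates, boolean flags).
    Consecutive alert days merge into one episode; an episode is false iff no
    decompensated-HF admission occurs within ``grace_days`` after its onset.
    The denominator is total monitored time across ``records`` in years.
    """
    total_days = sum(r.monitored_days for r in records)
    if total_days <= 0:
        raise ValueError("zero follow-up time")
    by_id = {r.patient_id: r for r in records}
    n_false = 0
    for pid, (dates, flags) in alerts_by_patient.items():
        rec = by_id[pid]
        admissions = [e.admission_date for e in rec.hf_events()]
        for onset, _last in alert_episodes(dates, flags):
            horizon = onset + timedelta(days=grace_days)
            if not any(onset <= a <= horizon for a in admissions):
                n_false += 1
    return n_false / (total_days / 365.25)


def evaluate_guideline_rule(
    cohort,
    rule: GuidelineRule,
    pause_days: int = 7,
    min_per_week: int = 3,
    adherence_mode: str = "per_week",
) -> ConfusionCounts:
    """Score a fixed published weight rule over a cohort's 14-day periods.

    Unlike the threshold-sweep pipeline, a guideline rule is a fixed boolean
    alert (possibly an OR of clauses), so each eligible period is labeled
    directly by "any alert day inside the window".  Adherence and warmup
    eligibility rules match ``label_periods``; the rule's warmup is its
    longest clause lag (or MACD long window).
    """
    lags = [n for _, n in rule.clauses]
    if rule.macd is not None:
        lags.append(rule.macd[1] - 1)
    warmup = max(lags)
    tp = fp = tn = fn = 0
    for rec in cohort:
        series = rec.series.get(Modality.WEIGHT)
        if series is None or len(series) == 0:
            continue
        alert_days = set()
        index_days = set()
        for start, end, _ev in _monitoring_blocks(rec, pause_days):
            sub = series.window(start, end)
            if len(sub) < 2:
                continue
            dates, flags = guideline_alerts(prepare_series(sub), rule)
            index_days.update(dates)
            alert_days.update(d for d, f in zip(dates, flags) if f)
        for p in segment_periods(rec, pause_days):
            if not is_adherent(series, p.start, p.end, min_per_week, adherence_mode):
                continue
            if (
                p.block_start is not None
                and (p.start - p.block_start).days < warmup
            ):
                continue
            if not any(p.start <= d <= p.end for d in index_days):
                continue
            fired = any(p.start <= d <= p.end for d in alert_days)
            if p.is_event:
                tp += fired
                fn += not fired
            else:
                fp += fired
                tn += not fired
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def compare_period_means(values, labels, patient_ids, n_perm: int = 999,
                         seed: int = 0):
    """Pre-event vs other-period mean difference with patient random intercepts.

    Fits ``value ~ 1 + label`` as a linear mixed model with a random intercept
    per patient and returns ``(estimate, p_value)`` for the label effect
    (label 1 = 2-week pre-hospitalization period).  If the fit is singular or
    degenerate, falls back to a patient-aware permutation test on the mean
    difference, with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    patient_ids = np.asarray(patient_ids)
    if len(np.unique(patient_ids)) < 2:
        raise ValueError("need at least two patients")
    diff = values[labels == 1].mean() - values[labels == 0].mean()
    if np.allclose(values, values[0]):
        return 0.0, 1.0
    try:
        import statsmodels.api as sm

        exog = np.column_stack([np.ones_like(values), labels.astype(float)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(values, exog, groups=patient_ids)
            fit = model.fit(reml=True, method="lbfgs")
        est = float(fit.fe_params[1])
        p = float(fit.pvalues[1])
        if np.isfinite(est) and np.isfinite(p):
            return est, p
        raise ValueError("degenerate mixed-model fit")
    except Exception:
        warnings.warn(
            "mixed-model fit failed; using patient-cluster permutation test",
            stacklevel=2,
        )
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            if perm.sum() in (0, len(perm)):
                continue
            d = values[perm == 1].mean() - values[perm == 0].mean()
            if abs(d) >= abs(diff):
                count += 1
        return float(diff), (count + 1) / (n_perm + 1)
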