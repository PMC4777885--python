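"""Stratified leave-patient-out parameter optimization and pooled evaluation.

Patients are split into k groups balanced on patient and decompensation-event
counts.  For each fold, algorithm parameters are chosen on the other k−1
groups by maximizing the normalized partial area under the ROC curve at high
specificity (> 95% by default); the left-out group's output indices are then
scaled by the magnitude of the training set's operating (Youden) threshold
so out-of-fold peaks from folds that chose different parameters pool onto
one axis in which "1" is each fold's own alert boundary.  The recombined out-of-fold periods give an unbiased ROC, from
which a single operating threshold is chosen at the Youden point with
specificity above 90%.
"""

from __future__ import annotations

import dataclasses
from datetime import date
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from .algorithms import (
    CUSUMParams,
    MACDParams,
    OutputIndexSeries,
    RoTParams,
    compute_record_index,
)
from .data_model import Cohort, Modality, PatientRecord
from .evaluation import (
    ConfusionCounts,
    ROCCurve,
    confusion_at_threshold,
    false_alarm_rate,
    partial_auc,
    roc_curve,
    segment_periods,
    label_periods,
    youden_threshold,
)

__all__ = [
    "ParameterGrid",
    "FoldAssignment",
    "FoldResult",
    "CVResult",
    "default_parameter_grid",
    "fast_parameter_grid",
    "stratified_folds",
    "optimize_parameters",
    "robust_scale",
    "normalize_index",
    "cross_validate",
]


@dataclasses.dataclass(frozen=True)
class ParameterGrid:
    """Candidate parameter settings for one algorithm."""

    algorithm: str
    settings: tuple

    def __post_init__(self):
        if not self.settings:
            raise ValueError("empty parameter grid")


def default_parameter_grid(algorithm: str) -> ParameterGrid:
    """The full search grids: RoT d 1–21; MACD N_l 10–50 step 5 × N_s 1–10
    (N_s < N_l); CUSUM d 10–30 step 5 × c 0.5–1.5 step 0.2."""
    algorithm = algorithm.lower()
    if algorithm == "rot":
        settings = tuple(RoTParams(d) for d in range(1, 22))
    elif algorithm == "macd":
        settings = tuple(
            MACDParams(ns, nl)
            for nl in range(10, 51, 5)
            for ns in range(1, 11)
            if ns < nl
        )
    elif algorithm == "cusum":
        settings = tuple(
            CUSUMParams(d, round(c, 2))
            for d in range(10, 31, 5)
            for c in (0.5, 0.7, 0.9, 1.1, 1.3, 1.5)
        )
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return ParameterGrid(algorithm, settings)


def fast_parameter_grid(algorithm: str) -> ParameterGrid:
    """Reduced screening grids spanning the same parameter ranges; useful for
    simulation studies and smoke runs where the full grid is unnecessary."""
    algorithm = algorithm.lower()
    if algorithm == "rot":
        settings = (RoTParams(2), RoTParams(7), RoTParams(14), RoTParams(21))
    elif algorithm == "macd":
        settings = (
            MACDParams(3, 15),
            MACDParams(5, 20),
            MACDParams(9, 20),
            MACDParams(9, 35),
        )
    elif algorithm == "cusum":
        settings = (
            CUSUMParams(10, 0.75),
            CUSUMParams(10, 1.25),
            CUSUMParams(20, 0.75),
            CUSUMParams(20, 1.25),
        )
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return ParameterGrid(algorithm, settings)


@dataclasses.dataclass
class FoldAssignment:
    """Patient → fold mapping with per-fold bookkeeping."""

    folds: Dict[str, int]
    k: int

    def patients_in(self, fold: int) -> list:
        return [pid for pid, f in self.folds.items() if f == fold]

    def counts(self, cohort: Cohort):
        """(patients, HF events) per fold, indexed 0..k-1."""
        n_pat = [0] * self.k
        n_ev = [0] * self.k
        for rec in cohort:
            f = self.folds[rec.patient_id]
            n_pat[f] += 1
            n_ev[f] += len(rec.hf_events())
        return n_pat, n_ev


def stratified_folds(cohort: Cohort, k: int = 8, seed: int = 0) -> FoldAssignment:
    """Random k-fold split balancing patient and HF-event counts.

    Event-positive patients (sorted by event count, shuffled within) are dealt
    round-robin across a shuffled fold order; event-free patients then fill
    folds smallest-first.  Patient counts per fold differ by at most one and
    event counts are balanced best-effort.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(cohort) < k:
        raise ValueError("fewer patients than folds")
    rng = np.random.default_rng(seed)
    with_events = [r for r in cohort if r.hf_events()]
    without = [r for r in cohort if not r.hf_events()]
    with_events = [with_events[i] for i in rng.permutation(len(with_events))]
    with_events.sort(key=lambda r: -len(r.hf_events()))  # stable: shuffled within count
    without = [without[i] for i in rng.permutation(len(without))]
    fold_order = list(rng.permutation(k))
    folds: Dict[str, int] = {}
    sizes = [0] * k
    for i, rec in enumerate(with_events):
        f = fold_order[i % k]
        folds[rec.patient_id] = f
        sizes[f] += 1
    for rec in without:
        f = int(np.argmin(sizes))
        folds[rec.patient_id] = f
        sizes[f] += 1
    return FoldAssignment(folds, k)


def optimize_parameters(
    periods_factory: Callable,
    grid: ParameterGrid,
    direction: str,
    spec_min: float = 0.95,
):
    """Grid-search the setting maximizing normalized partial AUC.

    ``periods_factory(setting)`` must return the labeled training periods for
    that setting.  Ties break toward simpler settings (smaller windows).
    Raises if no setting yields both period classes (training folds without
    events — stratification should prevent this).
    """
    best_setting = None
    best_score = -np.inf
    best_complexity = np.inf
    any_valid = False
    for setting in sorted(grid.settings, key=lambda s: s.complexity()):
        periods = periods_factory(setting)
        labels = {p.is_event for p in periods}
        if labels != {True, False}:
            continue
        any_valid = True
        score = partial_auc(roc_curve(periods, direction), spec_min)
        if score > best_score + 1e-12:
            best_score = score
            best_setting = setting
            best_complexity = setting.complexity()
    if not any_valid:
        raise ValueError("no event periods in training folds")
    return best_setting, best_score


def robust_scale(values) -> float:
    """MAD × 1.4826 of the training output index, with degenerate fallbacks.

    When the median absolute deviation is exactly zero (e.g. a noiseless
    index that is zero outside prodromes), the standard deviation and then
    the maximum absolute value are used; an identically zero index has no
    scale and raises.
    """
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("no index values to scale")
    mad = float(np.median(np.abs(v - np.median(v))))
    scale = mad * 1.4826
    if scale == 0.0:
        scale = float(np.std(v))
    if scale == 0.0:
        scale = float(np.max(np.abs(v)))
    if scale == 0.0:
        raise ValueError("zero training scale: output index is identically zero")
    return scale


def normalize_index(values, scale: float) -> np.ndarray:
    """Divide index values by a positive training scale (direction preserved)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return np.asarray(values, dtype=float) / scale


@dataclasses.dataclass
class FoldResult:
    fold: int
    params: object
    train_partial_auc: float
    train_threshold: float
    scale: float
    n_test_periods: int
    n_test_events: int


@dataclasses.dataclass
class CVResult:
    """Pooled out-of-fold evaluation plus per-fold parameter stability."""

    algorithm: str
    modality: Modality
    direction: str
    assignment: FoldAssignment
    fold_results: list
    pooled_periods: list  # labeled periods with normalized peaks
    roc: ROCCurve
    threshold: float
    confusion: ConfusionCounts
    false_alarms_per_patient_year: float

    @property
    def sensitivity(self):
        return self.confusion.sensitivity

    @property
    def specificity(self):
        return self.confusion.specificity

    @property
    def ppv(self):
        return self.confusion.ppv

    @property
    def npv(self):
        return self.confusion.npv

    def parameter_table(self) -> dict:
        """Per-fold chosen parameters and training thresholds with mean/SD."""
        table: Dict[str, dict] = {}
        rows: Dict[str, list] = {}
        for fr in self.fold_results:
            for f in dataclasses.fields(fr.params):
                rows.setdefault(f.name, []).append(getattr(fr.params, f.name))
            rows.setdefault("threshold", []).append(fr.train_threshold)
        for name, vals in rows.items():
            arr = np.asarray(vals, dtype=float)
            table[name] = {
                "values": [float(x) for x in vals],
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            }
        return table

    def summary(self) -> dict:
        def pct(x):
            return None if x is None else 100.0 * x

        return {
            "algorithm": self.algorithm,
            "modality": self.modality.value,
            "threshold": self.threshold,
            "sensitivity_pct": pct(self.sensitivity),
            "specificity_pct": pct(self.specificity),
            "ppv_pct": pct(self.ppv),
            "npv_pct": pct(self.npv),
            "false_alarms_per_patient_year": self.false_alarms_per_patient_year,
            "n_eligible_events": self.confusion.tp + self.confusion.fn,
            "n_periods": len(self.pooled_periods),
            "parameters": self.parameter_table(),
        }


class _EvalContext:
    """Caches per-patient segmentation, indices and labeled periods.

    Segmentation is parameter-free, and a patient's index under a given
    setting does not depend on the fold split, so both are computed once per
    cohort and reused across folds and grid points.
    """

    def __init__(
        self,
        cohort: Cohort,
        modality: Modality,
        algorithm: str,
        pause_days: int = 7,
        min_per_week: int = 3,
        adherence_mode: str = "per_week",
    ):
        self.cohort = cohort
        self.modality = Modality(modality)
        self.algorithm = algorithm.lower()
        self.pause_days = pause_days
        self.min_per_week = min_per_week
        self.adherence_mode = adherence_mode
        self.records = {r.patient_id: r for r in cohort}
        self.periods = {
            r.patient_id: segment_periods(r, pause_days) for r in cohort
        }
        self._cache: Dict[object, dict] = {}

    def per_patient(self, setting) -> dict:
        """pid → (OutputIndexSeries, labeled periods) under ``setting``."""
        if setting not in self._cache:
            entry = {}
            for pid, rec in self.records.items():
                if self.modality not in rec.series:
                    continue
                idx = compute_record_index(
                    rec, self.modality, self.algorithm, setting,
                    pause_days=self.pause_days,
                )
                labeled = label_periods(
                    self.periods[pid], idx, rec,
                    self.min_per_week, self.adherence_mode,
                )
                entry[pid] = (idx, labeled)
            self._cache[setting] = entry
        return self._cache[setting]

    def labeled_for(self, setting, pids) -> list:
        entry = self.per_patient(setting)
        out = []
        for pid in pids:
            if pid in entry:
                out.extend(entry[pid][1])
        return out

    def index_values_for(self, setting, pids) -> np.ndarray:
        entry = self.per_patient(setting)
        chunks = [entry[pid][0].values for pid in pids if pid in entry]
        return np.concatenate(chunks) if chunks else np.array([])


def cross_validate(
    cohort: Cohort,
    algorithm: str,
    modality,
    grid: Optional[ParameterGrid] = None,
    k: int = 8,
    seed: int = 0,
    spec_min_opt: float = 0.95,
    spec_min_youden: float = 0.90,
    pause_days: int = 7,
    min_per_week: int = 3,
    adherence_mode: str = "per_week",
    grace_days: int = 14,
    max_redeals: int = 100,
) -> CVResult:
    """Stratified leave-patient-out evaluation of one algorithm/modality.

    Per fold: optimize parameters on the other folds (normalized partial AUC,
    specificity > ``spec_min_opt``), rescale the left-out patients' indices by
    the training robust scale, and collect their labeled periods.  The pooled
    periods give the unbiased ROC; the operating threshold is the Youden point
    with specificity > ``spec_min_youden``; false alarms are episodes of
    consecutive above-threshold days not followed by an HF admission within
    ``grace_days``.  A fold split leaving some training set without events is
    re-dealt with the next seed (up to ``max_redeals`` attempts).
    """
    modality = Modality(modality)
    if grid is None:
        grid = default_parameter_grid(algorithm)
    ctx = _EvalContext(cohort, modality, algorithm, pause_days,
                       min_per_week, adherence_mode)
    direction = modality.direction

    assignment = None
    for attempt in range(max_redeals):
        cand = stratified_folds(cohort, k, seed + attempt)
        ok = True
        for fold in range(k):
            train = [p for p in ctx.records if cand.folds[p] != fold]
            if not any(
                e.hf_adjudicated
                for pid in train
                for e in ctx.records[pid].hf_events()
            ):
                ok = False
                break
        if ok:
            assignment = cand
            break
    if assignment is None:
        raise ValueError("could not build folds with events in every training set")

    fold_results = []
    pooled = []
    alerts_input = {}  # pid -> (dates, normalized values) pending threshold
    for fold in range(k):
        train = [p for p in ctx.records if assignment.folds[p] != fold]
        test = [p for p in ctx.records if assignment.folds[p] == fold]
        best, best_pauc = optimize_parameters(
            lambda s: ctx.labeled_for(s, train), grid, direction, spec_min_opt
        )
        train_periods = ctx.labeled_for(best, train)
        train_thr = youden_threshold(
            roc_curve(train_periods, direction), spec_min_youden
        )
        # normalize by the fold's training operating point so out-of-fold
        # peaks from folds with different chosen parameters share one axis
        # (a raw-index MAD is unstable for the zero-inflated CUSUM output);
        # fall back to the robust index scale if the threshold degenerates
        scale = abs(train_thr)
        if not np.isfinite(scale) or scale == 0.0:
            scale = robust_scale(ctx.index_values_for(best, train))
        entry = ctx.per_patient(best)
        n_test_periods = n_test_events = 0
        for pid in test:
            if pid not in entry:
                continue
            idx, labeled = entry[pid]
            for p in labeled:
                pooled.append(
                    dataclasses.replace(p, peak_index=p.peak_index / scale)
                )
                n_test_periods += 1
                n_test_events += int(p.is_event)
            alerts_input[pid] = (idx.dates, normalize_index(idx.values, scale))
        fold_results.append(
            FoldResult(fold, best, best_pauc, train_thr, scale,
                       n_test_periods, n_test_events)
        )

    roc = roc_curve(pooled, direction)
    threshold = youden_threshold(roc, spec_min_youden)
    confusion = confusion_at_threshold(pooled, threshold, direction)
    alerts = {
        pid: (dates, vals > threshold if direction == "increase" else vals < threshold)
        for pid, (dates, vals) in alerts_input.items()
    }
    far = false_alarm_rate(alerts, list(cohort), grace_days)
    return CVResult(
        algorithm=algorithm.lower(),
        modality=modality,
        direction=direction,
        assignment=assignment,
        fold_results=fold_results,
        pooled_periods=pooled,
        roc=roc,
        threshold=threshold,
        confusion=confusion,
        false_alarms_per_patient_year=far,
    )
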