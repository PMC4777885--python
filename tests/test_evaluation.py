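import itertools
from datetime import date, timedelta

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from telealert import (
    CUSUMParams,
    EvaluationPeriod,
    HospitalizationEvent,
    MACDParams,
    Modality,
    PatientRecord,
    RoTParams,
    compare_period_means,
    compute_record_index,
    confusion_at_threshold,
    false_alarm_rate,
    label_periods,
    partial_auc,
    roc_curve,
    segment_periods,
    youden_threshold,
)
from telealert.evaluation import PERIOD_DAYS, alert_episodes

from conftest import D0, make_record, make_series


def _periods(peaks_pos, peaks_neg):
    out = []
    for i, v in enumerate(peaks_pos):
        out.append(
            EvaluationPeriod(
                "P1", D0 + timedelta(days=14 * i), D0 + timedelta(days=14 * i + 13),
                True, peak_index=float(v),
            )
        )
    for i, v in enumerate(peaks_neg):
        out.append(
            EvaluationPeriod(
                "P2", D0 + timedelta(days=14 * i), D0 + timedelta(days=14 * i + 13),
                False, peak_index=float(v),
            )
        )
    return out


class TestSegmentation:
    def test_28_day_record_no_events(self):
        periods = segment_periods(make_record(n_days=28, values=[80.0] * 28))
        assert len(periods) == 2
        assert all(not p.is_event for p in periods)
        assert periods[0].start == D0

    def test_backward_tiling_from_event(self):
        # event on day 20 of a record starting day 0: one event-ending period
        # spanning days 7..20; days 0..6 are discarded
        periods = segment_periods(make_record(n_days=40, event_days=[20]))
        ev = [p for p in periods if p.is_event]
        assert len(ev) == 1
        assert ev[0].start == D0 + timedelta(days=7)
        assert ev[0].end == D0 + timedelta(days=20)

    def test_short_record_yields_nothing(self):
        assert segment_periods(make_record(n_days=10, values=[80.0] * 10)) == []

    def test_non_hf_hospitalization_creates_no_event_period(self):
        rec = make_record(n_days=60, event_days=[])
        ev = HospitalizationEvent("P1", D0 + timedelta(days=30), False)
        rec = PatientRecord(
            rec.patient_id, rec.monitoring_start, rec.monitoring_end,
            rec.series, (ev,),
        )
        periods = segment_periods(rec)
        assert all(not p.is_event for p in periods)
        # the pause after the non-HF admission still splits the blocks
        assert all(
            p.end <= ev.admission_date or p.start >= ev.admission_date + timedelta(days=8)
            for p in periods
        )

    def test_day_conservation_over_random_event_placements(self, rng):
        """covered + discarded + pauses == monitored days, with the discarded
        and pause day counts recomputed by independent block bookkeeping."""
        for _ in range(40):
            n_days = int(rng.integers(20, 200))
            n_events = int(rng.integers(0, 4))
            days = sorted(rng.choice(n_days, size=n_events, replace=False)) if n_events else []
            # keep admissions out of each other's pauses
            filtered = []
            for d in days:
                if not filtered or d - filtered[-1] > 7:
                    filtered.append(int(d))
            rec = make_record(n_days=n_days, values=[80.0] * n_days, event_days=filtered)
            periods = segment_periods(rec)
            covered = PERIOD_DAYS * len(periods)
            # independent bookkeeping
            starts, pause = [0], 0
            blocks = []
            s = 0
            for d in filtered:
                blocks.append(d - s + 1)
                pause += min(n_days - 1, d + 7) - d
                s = d + 8
            if s <= n_days - 1:
                blocks.append(n_days - s)
            discarded = sum(b % PERIOD_DAYS for b in blocks)
            assert covered + discarded + pause == n_days

    def test_one_event_period_per_eligible_event(self, rng):
        for _ in range(20):
            n_days = int(rng.integers(40, 300))
            d1 = int(rng.integers(0, n_days))
            rec = make_record(n_days=n_days, values=[80.0] * n_days, event_days=[d1])
            ev_periods = [p for p in segment_periods(rec) if p.is_event]
            assert len(ev_periods) == (1 if d1 >= 13 else 0)
            if ev_periods:
                assert ev_periods[0].end == D0 + timedelta(days=d1)


class TestLabeling:
    def test_inadherent_event_period_excluded(self):
        # only 2 observed weights in the first week of the event window
        obs_days = [0, 1, 2, 3, 4, 5, 6, 7, 10, 14, 15, 16, 17, 18, 19, 20]
        rec = make_record(
            values=[80.0] * len(obs_days), dates=obs_days, n_days=21, event_days=[20]
        )
        idx = compute_record_index(rec, Modality.WEIGHT, "rot", RoTParams(1))
        labeled = label_periods(segment_periods(rec), idx, rec)
        assert all(not p.is_event for p in labeled)

    def test_fully_adherent_cohort_loses_only_warmup_window(self):
        # with full adherence the only exclusion left is the block's first
        # window, where the algorithm has no pre-window baseline yet
        rec = make_record(n_days=70, values=[80.0] * 70)
        idx = compute_record_index(rec, Modality.WEIGHT, "rot", RoTParams(1))
        labeled = label_periods(segment_periods(rec), idx, rec)
        assert len(segment_periods(rec)) == 5
        assert len(labeled) == 4
        assert min(p.start for p in labeled) == D0 + timedelta(days=14)

    def test_warmup_makes_early_event_ineligible(self):
        # CUSUM with a 20-day window cannot judge an event 20 days into
        # monitoring; the event is excluded, not counted as a false negative
        rec = make_record(n_days=120, values=[80.0] * 120, event_days=[20])
        idx = compute_record_index(rec, Modality.WEIGHT, "cusum", CUSUMParams(20, 0.75))
        labeled = label_periods(segment_periods(rec), idx, rec)
        assert all(not p.is_event for p in labeled)
        short = compute_record_index(rec, Modality.WEIGHT, "rot", RoTParams(2))
        assert any(p.is_event for p in label_periods(segment_periods(rec), short, rec))


class TestConfusion:
    def test_all_below_threshold(self):
        cc = confusion_at_threshold(_periods([1.0, 2.0], [0.5]), 5.0, "increase")
        assert (cc.tp, cc.fp, cc.tn, cc.fn) == (0, 0, 1, 2)
        assert cc.specificity == 1.0 and cc.ppv is None

    def test_threshold_minus_infinity(self):
        cc = confusion_at_threshold(_periods([1.0], [0.5, 0.2]), -np.inf, "increase")
        assert cc.sensitivity == 1.0 and cc.specificity == 0.0

    def test_counts_match_bruteforce(self, rng):
        for _ in range(20):
            pos = rng.normal(1, 1, int(rng.integers(1, 8)))
            neg = rng.normal(0, 1, int(rng.integers(1, 15)))
            thr = float(rng.normal(0.5, 1))
            direction = "increase" if rng.random() < 0.5 else "decrease"
            cc = confusion_at_threshold(_periods(pos, neg), thr, direction)
            fire = (lambda v: v > thr) if direction == "increase" else (lambda v: v < thr)
            assert cc.tp == sum(fire(v) for v in pos)
            assert cc.fp == sum(fire(v) for v in neg)
            assert cc.tp + cc.fn == len(pos)
            assert cc.fp + cc.tn == len(neg)


class TestROC:
    def test_perfect_separation(self):
        roc = roc_curve(_periods([3.0, 4.0], [0.0, 1.0]), "increase")
        assert partial_auc(roc, 0.0) == pytest.approx(1.0)
        assert partial_auc(roc, 0.95) == pytest.approx(1.0)

    def test_identical_scores_give_chance(self):
        roc = roc_curve(_periods([1.0, 1.0], [1.0, 1.0]), "increase")
        assert partial_auc(roc, 0.0) == pytest.approx(0.5)

    def test_endpoints_present(self, rng):
        roc = roc_curve(_periods(rng.normal(1, 1, 5), rng.normal(0, 1, 9)), "decrease")
        assert (roc.sensitivity[0], roc.specificity[0]) == (0.0, 1.0)
        assert (roc.sensitivity[-1], roc.specificity[-1]) == (1.0, 0.0)
        assert np.all(np.diff(roc.sensitivity) >= 0)

    @pytest.mark.parametrize("direction", ["increase", "decrease"])
    def test_full_auc_matches_sklearn(self, rng, direction):
        for _ in range(10):
            pos = rng.normal(0.8, 1, int(rng.integers(2, 10)))
            neg = rng.normal(0, 1, int(rng.integers(2, 20)))
            roc = roc_curve(_periods(pos, neg), direction)
            scores = np.r_[pos, neg] if direction == "increase" else -np.r_[pos, neg]
            labels = np.r_[np.ones_like(pos), np.zeros_like(neg)]
            assert partial_auc(roc, 0.0) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_youden_matches_exhaustive_enumeration(self, rng):
        """Constrained Youden point agrees with a brute-force sweep over all
        candidate thresholds, and every ROC point is realized exactly by
        confusion_at_threshold (threshold semantics are consistent)."""
        for _ in range(30):
            pos = np.round(rng.normal(0.8, 1, int(rng.integers(1, 8))), 1)
            neg = np.round(rng.normal(0, 1, int(rng.integers(2, 15))), 1)
            periods = _periods(pos, neg)
            spec_min = float(rng.choice([0.0, 0.5, 0.9]))
            roc = roc_curve(periods, "increase")
            # each curve point must be reproducible at its threshold
            for t, se, sp in zip(roc.thresholds, roc.sensitivity, roc.specificity):
                cc = confusion_at_threshold(periods, t, "increase")
                assert cc.sensitivity == pytest.approx(se)
                assert cc.specificity == pytest.approx(sp)
            thr = youden_threshold(roc, spec_min)
            cc = confusion_at_threshold(periods, thr, "increase")
            got_j = cc.sensitivity + cc.specificity - 1
            # brute force over a dense candidate set
            cands = np.r_[np.unique(np.r_[pos, neg]) - 1e-9, np.inf]
            best = -np.inf
            for t in cands:
                c = confusion_at_threshold(periods, t, "increase")
                if c.specificity > spec_min:
                    best = max(best, c.sensitivity + c.specificity - 1)
            assert got_j == pytest.approx(best, abs=1e-12)


class TestFalseAlarms:
    def test_no_alerts(self):
        rec = make_record(n_days=365, values=[80.0] * 365)
        rate = false_alarm_rate({"P1": ((), ())}, [rec])
        assert rate == 0.0

    def test_two_false_episodes_over_four_patient_years(self):
        recs = [
            make_record(n_days=731, values=[80.0] * 731, pid=f"P{i}") for i in (1, 2)
        ]
        dates = (D0 + timedelta(days=10), D0 + timedelta(days=11),
                 D0 + timedelta(days=100))
        rate = false_alarm_rate({"P1": (dates, np.array([True, True, True]))}, recs)
        assert rate == pytest.approx(2 / (2 * 731 / 365.25))

    def test_five_week_alert_is_one_episode_but_three_window_fps(self):
        n = 140
        rec = make_record(n_days=n, values=[80.0] * n)
        dates = tuple(D0 + timedelta(days=42 + i) for i in range(35))
        flags = np.ones(35, dtype=bool)
        assert len(alert_episodes(dates, flags)) == 1
        rate = false_alarm_rate({"P1": (dates, flags)}, [rec])
        assert rate == pytest.approx(1 / (n / 365.25))
        # the same alert seen through 14-day windows counts up to 3 FPs
        assert sum(
            1 for p in segment_periods(rec)
            if any(p.start <= d <= p.end for d in dates)
        ) == 3

    def test_episode_followed_by_admission_is_not_false(self):
        rec = make_record(n_days=120, values=[80.0] * 120, event_days=[60])
        dates = (D0 + timedelta(days=50),)
        rate = false_alarm_rate({"P1": (dates, np.array([True]))}, [rec])
        assert rate == 0.0

    def test_zero_followup_rejected(self):
        with pytest.raises(ValueError):
            false_alarm_rate({}, [])


@pytest.fixture(scope="module")
def cohort():
    from telealert import CohortConfig, generate_cohort

    return generate_cohort(
        CohortConfig(n_patients=16, monitoring_days_mean=150,
                     event_hazard=4e-3, seed=8)
    )


class TestGuidelineEvaluation:
    def test_all_presets_produce_consistent_confusion_tables(self, cohort):
        """Table-style evaluation of every published weight rule runs and
        respects the predictive-value identities PPV*(TP+FP) = TP and
        NPV*(TN+FN) = TN."""
        from telealert import GUIDELINE_PRESETS, evaluate_guideline_rule

        assert cohort.n_events() > 0
        for name, rule in GUIDELINE_PRESETS.items():
            cc = evaluate_guideline_rule(cohort, rule)
            assert cc.tp + cc.fp + cc.tn + cc.fn > 0, name
            if cc.ppv is not None:
                assert cc.ppv * (cc.tp + cc.fp) == pytest.approx(cc.tp)
            if cc.npv is not None:
                assert cc.npv * (cc.tn + cc.fn) == pytest.approx(cc.tn)

    def test_flat_cohort_perfect_specificity(self):
        from telealert import Cohort, GUIDELINE_PRESETS, evaluate_guideline_rule

        rec = make_record(n_days=120, values=[80.0] * 120)
        cc = evaluate_guideline_rule(Cohort((rec,)), GUIDELINE_PRESETS["esc_2kg_3d"])
        assert cc.fp == 0 and cc.tp == 0 and cc.tn > 0


def test_nitti_cusum_alert_precedes_weight_macd_alert():
    """On a two-modality record with a default injected prodrome, the
    impedance CUSUM detector (falling log-NITTI) fires before the weight
    MACD detector at their published operating thresholds — impedance
    gives the earlier warning."""
    import numpy as np
    from telealert import (
        MeasurementSeries, PatientRecord, compute_record_index, inject_event,
        threshold_alerts,
    )
    from telealert.algorithms import OPTIMAL_PRESETS

    rng = np.random.default_rng(5)
    n = 100
    dates = tuple(D0 + timedelta(days=i) for i in range(n))
    rec = PatientRecord(
        "P1", D0, dates[-1],
        {
            Modality.WEIGHT: MeasurementSeries(
                "P1", Modality.WEIGHT, dates, tuple(80 + rng.normal(0, 0.3, n))
            ),
            Modality.NITTI: MeasurementSeries(
                "P1", Modality.NITTI, dates, tuple(3.4 + rng.normal(0, 0.03, n))
            ),
        },
    )
    rec = inject_event(rec, D0 + timedelta(days=80))
    firsts = {}
    for key, modality, algo in (
        ("nitti_cusum", Modality.NITTI, "cusum"),
        ("weight_macd", Modality.WEIGHT, "macd"),
    ):
        idx = compute_record_index(
            rec, modality, algo, OPTIMAL_PRESETS[key]["params"]
        )
        d, f = threshold_alerts(idx, OPTIMAL_PRESETS[key]["threshold"])
        fired = [x for x, flag in zip(d, f) if flag]
        assert fired, key
        firsts[key] = fired[0]
    admission = D0 + timedelta(days=80)
    assert firsts["nitti_cusum"] < firsts["weight_macd"] <= admission


class TestPeriodMeans:
    def test_identical_values_give_zero_estimate(self):
        est, _ = compare_period_means(
            [3.4] * 20, [0, 1] * 10, [f"P{i % 4}" for i in range(20)]
        )
        assert est == 0.0

    def test_recovers_injected_shift(self, rng):
        n_pat, per = 40, 8
        pids, vals, labels = [], [], []
        for i in range(n_pat):
            b = rng.normal(3.4, 0.3)
            for j in range(per):
                lab = int(j == 0 and i < 12)
                vals.append(b + rng.normal(0, 0.1) - 0.4 * lab)
                labels.append(lab)
                pids.append(f"P{i}")
        est, p = compare_period_means(vals, labels, pids)
        assert est == pytest.approx(-0.4, abs=0.12)
        assert p < 0.001
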