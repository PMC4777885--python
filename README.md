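# telealert

Evaluation framework for alert algorithms that detect decompensating heart
failure from daily home telemonitoring of **body weight** and **noninvasive
transthoracic bio-impedance** (NITTI, stored as log-ohm — thoracic fluid
accumulation *raises* weight and *lowers* impedance).

It is aimed at researchers and telehealth engineers who need to answer, on
longitudinal daily-measurement cohorts: *which trend-detection rule, at which
parameters and threshold, best anticipates hospitalization — and at what
false-alarm cost?*

## What it implements

**Output-index algorithms** (`telealert.algorithms`), each mapping a gap-imputed
daily series x_t to a scalar index with an alert on threshold crossing:

- **RoT** (rule of thumb): `RoT_t = x_t − x_{t−d}` — the simple difference
  behind published weight-gain rules ("> 2 kg in 3 days", ...). All 13
  guideline/literature presets ship, pounds converted at 0.45 kg/lb.
- **MACD**: `MACD_t = SMA_{N_s}(x)_t − SMA_{N_l}(x)_t`, short minus long
  trailing simple moving average — a smooth bidirectional trend follower.
- **CUSUM**: with trailing mean/SD μ_t, σ_t over the previous *d* days and
  z_t = (x_t − μ_t)/σ_t, the one-sided sum `S_t = min(0, S_{t−1} + z_t + c)`
  (falling signals; mirrored for rising) accumulates sustained drift beyond
  the allowance *c*.

**Evaluation** (`telealert.evaluation`): monitoring time is tiled into 14-day
periods such that a period containing a decompensation ends on the admission
day; an alert inside the two weeks preceding admission is a true positive,
any other alert a false positive. Periods with < 3 observed measurements in
either week are excluded. ROC curves sweep per-period peak indices; partial
AUC is restricted to high specificity; the operating threshold is the Youden
point with specificity > 90%. A mixed-effects model (patient random
intercepts) compares pre-event and other-period means, and an episode-based
**false alarms per patient-year** metric quantifies alert burden.

**Cross-validation** (`telealert.cross_validation`): 8-fold leave-patient-out,
stratified on patients *and* events; parameters optimized per fold by partial
AUC (specificity > 95%), out-of-fold indices normalized by the training
robust scale, folds recombined into one unbiased ROC.

**Synthetic cohorts** (`telealert.synthetic`): a generator emulating such a
study — 91 patients, ~300 days each, baselines N(84, 19²) kg and
N(3.4, 0.3²) log-ohm, 80% daily adherence, event hazard giving ~24
hospitalizations, and linear pre-event prodromes (weight +2.5 kg, NITTI
−0.4 log-ohm over 14 days).

## Worked example

```python
import telealert as ta

cohort = ta.generate_cohort(ta.CohortConfig(seed=2))      # 91 synthetic patients
print(len(cohort), cohort.n_events())                     # 91 23

res = ta.cross_validate(cohort, "cusum", ta.Modality.NITTI,
                        grid=ta.fast_parameter_grid("cusum"), seed=2)
print(f"sens {100*res.sensitivity:.0f}%  spec {100*res.specificity:.1f}%  "
      f"thr {res.threshold:.2f}  false alarms/py {res.false_alarms_per_patient_year:.2f}")
# sens 100%  spec 99.9%  thr -0.88  false alarms/py 0.04
```

Reading: pooling the 8 held-out folds, the NITTI-CUSUM detector caught all
of the eligible decompensation windows at 99.9% specificity. Out-of-fold
indices are normalized so 1 marks each training fold's own alert boundary,
hence the pooled operating threshold of −0.88 ≈ −1; above-threshold episodes
not followed by a hospitalization within 14 days were essentially absent
(0.04 per patient-year). (The
synthetic prodromes are cleaner than real patient data, so absolute numbers
are optimistic; the framework's value is in comparing algorithms under
identical conditions.)

Per-fold parameter stability is in `res.parameter_table()` (per-fold values,
mean, SD), and `res.summary()` gives a JSON-ready report.

The same pipeline is scriptable from the shell:

```bash
telealert simulate --seed 2 --out cohort/
telealert cv --measurements cohort/measurements.csv --events cohort/events.csv \
             --monitoring cohort/monitoring.csv --algo cusum --modality nitti --seed 2
```

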