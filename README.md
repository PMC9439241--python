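# hrvdecay

Heart-rate variability (HRV) collapses as the heart speeds up during
exercise. `hrvdecay` implements an analysis pipeline that quantifies that
collapse from nothing but beat-to-beat cardiac intervals recorded during a
graded exercise test (GET), and relates the resulting per-subject decay
constant to cardiorespiratory fitness. It is aimed at exercise
physiologists and biosignal analysts working with RR-interval series from
ECG, Holter or chest-strap recordings.

## The model

Given a cleaned RR series (ms), the slow workload-driven trend is removed
with a first-order dynamical model driven by the pedalling power *P(t)*:

    rr'(t) = c0 + c1·rr(t) + c2·P(t),        c1 < 0

whose physical parameters are the time constant −1/c1 (s), the steady-state
gain c2/c1 (ms of RR drop per W) and the baseline −c0/c1 (resting RR).
HRV is then the standard deviation of the detrended residuals (SDRR) in
successive one-minute windows, aligned with the protocol's power steps.
Windowed SDRR follows an exponential decay of the mean heart rate HR (with
HR = 60000/RR in beats/min):

    SDRR_j = b · 2^(−HR_j / τ)

where τ (beats/min) is the *HRV halving constant* — the HR increase that
divides SDRR by two — and b (ms) the intercept at a hypothetical HR of
zero. Competing parameterisations using workload (W) or work intensity
(%VO₂max) as the predictor are fit the same way and compared by AIC/BIC;
the HR-based model wins because it also describes the unloaded pre-effort
and recovery phases. Per-subject τ is finally correlated (Pearson and
rank) with fitness indices: VO₂max, maximal aerobic power (MAP),
ventilatory-threshold powers (PVT1/PVT2), peak HR, heart-rate recovery.

Because no machine-readable cohort is distributed, a first-class synthetic
generator produces GET datasets with the same statistical anatomy —
stepwise 15 W/min protocol, first-order RR kinetics, heteroscedastic
HRV noise obeying the decay law above, VO₂ kinetics, electrode-artifact
contamination, and a tunable coupling between the per-subject decay
constant and fitness — so every stage of the analysis is testable against
known ground truth.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
simulated cohort and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_clean_and_detrend.py
python analysis/03_model_comparison.py
```

Output of `01_simulate_cohort.py` (18 subjects, seed 1):

```
subjects: 18  (seed 1, artifacts at calibration rates)
beats per test  median [IQR]: 2744 [2620, 2814]
VO2max (mL/kg/min) median [IQR]: 36.3 [34.2, 39.1]
MAP (W)            median [IQR]: 237.5 [230.0, 260.0]
peak HR (bpm)      median [IQR]: 186.7 [184.1, 188.6]
```

`02_clean_and_detrend.py` reports that the three cleaning rules removed
~0.57 % of beats in total and that the ODE trend explains the RR series
with a median R² of 0.927, yielding a median of 24 one-minute windows per
subject. `03_model_comparison.py` then prints:

```
model comparison (lower AIC/BIC is better):
 model effort_range    aic    bic  rank
     1         full 2738.1 2750.3     1
     3         full 3115.5 3127.7     2
     2         full 3436.8 3449.0     3
     1       effort 1525.3 1536.3     1
     3       effort 1822.4 1833.4     2
     2       effort 2006.5 2017.5     3

pooled HR-decay fit: b = 1196 ms, tau = 20.27 beats/min
  (SDRR halves every 20.3 beats/min; division over +20 bpm: 1.98)
```

The HR-based model (model 1) attains the lowest AIC and BIC on both the
whole test and the effort phase alone, and the pooled fit says this
cohort's SDRR halves roughly every 20 beats/min of HR increase — i.e. the
fitted curve divides SDRR by ~2 across a +20 beats/min step.
`04_fitness_correlations.py` and `05_sensitivity_grid.py` continue with
the per-subject correlation table and the 147-cell detrending-robustness
grid; `06_pipeline_fidelity.py` repeats the whole chain over replicate
cohorts and compares the recovered decay parameters with the generator's
documented defaults (τ = 19.6 beats/min, b = 1325 ms).

A `hrvdecay` command-line interface exposes the same stages for external
CSV data (`simulate`, `clean`, `detrend`, `windows`, `fit`, `cohort`,
`sensitivity`, `run-all`); see `hrvdecay --help`.

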