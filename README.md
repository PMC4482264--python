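# platetrace

Analysis of **time-resolved (on-line) multi-well cell-culture assays**: the
kind of data produced when a sensor plate — for example a 24-well dish with
an optical dissolved-oxygen spot in every well — is read out every few
minutes for days while cells grow, are treated with a drug, and respond.

Such experiments replace arbitrary end-point read-outs with full kinetics,
but the resulting tables (hundreds of time points × dozens of wells) need
analysis steps that spreadsheets handle poorly. `platetrace` provides them
as a tested library and CLI:

- **Two-step logarithmic sensor correction** for sensors whose calibration
  curve is exponential, `x = P + S·e^(αy)` (plateau `P`, span `S`).
  Per-sensor miscalibration acts as a multiplicative gain in the log domain
  `z = ln((x − P)/S)`; over a calibration window with a stable common true
  value, each sensor's log-domain mean `m_s` and the plate mean `m_p` give
  the recalibration `x' = P + S·exp((m_p/m_s)·z)` (step 1), after which each
  sensor is scaled so its window mean equals a known target (step 2). The
  classical divide-by-control correction is only exact for *linear*
  calibrations; the logarithmic form is exact for exponential ones.
- **Reference normalization**: every value is divided by the time-matched
  mean `m_t` of designated control wells and multiplied by a target `M`,
  so controls become flat lines at `M`.
- **Replicate aggregation** (mean and sample SD per time point),
  **moving-average smoothing** (centered, odd window `n`, losing
  `(n−1)/2` points per end) and **moving-window slope**: an ordinary
  least-squares line through each point and `n` neighbours per side, with
  the residual standard error of each local fit.
- **Time-resolved IC50/EC50**: the log-logistic dose-response family

  `f(x) = c + (d − c) / (1 + (x/e)^b)^g`

  (LL2/LL3/LL4/LL5, with `e` the IC50) is fitted at *every* selected time
  point, tracing `e(t)` — how a drug's half-maximal concentration evolves
  with exposure time — instead of a single end-point IC50.
- A **synthetic-plate generator** that emulates the whole experiment
  (per-sensor gains, reader noise, seeding dip, medium change, a
  dose–death law with programmed `e(t)`), so every stage is testable
  against a known ground truth without any external data.

## Worked example

```python
from platetrace import (SimConfig, simulate_treatment_experiment, correct_sensors,
                        normalize_to_reference, fit_ic50_over_time, true_ic50)

cfg = SimConfig(seed=0)                      # 13 doses x 3 + 3 medium wells
table, layout = simulate_treatment_experiment(cfg)
corrected, factors = correct_sensors(table, cfg.calibration(), target=91.3)
normalized = normalize_to_reference(corrected, layout, target=91.3)
traj, fits = fit_ic50_over_time(normalized, layout, family="LL4",
                                time_window=(2.5, 4.7), stride=30)
print(f"correction factors span [{factors.factors.min():.4f}, {factors.factors.max():.4f}]")
for t, e, se in zip(traj.time, traj.e, traj.se):
    print(f"day {t:4.2f}: IC50 = {e:5.1f} ± {se:.1f} uM   (true {float(true_ic50(cfg, t)):5.1f})")
```

prints

```
correction factors span [0.9556, 1.0557]
day 2.50: IC50 =  78.6 ± 0.8 uM   (true  79.9)
day 2.71: IC50 =  73.6 ± 0.4 uM   (true  72.8)
day 2.92: IC50 =  66.7 ± 0.3 uM   (true  66.3)
day 3.13: IC50 =  60.8 ± 0.4 uM   (true  60.5)
day 3.34: IC50 =  55.5 ± 0.4 uM   (true  55.1)
day 3.55: IC50 =  50.8 ± 0.4 uM   (true  50.2)
day 3.75: IC50 =  45.3 ± 0.3 uM   (true  45.7)
day 3.96: IC50 =  41.7 ± 0.3 uM   (true  41.7)
day 4.17: IC50 =  38.0 ± 0.3 uM   (true  38.0)
day 4.38: IC50 =  34.5 ± 0.3 uM   (true  34.6)
day 4.59: IC50 =  31.2 ± 0.2 uM   (true  31.6)
```

The simulated plate carries per-sensor gains up to ±5% and 0.3% a.s. of
reader noise; after correction, normalization and per-time-point LL4
fitting, the fitted IC50 trajectory tracks the programmed decay from
80 μM to 30 μM to within a fraction of a μM, with honest per-fit standard
errors.

The same chain is available from the shell:

```sh
platetrace simulate experiment --seed 0 -o demo
platetrace correct demo_experiment.csv --plateau 1 --span 2 \
    --window 0:0.094 --target 91.3 -o corrected.csv
platetrace normalize corrected.csv --layout demo_layout.yaml --target 91.3 -o norm.csv
platetrace ic50 norm.csv --layout demo_layout.yaml --window 2.5:4.7 -o traj.csv
```

or settings-driven (`platetrace run settings.yaml`), which writes every
stage's CSV, plots and the resolved settings to a fresh run directory.

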