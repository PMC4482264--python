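# Methods

This note documents the statistical models and procedures implemented in
`platetrace`, the parameter choices that matter, what the synthetic-data
generator does and does not emulate, and the package's numerical
conventions.

## Sensor model and two-step correction

Optical sensors read out through luminescence quenching often have a
nonlinear calibration between the measured quantity `y` (e.g. dissolved
oxygen in % air saturation) and the raw signal. `platetrace` assumes an
**exponential calibration**, `x = P + S·e^(αy)`, with plateau `P` and span
`S` in measurement units and exponent factor `α`. For correction purposes
`α` cancels and only `P` and `S` are needed; both are required
configuration inputs (`estimate_calibration` can fit all three from
read-outs at ≥3 known levels, profiling `α` on a grid — linear in `(P, S)`
for fixed `α` — before a full nonlinear polish; near-linear data triggers a
degeneracy warning instead of a meaningless `α̂`).

Per-sensor miscalibration is modelled as a multiplicative **gain in the log
domain** `z = ln((x − P)/S)`: sensor `s` reports `z_s = g_s·z_true`. Over a
calibration window where all sensors share a stable true value, the
per-sensor mean `m_s` of `z` and the plate mean `m_p = mean(m_s)` give

- step 1 (logarithmic recalibration): `x' = P + S·exp((m_p/m_s)·z)`, which
  maps all sensors onto the common gain `mean(g)` — exactly, when the gain
  model holds and noise is zero;
- step 2 (linear normalization): each sensor is multiplied by
  `target / (its recalibrated window mean)`, pinning the window mean to the
  known true value. Step 2 is per-sensor and multiplicative; it must follow
  step 1.

Values at or below the plateau make the log transform undefined; the
default is a hard error enumerating the offending (time, sensor) cells,
with an opt-in `clip_epsilon` that clips `(x − P)/S` for exploratory use.
Correction factors are computed once from the window and applied to all
time points (time-invariant gain); no drift correction is attempted. The
calibration window is user-specified; the implementation requires ≥2
window time points, and ≥10 is recommended practice (with noisy data, more
window points directly shrink the residual per-sensor bias of the
correction — the bundled simulator uses a 136-point window at a 1-minute
read-out interval, mirroring common practice of calibrating at a finer
interval than the experiment proper).

## Reference normalization, aggregation, smoothing, slope

- **Reference normalization**: `x'_{t,c} = x_{t,c} / m_t · M` with `m_t`
  the mean of the reference (or medium-control) columns at time `t`. The
  reference mean becomes exactly `M` at every time point; the operation is
  idempotent. `m_t = 0` is an error naming the time point.
- **Aggregation**: per replicate group, per time point, mean and *sample*
  SD (divisor `n−1`; the divisor is a convention choice). Missing values
  are excluded pairwise; singleton groups get SD 0 and are flagged.
- **Smoothing**: centered moving average over an odd window `n ≥ 3`;
  `(n−1)/2` points are dropped at each end (no padding or reflection —
  edge values are simply lost, and downstream stages see the shorter
  series).
- **Windowed slope**: at each interior point, an OLS line through the
  point and `n` points per side (`2n+1` total), using the actual time
  stamps, so irregular spacing is handled correctly. Output: slope (value
  unit per time unit) and the local fit's residual standard error
  `sqrt(SSE/(2n+1−2))`. A half-width convention is used throughout: "slope
  with n = 15" means a 31-point window.

## Log-logistic dose-response family and the time-resolved IC50

The family is `f(x) = c + (d−c)/(1 + (x/e)^b)^g` with slope `b`, lower
limit `c`, upper limit `d`, inflection `e` (= IC50/EC50) and asymmetry `g`.
LL2 fixes `c=0, d=1, g=1`; LL3 fixes `c=0, g=1`; LL4 fixes `g=1`; LL5 is
free. This algebraic form is total on `x ≥ 0`: the zero dose enters as the
limit (`d` for `b>0`, `c` for `b<0`), so untreated wells are fitted without
ever taking `log(0)`.

Fitting is nonlinear least squares (`scipy.optimize.least_squares`, trf)
in the internal parameterization `(b, c, Δ = d−c ≥ 0, log(e/e₀))`, which
enforces `d ≥ c` and `e > 0` and makes the whole optimization invariant
under a joint rescaling of doses — the fitted `e` scales exactly with the
dose unit. Initialization: `c₀ = min` response, `d₀ = max` response,
`e₀` = the dose whose response is nearest `(c₀+d₀)/2`, `b₀ = ±1` by the
response trend; all overridable. Bounds: `|b| ≤ 50`, `e ∈ [10⁻⁶·e₀,
10·max dose]`, `g ∈ [10⁻³, 10³]`; tolerances 10⁻⁸, ≤1000 iterations.
Standard errors come from the Jacobian at the optimum
(`σ̂²(JᵀJ)⁻¹`, delta-method transform to the external parameters). Fits
never raise on bad data: non-convergence and degeneracy (no dose effect)
are flagged so a trajectory of fits continues past a bad time point. Fits
are unweighted and, by default, run on replicate-mean responses (a flag
fits every replicate point).

The **time-resolved IC50** fits the chosen family at every selected time
point (time window + stride) and traces `e(t)` with its per-fit SE; failed
fits become gaps.

## Synthetic-data generator

The generator produces plates with exactly the error structure the
correction inverts and a dose-response surface whose truth is known:

- per-sensor gains `g_s ~ U(1−δ, 1+δ)` in the log domain (default
  δ = 0.05), additive Gaussian reader noise after the calibration map
  (default SD 0.3% a.s.), calibration constants `P = 1.0`, `S = 2.0`
  (% a.s.), all levels kept well above `P`;
- an empty-plate protocol stepping through constant setpoints
  (91.3, 72.1, 48.1, 24.0, 4.8% a.s. by default, equal-length segments);
- a treatment experiment: 24-well-style plate with 13 doses
  (300…10, 0 μM) in triplicate plus 3 medium-only wells (42 columns);
  1-minute read-out for the 136-minute empty-plate calibration segment,
  then 10-minute intervals to day 5; seeding dip, partial medium-change
  recovery at day 1.09, treatment at day 2.1; medium wells drift upward
  at 0.5% a.s./day from seeding. Per sample well the true oxygen is
  `ambient − depth(t)·v(t, dose)` with viable fraction
  `v = 1/(1+(dose/e(t))^b)`, `b = 2`, and `e(t)` decaying exponentially
  from 80 μM at day 2.5 to 30 μM at day 4.7 — so at any fixed time the
  replicate-mean response is *exactly* LL4 in dose with inflection `e(t)`,
  and closure tests have a sharp truth.

Every generator is a pure function of its configuration: the same seed
yields bit-identical tables.

**What passing closure tests do and do not show.** The generator's
dose-response surface is exactly log-logistic, its gain model is exactly
the one the correction inverts, and its noise is i.i.d. Gaussian. Passing
therefore demonstrates correctness of the estimators and their
composition, not robustness to model misspecification in real plates
(attachment artefacts, drifting gains, non-exponential calibration,
heteroscedastic noise, outlier wells). Those must be judged per
experiment; the exclusion role in the plate layout and the honest per-fit
convergence flags are the tools provided.

## Numerical conventions and edge cases

- Time-unit conversion uses exact rational ratios; a convert/invert round
  trip is reproducible to 1 ulp (bitwise identity is not attainable in
  float64 for ratios that are not powers of two).
- Trimming uses a closed interval on the time axis; time shifts may
  produce negative times (pre-treatment baseline).
- CSV I/O round-trips values at full float precision
  (`float_precision="round_trip"` on read); non-numeric cells become
  missing values and propagate pairwise-excluded through means, SDs and
  fits; duplicate column names and non-monotone time vectors are hard
  errors naming the offence.
- Multiple input files merge column-wise only if their time vectors agree
  within 10⁻⁹ (input units).
- Windows with fewer than 2 (slope) or 3 (residual) valid points yield
  missing outputs rather than errors.
- The pipeline driver validates stage order before computing (slope
  requires smoothing; the IC50 stage requires aggregation unless
  replicate-point fitting is chosen) and writes each run to a fresh
  directory.

## Test problem sizes

The bundled end-to-end checks run a full 42-column plate at the default
842-point grid with ~317 per-time-point fits (a few seconds), plus
per-estimator oracle comparisons (brute-force OLS per window, hand-derived
closed forms) at 3–50-point sizes. The noisy closure test uses reader
noise of 0.2% a.s. — 0.5% of the ~40% a.s. dose-response range — and
checks the recovered trajectory against the programmed truth within 3
per-fit SEs at every time point.

## Known limitations

- No Stern–Volmer correction and no time-varying (drift) gain model.
- No LOESS/Savitzky–Golay smoothing alternatives; the estimators are
  deliberately the plain moving mean and local OLS described above.
- No model averaging or information-criterion family selection; IC50 vs
  EC50 is labeling only (the `e` parameter is reported as fitted).
- The GUI-style interactive workflow is out of scope; plotting is static
  file export.
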