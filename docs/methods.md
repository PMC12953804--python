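# Methods

`neurocast` measures how temporal resolution reduction affects ARIMA point
and interval forecasting of cerebral physiologic signals. Because real
high-resolution neuromonitoring cohorts are not openly shareable, the
package ships a synthetic cohort generator with the statistical structure
the analysis assumes, and every quantitative claim in the test suite is
made against that generator or against closed-form/Monte-Carlo oracles.

## Synthetic waveforms

Each synthetic patient is a set of uniform-rate channels (default 100 Hz):

* **ABP** = MAP baseline + slow vasogenic waves + baseline drift +
  respiration + cardiac pulse + white noise.
* **ICP** = ICP baseline + `g` × (MAP slow-wave component) + an independent
  ICP slow wave + baseline drift + a cardiac pulse whose amplitude is
  `icp_pulse_base · (1 + a·z)` with `z` the normalized ICP slow-wave level
  + white noise.
* **PbtO2** = baseline + gain × (CPP slow-wave component lagged by
  `pbto2_lag`, default 20 s) + drift + noise.

Key parameters (units, defaults, rationale):

| parameter | default | why |
|---|---|---|
| `map_baseline` / `icp_baseline` | 90 / 12 mmHg | typical adult TBI values under ICU management |
| `cardiac_freq` | 1.2 Hz | 72 bpm; an integer multiple of 0.1 Hz so a 10-s frame holds whole pulse cycles and AMP estimation is leakage-free |
| `resp_freq`, `resp_amplitude` | 0.25 Hz, 2 mmHg | quiet mechanical-ventilation range |
| slow waves | 3 sinusoids, 0.017/0.025/0.04 Hz, 3/1.5/1 mmHg | inside the 0.005–0.05 Hz vasogenic band, periods well below the 5-min correlation window so PRx-style indices are informative |
| `autoregulation_gain` (`g`) | +1 (impaired) / −1 (intact) | the controlled truth that PRx should recover: for `y = g·x + ε`, corr ≈ `g·σx/√(g²σx²+σε²)` ≈ ±0.95 at the default amplitudes |
| `pulse_pressure` / `icp_pulse_base` | 20 / 2 mmHg | cardiac fundamental amplitudes; the ICP value is what AMP should read back |
| `noise_sd` | 1 mmHg | sensor-level white noise |
| `drift_sd` | 0.3 mmHg per √minute | a per-minute Gaussian random walk interpolated to the sample grid; represents the slow non-oscillatory baseline wander of real recordings. Without it, hourly averages of a purely band-limited signal are almost constant and coarse-resolution forecasting would look artificially easy — the opposite of what bedside data show |

The slow-wave model is a fixed sum of three seeded-random-phase sinusoids
(a `filtered_noise` mode generates band-limited Gaussian noise of matched
RMS instead); sinusoids keep the analytic correlation predictions
tractable. The MAP→ICP coupling has zero lag — physiologic transfer lags
would only attenuate the derived correlations. Missingness is represented
by a per-channel boolean mask, never by sentinel values, and masked samples
retain their underlying values so tests can compare against the truth.

The pure-ARMA generator (`generate_arma_series`) filters Gaussian
innovations through the ARMA recursion, discards a 500-sample burn-in to
remove initialization transients, and integrates `d` times. Non-stationary
AR or non-invertible MA polynomials are rejected; unit roots must be
expressed through `d`.

**What the generator does not emulate:** artifact spikes, device changes,
therapy-driven interventions (osmotherapy, CSF drainage), circadian
structure, heavy-tailed noise, or realistic ICP pulse morphology beyond a
fundamental plus two harmonics. Passing tests therefore demonstrate the
correctness and calibration of the pipeline, not clinical performance on
real recordings.

## Signal derivation

ABP/ICP/PbtO2 are reduced to 10-s non-overlapping block means (a frame is
valid when ≥ 50 % of its samples are unmasked — a majority rule keeps means
unbiased under short dropouts; clinical workflows clean artifacts manually
and publish no threshold). AMP is the maximum-magnitude DFT bin of each
Hanning-windowed 10-s ICP frame within the cardiac band 0.67–3 Hz,
converted to pressure units by dividing by the window's coherent gain; the
fundamental-peak reading is the simplest defensible choice and makes AMP
invariant to DC offsets. AMP requires a fully observed frame. CPP = MAP −
ICP with no clamping.

The reactivity indices are Pearson correlations over trailing windows of
30 consecutive 10-s means, updated every minute (stride 6 frames): PRx
(ICP~MAP), PAx (AMP~MAP), RAC (AMP~CPP), RAP (AMP~ICP). Windows are causal
(trailing) — a forecasting pipeline must not leak future samples into a
feature — and require full validity; zero-variance windows yield missing
values rather than errors. Minute summaries average the 6 frames of each
minute and need ≥ 4 valid frames.

## Resolution ladder and gap handling

Minute signals are averaged over non-overlapping windows of
1, 5, 10, 15, 30, 60, 120, 180, 240, 300, 360, 720 and 1440 minutes; a
window is valid when ≥ 50 % of its minutes are present, and a trailing
incomplete window is dropped. Gap rules apply at the working resolution
(after reduction, matching the preprocessing-then-model order of the
analysis): interior missing runs shorter than five points are linearly
interpolated between their flanking values; runs of five or more are
removed, splitting the series into segments (a run of exactly five falls
on the removal side — the conservative reading of a "fewer than five /
more than five" rule). Leading/trailing missing runs have no flank and are
trimmed. Modeling proceeds on the longest contiguous segment; whenever a
split occurs it is logged, never silently bridged.

Diagnostics are computed from scratch: ADF with constant (no trend), lag
order by AIC up to a Schwert-rule maximum, final regression re-estimated on
the full sample the chosen lag allows, 5 % critical value from the
MacKinnon response surface; KPSS in the level-stationary variant with
Bartlett-kernel long-run variance at bandwidth `⌊4(n/100)^¼⌋` and critical
value 0.463; ACF via biased autocovariances and PACF via Durbin–Levinson.
Both tests hold empirical size within [3 %, 7 %] at nominal 5 % on their
null models (n = 500, 200 draws), and the statistics match the statsmodels
reference implementations to 1e−6 when evaluated at the same lag orders.

## ARIMA estimation

The model on the d-times-differenced series is

    w_t = c + Σ_{i≤p} φ_i w_{t−i} + e_t + Σ_{j≤q} θ_j e_{t−j}

estimated by conditional sum of squares: residuals are computed by the
recursion with `e_t = 0` for `t ≤ max(p, q)` and the Gaussian likelihood is
maximized with the innovation variance concentrated out. CSS was chosen
over exact state-space likelihood because it is fully specifiable from the
recursion, fast enough for the AIC grid, and testable against closed forms;
estimates agree with exact-MLE reference fits within 0.05 elementwise on
identifiable ARMA(1,1) data at n = 500. Stationarity and invertibility are
enforced by optimizing over partial autocorrelations mapped through `tanh`
and the Durbin–Levinson recursion, so every iterate is admissible. The
optimizer (L-BFGS-B, objective tolerance 1e−8) is cold-started from an OLS
autoregression (shrunk into the stationary region when needed) and
warm-started from the previous fit in rolling re-estimation. The constant
is estimated when `d = 0` and fixed at 0 when `d ≥ 1` (a constant under
differencing implies a polynomial trend the analysis never invokes).

Two comparability corrections matter when AIC ranks CSS fits:

* the reported log-likelihood is scaled to the full differenced length,
  because the raw conditional likelihood covers `n − d − max(p, q)` points
  and would otherwise reward larger conditioning sets;
* `select_order` scores all candidates on a **common conditioning set** —
  residuals from the same original-time index (the largest
  `d + max(p, q)` among orders feasible at the given length) — otherwise
  large orders gain spurious likelihood by fitting the zero-initialized
  startup transient. `ArimaFit.aic` itself keeps the plain
  `2k − 2 logL`, `k = p + q + 2` definition.

Ties in AIC (within 1e−12) go to the smaller `p + q`, then smaller `q`,
then smaller `d`. The default grid is p ∈ 1..10, d ∈ 0..2, q ∈ 0..10;
note the deliberate floor at p = 1 even though p = 0 models exist.
Degenerate inputs (zero variance, below the hard length floor
`p + q + d + 2`) are rejected with diagnostics; a non-convergent
optimization returns a flagged fit which order selection skips.

Forecasts follow the conditional-expectation recursion on the differenced
scale (future innovations zero) and are integrated back using the stored
tails of each differencing level. Standard errors use ψ (MA(∞)) weights,
cumulated `d` times to the original scale:
`se_h = σ √(Σ_{j<h} ψ_j²)`; intervals are Gaussian,
`point ∓ z_{(1+level)/2}·se`. Empirical one-step 95 % coverage on AR(1)
data (n = 300, 1000 replicates) lies in [0.93, 0.97].

## Cross-validation schemes

* **one_step** — the evaluation region is the second half of the series;
  every index is a one-step-ahead test trained on all prior observations.
  The rolled tests are grouped into 5 contiguous reporting folds; the
  order is selected once per fold on the fold's initial training range
  (per-fold selection keeps the grid search tractable while the training
  window still absorbs every new observation), and
  coefficients are re-estimated at every step. In interval mode the window
  advances by the horizon (5), giving non-overlapping forecast blocks so
  every evaluated point is covered exactly once.
* **blocked** — 5 sequential non-overlapping blocks; within each block 70 %
  trains, a 2-point gap is discarded against adjacency leakage, and the
  remainder is tested by one-step predictions with coefficients frozen
  from the block's training fit. The internal proportions have no
  canonical convention; 70 %/gap 2 were chosen and are exposed as
  arguments. Blocked CV is point-prediction only.
* **tss** — expanding-train/fixed-test splitting into `n_splits + 1`
  partitions; in interval mode the first 5 points of each test partition
  are forecast with intervals.

All schemes preserve chronology (max train index < min test index in every
fold, property-tested), and prediction failures degrade to missing entries
rather than aborting a patient — the behavior a cohort-scale batch run
needs.

## Metrics and aggregation

MAE, RMSE and R² follow their standard definitions over pairwise-valid
(actual, predicted) pairs; R² is missing when the actuals have zero
variance and may be negative. CI spread is the mean (optionally median)
interval width; the median variant is more robust to outlying forecasts.
Cross-patient aggregation reports mean and SD (n−1 denominator) per
(signal, resolution, method, prediction type), excluding missing metrics
rather than imputing, and pivots into signal × resolution tables with R²
as the cell value and RMSE as companion. Wall-clock timings are recorded
in `timings.csv` and the run manifest, never in `metrics.csv`, so
`metrics.csv` is byte-deterministic given config + seed.

## Problem sizes used in the shipped studies

The package's own validation studies run at desk scale: coefficient
recovery at n = 2000 over 50 seeds; selection consistency at n = 1000 over
30 seeds; coverage over 1000 replicates at n = 300; stationarity-test
calibration over 200 draws at n = 500; and an end-to-end sweep of 5
synthetic patients × 12 h over resolutions {1, 5, 15, 60} min with a
reduced grid (p ≤ 3, d ≤ 1, q ≤ 1) and `min_points = 8`. The benchmark
default skips series shorter than 30 points (coarse-resolution cells are
known to be distorted by data scarcity) — the end-to-end study lowers the
threshold deliberately so the 60-min cells exist at 12 h, and the skip is
always logged, never silent.

## Known limitations

* CSS conditioning makes small-sample estimates differ from exact MLE by
  O(1/n); the grid search inherits AIC's overfitting tendency (on pure
  white noise, parsimonious orders are selected in roughly half the runs —
  comparable to exact-MLE AIC selection over the same candidate set).
* Gaussian prediction intervals understate uncertainty under heavy-tailed
  innovations; no bootstrap intervals.
* No seasonal differencing, exogenous regressors, trend-stationary KPSS
  variant, or structural-break handling.
* Gap counting operates on points at the working resolution; a
  minute-level counting convention would differ at coarse resolutions.
* The synthetic cohort makes no fidelity claim to any clinical cohort's
  distributions; it is a controlled environment for validating the
  machinery.
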