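# Methods

This note documents the models, conventions and parameter choices
behind `eegstress`, in the order the pipeline runs.

## Session model

A session contributes 12 min of processed signal: the MIST arithmetic
stressor test (360 s), VR relaxation (300 s) and the central minute of
a ~120-s final rest (60 s). Epochs are 2 s, non-overlapping, half-open
windows [2k, 2k+2), indexed 0-based per phase and concatenated in
session order — 180 + 150 + 30 = 360 epochs. Surveys map to epochs by
`floor(offset / 2)`; a survey at the exact end of a phase anchors to
that phase's last epoch (T4→179, T7→329, T8→359). T1 is answered at the
end of the initial rest, which is discarded before processing (it only
establishes a baseline), so T1 is anchored to the first processed epoch
(index 0). This mapping of T1 and T8 onto the processed timeline is a
package convention — the protocol itself does not dictate which feature
row a survey taken outside the processed span should label.

## Synthetic sessions

The generator emulates the acquisition conditions rather than cortical
physiology. Per channel, the EEG is a sum of five band-limited noise
components (white noise through a 4th-order Butterworth bandpass at the
band edges, normalized to unit variance), scaled so that the
instantaneous per-band variance is

    baseline_band · (1 + coupling_band · s(t)),   s(t) = (stress(t) − 1) / 4 ∈ [0, 1].

Defaults (chosen once as a plausible frontal-EEG operating point):
baselines Delta 30, Theta 20, Alpha 25, Beta 15, Gamma 10 μV² (total
σ ≈ 10 μV, comfortably under the 75 μV rejection threshold); couplings
Gamma +1.5, Beta +0.8, Alpha −0.5, Delta/Theta 0 — gamma and beta power
rise with stress, alpha falls, giving the relative-gamma index a strong
monotone relationship with the latent trajectory. A 50 Hz sinusoid
(5 μV) emulates line coupling; artifact epochs are drawn per nominal
epoch with probability 0.05 and receive a Tukey-tapered 10 Hz burst of
150 μV over the central 1.2 s of the epoch.

The latent stress trajectory is piecewise linear through anchors
(0 s, 1.4) → (360 s, 4.6) → (660 s, 1.8) → (720 s, 1.6): baseline rest,
monotone rise to the peak at the end of the stressor, decay through
relaxation. Anchor levels avoid half-integers so quantized survey
answers are rounding-rule independent. Survey answers are the
trajectory at the survey instants, rounded and clipped to 1–5; a ±1
reporting-jitter probability exists but defaults to 0, so the answers
are by construction consistent with the trajectory (the jitter knob is
for robustness experiments, not the default condition).

Recording lengths jitter by a whole-second uniform draw in ±3 s,
mimicking manually marked onsets and exercising the resampling stage.
Artifact bursts are positioned on the *nominal* epoch grid (their raw
position scaled by actual/nominal length), so after resampling each
burst lands exactly in its intended epoch and injected-artifact
recovery is exact, not approximate.

Not emulated: blink/EMG artifact morphology, inter-channel covariance,
1/f spectral slope, non-stationarity beyond the stress coupling.
Passing tests therefore demonstrate that the pipeline recovers signals
of this synthetic family, not that real EEG carries them.

## Preprocessing

- **Notch**: Butterworth band-stop with stopband exactly 48–52 Hz,
  2nd-order design applied forward-backward (`sosfiltfilt`). The order
  is a package choice (stable at 256 Hz, >40 dB at 50 Hz, <0.5 dB
  ripple in the EEG passband).
- **Bandpass**: 4th-order Butterworth, 2–48 Hz, forward-backward — the
  "zero-phase 4th-order" reading, with an effective 8th-order magnitude
  response. Filtering is always per phase recording, never across
  phase boundaries.
- **Resampling**: rational-factor polyphase (`resample_poly` at
  up/down = nominal/actual after gcd reduction) to hit the exact
  nominal sample count; an FFT fallback covers pathological ratios.
  Lengths outside ±10% of nominal are rejected as corrupt. The final
  rest is first trimmed to its central 60 s (after filtering, so the
  trim discards filter edge transients along with the phase margins).
- **Outliers**: an epoch whose absolute amplitude exceeds 75 μV on
  *any* channel is zeroed across all channels and masked — rejection
  acts on epochs, not channel-epochs. The threshold applies to
  filtered, pre-standardization microvolts.
- **Detrend + standardize**: least-squares line removed per
  channel-epoch, then z-scoring to mean 0, sd 1 (ddof 0). A
  channel-epoch left constant (e.g. a pure ramp) would make the
  division undefined; such epochs are zeroed and added to the outlier
  mask rather than propagating NaNs.

## Features

Per epoch and channel, a single-segment periodogram of the 512-sample
epoch under a Tukey window (taper fraction 0.25; the window family is
fixed, the fraction is a package default exposed in the API). Band
power integrates the PSD by the trapezoidal rule over bins whose
centers fall in [low, high) — explicit and deterministic at the 0.5 Hz
resolution. The Delta band keeps its nominal 1–4 Hz edges even though
the 2 Hz bandpass attenuates its lower half; the band table is applied
verbatim and the interaction documented here. Powers are absolute (not
log-transformed). RG is computed from channel-averaged powers (the
channel-averaged PSD convention); a zeroed epoch has zero denominator
and RG is defined as 0 so the matrix stays dense, with the outlier flag
carried alongside. AA uses channel-specific alpha at F6 and F5.

Smoothing: centered moving average, 30 s = 15 epochs, truncated
(shrinking) at recording edges — no phase lag, no leakage across phase
boundaries.

Note that standardization fixes every epoch's total variance at 1, so
band "powers" downstream are effectively band *shares* of the epoch
spectrum. The stress signal survives because the couplings shift the
spectral balance, not just the absolute power.

## Labels

Linear interpolation uses `np.interp`; pchip the shape-preserving
Hermite interpolator; spline a cubic spline with natural boundary
conditions (the boundary rule is a package choice); nearest the
closest-knot rule. Values are clipped to [1, 5] and knots are exact by
construction. The train/test split is the 352/8 partition described
above; feature-column scaling uses training-row statistics only, and
cross-validation folds are drawn from training rows only — test rows
are untouched until final evaluation.

## Models

Grids (fixed): ridge — polynomial degree {1,2,3} × penalty
{1e-4,…,1e-1,10,1e2}; random forest — estimators {100,200,300} ×
max features {5,6,7} × depth {6,7}; MLP — layers {1,2} × neurons {3,4}
× activation {relu,tanh} × penalty {1e-3,1e-2,1e-1}; SVR — kernel
{linear,poly,rbf,sigmoid} × C {2⁻⁵,2⁻³,2⁻¹,2,2³} × ε {1e-3,1e-2,1e-1}.
"Polynomial degree" for ridge is realized as polynomial feature
expansion of the 7 columns before the linear ridge fit — the only
reading under which degree is a ridge hyperparameter.

CV scoring is mean squared error (consistent with the MSPE numerator);
folds are contiguous, unshuffled 5-fold splits of the training rows
(fully deterministic; a seeded shuffled option exists). Ties in mean CV
error break to the earliest combination in grid-enumeration order. A
combination that raises during fitting is scored as infinitely bad, not
fatal. Every stochastic estimator receives a single pipeline-level
`random_state` (default 0). The MLP trains with lbfgs, max_iter 500:
for networks of 3–4 neurons on ~350 samples lbfgs converges quickly and
reproducibly; convergence warnings are suppressed, not errors.
Predictions may optionally be clipped to [1, 5] (off by default).

## Evaluation

MSPE is implemented exactly as defined — MSE divided by the mean of the
true answers, ×100 — although the resulting units are irregular (the
ratio has units of the target, not dimensionless); the conventional
alternative (normalizing by the squared mean) is available behind
`normalization="mean_squared"`. R² is the squared Pearson correlation;
the coefficient of determination is available behind a flag. Undefined
R² (constant arrays) is reported as missing (NaN), never as 0.
Aggregation reports mean ± SEM (sample sd, n−1, over √n participants);
SEM with fewer than two participants is missing. The per-survey table
reports mean absolute error ± SEM at T1…T8 for the cell with minimum
mean MSPE.

## Problem sizes

The default study condition is a 23-participant cohort with all four
regressors and all four interpolation schemes. On one CPU the full
Table-1-sized grids cost roughly 35 s per participant-interpolation
(random forest dominates), so the package's standard runs are sized as
follows: the model-recovery study uses 5 participants, full grids,
linear interpolation, under the low-noise strong-coupling condition
(`SynthConfig.strong_coupling()`: couplings Gamma +2.5, Beta +1.2,
Alpha −0.7, Theta −0.3, no line noise, no artifacts); the 23-participant
4 × 4 cohort report uses the thinned grids (`reduced_grids()`, 1–2
combinations per family drawn from the full grids), which exercise the
identical code path while keeping a cohort run under a few minutes.
Full grids on the full cohort are a supported configuration
(`RunConfig(grids=None)`), just a long one.

## Known limitations

- Interpolated training labels share information with the test knots by
  construction (neighbouring training rows interpolate *through* the
  test answers), so test scores overstate generalization to unseen
  sessions; this is inherent to the single-session individualized
  design, and the random-forest train-vs-test gap test documents the
  direction of the bias.
- Synthetic sessions are far cleaner than real EEG; absolute MSPE/R²
  values on them are not comparable to values obtainable on human data.
- The generator's couplings are monotone and instantaneous; hysteresis,
  habituation and delayed autonomic responses are out of scope.
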