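# eegstress

Individualized, quantitative prediction of self-perceived stress from
frontal EEG.

Stress classifiers usually stop at two or three discrete levels. This
package implements the alternative: treat momentary stress as a
continuous variable and fit, **per participant**, a regression model
that maps spectral EEG features onto the participant's own 1–5
self-reports (SPSL, self-perceived stress level) collected during a
stress–relax session — a 6-min arithmetic stressor (MIST), 5 min of VR
relaxation, and a final rest, with eight surveys T1…T8 along the way.

Because the human recordings behind this protocol are not publicly
deposited, the package ships a protocol-faithful synthetic session
generator, so every stage is runnable and testable end to end.

## The pipeline

For each of the three phase recordings (4 channels — Fp1, Fp2, F5, F6 —
at 256 Hz, microvolts):

1. **Preprocess**: 48–52 Hz notch → 4th-order zero-phase Butterworth
   bandpass 2–48 Hz → resample to the phase's nominal length → split
   into 2-s epochs → zero epochs exceeding 75 μV → per-epoch linear
   detrend and z-scoring. A nominal session yields exactly
   360 epochs = (60 s/min · 12 min) / (2 s/epoch).
2. **Features** (per epoch, Tukey-windowed periodogram): channel-averaged
   power P in Delta (1–4 Hz), Theta (4–8), Alpha (8–13), Beta (13–25),
   Gamma (25–45), plus

   - relative gamma   RG = P_Gamma / (P_Alpha + P_Theta)
   - alpha asymmetry  AA = P_Alpha(F6) − P_Alpha(F5)

   smoothed by a 30-s moving average → a 360 × 7 feature matrix X.
3. **Labels**: the eight survey answers are interpolated (linear, pchip,
   spline or nearest) onto the 360-epoch grid → target y. The 352
   interpolated rows train; the 8 true answers test.
4. **Model**: grid-search 5-fold cross-validation per regressor family —
   ridge (on polynomial expansions), random forest, MLP, SVR — over
   fixed grids of 18/18/24/60 hyperparameter combinations; the winner
   is refitted on all training rows.
5. **Evaluate**: MSPE = (mean squared error / mean true answer) · 100
   and R² (squared Pearson correlation) at the eight surveys; cohorts
   aggregate mean ± SEM per (regressor × interpolation) cell.

## Worked example

`examples/04_fit_one_participant.py` simulates one participant, extracts
the feature matrix, and fits the ridge grid:

```text
ridge grid: 18 combinations, 90 fold fits
best hyperparameters: {'degree': 1, 'alpha': 10.0} (CV MSE 0.2264)

    true answers: [1.0, 2.0, 4.0, 5.0, 4.0, 3.0, 2.0, 2.0]
  predictions: [1.41, 2.51, 3.76, 4.65, 3.58, 3.24, 1.39, 1.5]

MSPE = 6.37   R^2 = 0.896
```

The true answers are what the synthetic participant "reported" at
T1…T8; the predictions come from EEG features alone. MSPE = 6.37 means
the mean squared prediction error is ~6% of the participant's mean
reported stress; R² = 0.896 says the predictions track the rise through
the stressor and the decay through relaxation almost perfectly.

`examples/05_cohort_report.py` runs a small cohort and prints the
per-cell mean ± SEM table; on synthetic cohorts the best cell is
consistently random forest on linearly interpolated labels. The other
examples walk through simulation, preprocessing and label
interpolation. A thin CLI wraps the same functions:

```bash
eegstress simulate --seed 0 --out session/
eegstress run --seed 0 --participants 4 --quick --out cohort/
```

## Layout

- `src/eegstress/` — `schedule`, `synthetic`, `preprocess`, `features`,
  `labels`, `model`, `evaluate`, `pipeline`, `io`, `cli`
- `examples/` — one narrative script per capability
- `docs/methods.md` — model, assumptions, parameter choices, limitations
- `tests/` — pytest suite (unit, property and end-to-end acceptance)
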