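"""Fit an individualized stress regressor for one synthetic participant.

Grid-search 5-fold cross-validation over the ridge grid (18 parameter
combinations), refit the winner on the 352 training rows, and score it
on the 8 held-out survey answers with MSPE and R^2.
"""

import numpy as np

import eegstress as es
from eegstress.pipeline import surveys_from_truth

schedule = es.build_default_schedule()
recordings, truth = es.simulate_session(schedule, es.SynthConfig(seed=0))
fm = es.extract_session_features(recordings, schedule, es.RunConfig())
surveys = surveys_from_truth(truth, schedule)

knots = es.map_surveys_to_epochs(schedule)
trace = es.interpolate_spsl(surveys, knots, fm.n_epochs, "linear")
train, test = es.make_split(trace)
X, _, _ = es.scale_columns(fm.values, train)  # training-row statistics only

fit = es.grid_search_fit("ridge", X[train], trace.values[train])
print(f"ridge grid: {fit.n_combinations} combinations, {fit.n_fold_fits} fold fits")
print("best hyperparameters:", fit.best_params, f"(CV MSE {fit.best_cv_mse:.4f})")

y_true = trace.values[test]
y_pred = es.predict(fit, X[test])
print("\n    true answers:", y_true.tolist())
print("  predictions:", np.round(y_pred, 2).tolist())
print(f"\nMSPE = {es.mspe(y_true, y_pred):.2f}   R^2 = {es.r_squared(y_true, y_pred):.3f}")
# MSPE is the mean squared error at the eight surveys, normalized by the
# mean true answer, x100; R^2 the squared Pearson correlation.
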