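"""Run a small synthetic cohort and print the aggregate report.

One individualized model per participant and per (regressor x
interpolation) cell; the report aggregates MSPE and R^2 as mean +/- SEM
across participants, mirroring a per-cell performance table, plus the
per-survey mean absolute error of the best cell.

Uses the thinned hyperparameter grids so it finishes in ~30 s; drop
``grids=`` to search the full grids.
"""

import eegstress as es

cfg = es.RunConfig(
    seed=0,
    n_participants=4,
    grids=es.reduced_grids(),
    families=("ridge", "random_forest"),
    interpolations=("linear", "nearest"),
)
report, results = es.run_cohort(cfg)

print("per-cell performance, mean ± SEM over participants:\n")
print(report.table().to_string())
print(
    f"\nbest cell: {report.best_family} on {report.best_interpolation} "
    "interpolation (minimum mean MSPE)"
)
print("\nper-survey mean absolute error of the best cell:")
print(report.survey_errors.round(3).to_string(index=False))
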