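"""Turn eight sparse survey answers into a 360-sample regression target.

The eight SPSL answers anchor the target at their epoch indices (the
knots); four interpolation schemes fill the 352 epochs in between. The
knot rows become the test set; the interpolated rows train the model.
"""

import numpy as np

import eegstress as es
from eegstress.labels import SurveySeries

schedule = es.build_default_schedule()
knots = es.map_surveys_to_epochs(schedule)
print("survey -> epoch mapping:", dict(zip(schedule.survey_ids, knots.tolist())))

surveys = SurveySeries(
    survey_ids=tuple(schedule.survey_ids),
    times_s=schedule.survey_times_s,
    values=[1, 2, 4, 5, 4, 3, 2, 2],
)

for method in es.INTERPOLATION_METHODS:
    trace = es.interpolate_spsl(surveys, knots, schedule.n_epochs, method)
    mid = trace.values[[30, 150, 250, 344]]
    print(f"{method:8s} trace at epochs 30/150/250/344: {np.round(mid, 2).tolist()}")

train, test = es.make_split(trace)
print(f"\nsplit: {len(train)} interpolated training rows, {len(test)} true-answer test rows")
# All methods pass exactly through the answers; they differ only between
# knots (spline may overshoot and is clipped back to the 1-5 scale).
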