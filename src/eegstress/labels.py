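"""From eight SPSL survey answers to a 360-sample regression target.

Eight ordinal self-reports are too few to train on directly, so the
answers are interpolated onto the epoch grid of the feature matrix,
under the assumption that self-perceived stress does not change
drastically between neighbouring surveys. Four schemes are supported:
linear, pchip (shape-preserving cubic Hermite), spline (natural cubic)
and nearest. Interpolated values are clipped back to the [1, 5] scale
(cubic splines can overshoot).

The interpolated rows form the training set (352 samples); the rows at
the eight survey knots — the answers the participant actually gave —
form the test set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator, interp1d

from .schedule import SessionSchedule

INTERPOLATION_METHODS = ("linear", "pchip", "spline", "nearest")
SPSL_MIN, SPSL_MAX = 1.0, 5.0


@dataclass
class SurveySeries:
    """The ordered survey answers: ids T1..T8, session times, SPSL in 1-5."""

    survey_ids: tuple[str, ...]
    times_s: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.survey_ids = tuple(self.survey_ids)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values)
        if not (len(self.survey_ids) == len(self.times_s) == len(self.values)):
            raise ValueError("ids, times and values must have equal length")
        if (np.diff(self.times_s) <= 0).any():
            raise ValueError("survey times must be strictly increasing")
        v = self.values
        if not (np.equal(np.mod(v, 1), 0).all() and (v >= SPSL_MIN).all() and (v <= SPSL_MAX).all()):
            raise ValueError("SPSL answers must be integers in [1, 5]")
        self.values = self.values.astype(float)

    def __len__(self) -> int:
        return len(self.survey_ids)


@dataclass
class SPSLTrace:
    """The interpolated target array with its knot bookkeeping."""

    values: np.ndarray  # length n_epochs, within [1, 5]
    method: str
    knots: np.ndarray  # 8 strictly increasing epoch indices

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.knots = np.asarray(self.knots, dtype=int)
        if (np.diff(self.knots) <= 0).any():
            raise ValueError("knot indices must be strictly increasing")
        if self.knots[0] < 0 or self.knots[-1] >= len(self.values):
            raise ValueError("knot indices outside the trace")

    def __len__(self) -> int:
        return len(self.values)


def map_surveys_to_epochs(schedule: SessionSchedule) -> np.ndarray:
    """Epoch index of each survey on the concatenated session grid.

    A survey at offset t into its phase lands in epoch floor(t / 2);
    a survey at the exact end of a phase is anchored to that phase's
    last epoch (it cannot index into the next recording).
    """
    indices = []
    for s in schedule.surveys:
        ph = schedule.phase(s.phase)
        first = int(round(schedule.phase_offset_s(s.phase) / schedule.epoch_s))
        if s.offset_s >= ph.duration_s:
            idx = first + ph.n_epochs - 1
        else:
            idx = first + int(s.offset_s // schedule.epoch_s)
        indices.append(idx)
    out = np.array(indices, dtype=int)
    if out.min() < 0 or out.max() >= schedule.n_epochs:
        raise ValueError("survey outside the processed session timeline")
    return out


def interpolate_spsl(
    surveys: SurveySeries, knots: np.ndarray, n: int, method: str = "linear"
) -> SPSLTrace:
    """Interpolate the survey answers onto an n-epoch grid.

    Exact at every knot (before clipping, and after it too since the
    answers themselves lie in [1, 5]); values in between follow the
    requested scheme, clipped to the SPSL scale.
    """
    if method not in INTERPOLATION_METHODS:
        raise ValueError(f"method must be one of {INTERPOLATION_METHODS}")
    knots = np.asarray(knots, dtype=int)
    if len(knots) < 2:
        raise ValueError("at least two survey knots are required")
    if len(knots) != len(surveys):
        raise ValueError("one knot index per survey answer required")
    x, y = knots.astype(float), surveys.values
    grid = np.arange(n, dtype=float)
    if method == "linear":
        vals = np.interp(grid, x, y)
    elif method == "pchip":
        vals = PchipInterpolator(x, y)(grid)
    elif method == "spline":
        vals = CubicSpline(x, y, bc_type="natural")(grid)
    else:  # nearest
        vals = interp1d(x, y, kind="nearest", fill_value=(y[0], y[-1]), bounds_error=False)(grid)
    vals = np.clip(vals, SPSL_MIN, SPSL_MAX)
    vals[knots] = y  # knot exactness, immune to float round-off
    return SPSLTrace(values=vals, method=method, knots=knots)


def make_split(trace: SPSLTrace) -> tuple[np.ndarray, np.ndarray]:
    """Partition epochs: test = the survey knots, train = everything else."""
    n = len(trace)
    test = trace.knots.copy()
    train = np.setdiff1d(np.arange(n), test)
    return train, test
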