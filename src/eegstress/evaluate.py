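"""Scoring and cohort aggregation for SPSL predictions.

Two headline metrics per participant and model:

* MSPE, the mean squared percentage error: the mean squared prediction
  error at the eight survey instants, normalized by the mean of the
  true answers, times 100. Normalizing by the participant's own mean
  keeps the error comparable across participants whose stress never
  approaches the top of the scale.
* R^2, the squared Pearson correlation between true answers and
  predictions.

Cohort aggregation reports mean +/- SEM per (regressor x interpolation)
cell, plus the per-survey mean absolute error of the best cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def mspe(y_test, y_pred, normalization: str = "mean") -> float:
    """Mean squared percentage error.

    ``normalization="mean"`` divides the MSE by the mean of y_test (the
    study's definition); ``"mean_squared"`` divides by the squared mean,
    the dimensionally conventional alternative.
    """
    y_test = np.asarray(y_test, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_test.shape != y_pred.shape:
        raise ValueError("y_test and y_pred must have equal length")
    m = y_test.mean()
    if m <= 0:
        raise ValueError("mean of y_test must be positive")
    mse = float(np.mean((y_test - y_pred) ** 2))
    if normalization == "mean":
        return mse / m * 100.0
    if normalization == "mean_squared":
        return mse / m**2 * 100.0
    raise ValueError("normalization must be 'mean' or 'mean_squared'")


def r_squared(y_test, y_pred, definition: str = "pearson") -> float:
    """Squared Pearson correlation (default) or coefficient of determination.

    Returns NaN (missing) when the correlation is undefined, i.e. either
    array is constant.
    """
    y_test = np.asarray(y_test, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if definition == "coefficient_of_determination":
        ss_res = np.sum((y_test - y_pred) ** 2)
        ss_tot = np.sum((y_test - y_test.mean()) ** 2)
        return float(1.0 - ss_res / ss_tot) if ss_tot > 0 else float("nan")
    if definition != "pearson":
        raise ValueError("definition must be 'pearson' or 'coefficient_of_determination'")
    if np.ptp(y_test) == 0 or np.ptp(y_pred) == 0:
        return float("nan")
    r = stats.pearsonr(y_test, y_pred).statistic
    return float(r**2)


def per_survey_abs_error(y_test, y_pred) -> np.ndarray:
    """Absolute prediction error at each survey instant, in answer order."""
    y_test = np.asarray(y_test, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_test.shape != y_pred.shape:
        raise ValueError("y_test and y_pred must have equal length")
    return np.abs(y_test - y_pred)


@dataclass
class EvalResult:
    """One participant's score for one (regressor, interpolation) cell."""

    participant: int
    family: str
    interpolation: str
    mspe: float
    r2: float
    abs_errors: np.ndarray
    best_params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.abs_errors)


def score_predictions(
    participant: int,
    family: str,
    interpolation: str,
    y_test,
    y_pred,
    best_params: dict | None = None,
) -> EvalResult:
    return EvalResult(
        participant=participant,
        family=family,
        interpolation=interpolation,
        mspe=mspe(y_test, y_pred),
        r2=r_squared(y_test, y_pred),
        abs_errors=per_survey_abs_error(y_test, y_pred),
        best_params=dict(best_params or {}),
    )


def _sem(x: np.ndarray) -> float:
    """Sample-sd / sqrt(n); NaN below two observations."""
    x = np.asarray(x, dtype=float)
    return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) >= 2 else float("nan")


@dataclass
class AggregateReport:
    """Cohort summary: one row per (regressor x interpolation) cell.

    cells has columns family, interpolation, mspe_mean, mspe_sem,
    r2_mean, r2_sem, n_participants. survey_errors holds the per-survey
    mean absolute error +/- SEM of the best cell (minimum mean MSPE).
    """

    cells: pd.DataFrame
    survey_errors: pd.DataFrame
    best_family: str
    best_interpolation: str

    def table(self, metric_fmt: str = "{:.2f} ± {:.2f}") -> pd.DataFrame:
        """Human-readable layout: regressor rows, interpolation columns,
        MSPE and R^2 side by side, mean +/- SEM."""
        rows = {}
        for fam, block in self.cells.groupby("family", sort=False):
            row = {}
            for _, c in block.iterrows():
                row[(c["interpolation"], "MSPE")] = metric_fmt.format(c["mspe_mean"], c["mspe_sem"])
                row[(c["interpolation"], "R2")] = metric_fmt.format(c["r2_mean"], c["r2_sem"])
            rows[fam] = row
        df = pd.DataFrame(rows).T
        df.columns = pd.MultiIndex.from_tuples(df.columns)
        return df


def aggregate(results: list[EvalResult], survey_ids: tuple[str, ...] | None = None) -> AggregateReport:
    """Mean +/- SEM per cell across participants; SEM missing below n=2."""
    if not results:
        raise ValueError("no results to aggregate")
    df = pd.DataFrame(
        {
            "participant": [r.participant for r in results],
            "family": [r.family for r in results],
            "interpolation": [r.interpolation for r in results],
            "mspe": [r.mspe for r in results],
            "r2": [r.r2 for r in results],
        }
    )
    cells = (
        df.groupby(["family", "interpolation"], sort=False)
        .agg(
            mspe_mean=("mspe", "mean"),
            mspe_sem=("mspe", _sem),
            r2_mean=("r2", "mean"),
            r2_sem=("r2", _sem),
            n_participants=("participant", "count"),
        )
        .reset_index()
    )
    best = cells.loc[cells["mspe_mean"].idxmin()]
    best_results = [
        r
        for r in results
        if r.family == best["family"] and r.interpolation == best["interpolation"]
    ]
    errs = np.vstack([r.abs_errors for r in best_results])
    ids = list(survey_ids) if survey_ids else [f"T{i + 1}" for i in range(errs.shape[1])]
    survey_errors = pd.DataFrame(
        {
            "survey": ids,
            "mean_abs_error": errs.mean(axis=0),
            "sem": [_sem(errs[:, j]) for j in range(errs.shape[1])],
        }
    )
    return AggregateReport(
        cells=cells,
        survey_errors=survey_errors,
        best_family=str(best["family"]),
        best_interpolation=str(best["interpolation"]),
    )
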