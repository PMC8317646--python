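"""Delimited-table interchange for recordings, surveys, features, traces.

Recordings travel as a CSV with columns ``time_s, Fp1, Fp2, F5, F6``
(microvolts) plus a YAML sidecar (``<name>.meta.yaml``) carrying the
sampling rate, phase tag and nominal processed duration. Surveys,
feature matrices, SPSL traces and cohort reports are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluate import AggregateReport
from .features import FEATURE_COLUMNS, FeatureMatrix
from .labels import SPSLTrace, SurveySeries
from .preprocess import Recording


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.yaml")


def write_recording(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.sampling_rate_hz
    df = pd.DataFrame({"time_s": t})
    for i, ch in enumerate(rec.channels):
        df[ch] = rec.data[i]
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "sampling_rate_hz": float(rec.sampling_rate_hz),
        "phase": rec.phase,
        "nominal_duration_s": float(rec.nominal_duration_s),
        "channels": list(rec.channels),
        "units": "uV",
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    meta = yaml.safe_load(_sidecar(path).read_text())
    df = pd.read_csv(path)
    channels = meta["channels"]
    return Recording(
        data=df[channels].to_numpy().T,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        channels=tuple(channels),
        phase=meta["phase"],
        nominal_duration_s=float(meta["nominal_duration_s"]),
    )


def write_surveys(surveys: SurveySeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "survey_id": list(surveys.survey_ids),
            "time_s": surveys.times_s,
            "spsl": surveys.values.astype(int),
        }
    ).to_csv(path, index=False)
    return path


def read_surveys(path: str | Path) -> SurveySeries:
    df = pd.read_csv(path)
    return SurveySeries(
        survey_ids=tuple(df["survey_id"]),
        times_s=df["time_s"].to_numpy(),
        values=df["spsl"].to_numpy(),
    )


def write_features(fm: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    fm.to_frame().to_csv(path, index=False)
    return path


def read_features(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    return FeatureMatrix(
        values=df[list(FEATURE_COLUMNS)].to_numpy(),
        phase=df["phase"].to_numpy(),
        epoch_start_s=df["epoch_start_s"].to_numpy(),
        mask=df["is_outlier"].to_numpy(dtype=bool),
    )


def write_trace(trace: SPSLTrace, path: str | Path) -> Path:
    path = Path(path)
    n = len(trace)
    is_knot = np.zeros(n, dtype=bool)
    is_knot[trace.knots] = True
    pd.DataFrame(
        {
            "epoch_index": np.arange(n),
            "spsl": trace.values,
            "is_knot": is_knot,
            "method": trace.method,
        }
    ).to_csv(path, index=False)
    return path


def write_report(report: AggregateReport, directory: str | Path, prefix: str = "cohort") -> dict:
    """Write the cell summary, the formatted table and the per-survey
    error table; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": directory / f"{prefix}_cells.csv",
        "table": directory / f"{prefix}_table.csv",
        "survey_errors": directory / f"{prefix}_survey_errors.csv",
    }
    report.cells.to_csv(paths["cells"], index=False)
    report.table().to_csv(paths["table"])
    report.survey_errors.to_csv(paths["survey_errors"], index=False)
    return paths
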