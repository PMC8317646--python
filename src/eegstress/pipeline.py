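"""End-to-end orchestration: simulate -> preprocess -> features -> labels
-> per-(regressor x interpolation) fit -> evaluation -> cohort report.

Each participant is processed independently: their own synthetic
session, their own feature scaling (training rows only), their own grid
searches. Participant seeds derive deterministically from the master
seed, so a cohort run is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as eio
from .evaluate import AggregateReport, EvalResult, aggregate, score_predictions
from .features import (
    DEFAULT_SMOOTH_WINDOW_S,
    DEFAULT_TUKEY_ALPHA,
    FeatureMatrix,
    assemble_features,
    concat_features,
    smooth_features,
)
from .labels import INTERPOLATION_METHODS, SurveySeries, interpolate_spsl, make_split, map_surveys_to_epochs
from .model import DEFAULT_GRIDS, FAMILIES, grid_search_fit, predict, scale_columns
from .preprocess import OUTLIER_THRESHOLD_UV, Recording, preprocess_recording
from .schedule import SessionSchedule, build_default_schedule
from .synthetic import GroundTruth, SynthConfig, simulate_session

logger = logging.getLogger("eegstress")


@dataclass
class RunConfig:
    """Everything a cohort run depends on; defaults match the study."""

    seed: int = 0
    n_participants: int = 23
    synth: SynthConfig = field(default_factory=SynthConfig)
    outlier_threshold_uv: float = OUTLIER_THRESHOLD_UV
    notch_hz: tuple[float, float] = (48.0, 52.0)
    band_hz: tuple[float, float] = (2.0, 48.0)
    tukey_alpha: float = DEFAULT_TUKEY_ALPHA
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S
    interpolations: tuple[str, ...] = INTERPOLATION_METHODS
    families: tuple[str, ...] = FAMILIES
    folds: int = 5
    model_seed: int = 0  # random_state handed to every stochastic estimator
    cv_shuffle: bool = False
    clip_predictions: bool = False
    grids: dict | None = None  # None -> the full default grids
    mlp_max_iter: int = 500
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        for key in ("interpolations", "families", "notch_hz", "band_hz"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synth=synth, **raw)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"] = dataclasses.asdict(self.synth)
        return d


def participant_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic, distinct per-participant seeds below 2**31."""
    return np.random.SeedSequence(master_seed).generate_state(n) % (2**31)


def extract_session_features(
    recordings: list[Recording],
    schedule: SessionSchedule,
    config: RunConfig,
) -> FeatureMatrix:
    """Preprocess each phase recording, extract and smooth its features,
    and concatenate the phases in session order."""
    by_phase = {r.phase: r for r in recordings}
    parts = []
    for ph in schedule.phases:
        ep = preprocess_recording(
            by_phase[ph.name],
            threshold_uv=config.outlier_threshold_uv,
            notch_hz=config.notch_hz,
            band_hz=config.band_hz,
        )
        fm = assemble_features(
            ep, phase_offset_s=schedule.phase_offset_s(ph.name), tukey_alpha=config.tukey_alpha
        )
        parts.append(smooth_features(fm, config.smooth_window_s))
    return concat_features(parts)


def surveys_from_truth(truth: GroundTruth, schedule: SessionSchedule) -> SurveySeries:
    return SurveySeries(
        survey_ids=tuple(schedule.survey_ids),
        times_s=truth.survey_times_s,
        values=truth.survey_answers,
    )


def fit_participant(
    features: FeatureMatrix,
    surveys: SurveySeries,
    schedule: SessionSchedule,
    config: RunConfig,
    participant: int = 0,
) -> list[EvalResult]:
    """Grid-search every configured (interpolation x family) cell for one
    participant's feature matrix and survey answers."""
    knots = map_surveys_to_epochs(schedule)
    results = []
    for method in config.interpolations:
        trace = interpolate_spsl(surveys, knots, features.n_epochs, method=method)
        train_idx, test_idx = make_split(trace)
        X, _, _ = scale_columns(features.values, train_idx)
        y = trace.values
        for family in config.families:
            grid = (config.grids or DEFAULT_GRIDS).get(family)
            fit = grid_search_fit(
                family,
                X[train_idx],
                y[train_idx],
                folds=config.folds,
                seed=config.model_seed,
                grid=grid,
                shuffle=config.cv_shuffle,
                mlp_max_iter=config.mlp_max_iter,
            )
            y_pred = predict(fit, X[test_idx], clip=config.clip_predictions)
            res = score_predictions(
                participant, family, method, y[test_idx], y_pred, fit.best_params
            )
            logger.info(
                "participant %d %s/%s: MSPE=%.2f R2=%.3f best=%s",
                participant, family, method, res.mspe, res.r2, fit.best_params,
            )
            results.append(res)
    return results


def run_participant(
    config: RunConfig,
    participant_seed: int,
    participant: int = 0,
    schedule: SessionSchedule | None = None,
) -> tuple[list[EvalResult], FeatureMatrix]:
    """Simulate and fully analyse one synthetic participant."""
    schedule = schedule or build_default_schedule()
    synth = dataclasses.replace(config.synth, seed=int(participant_seed))
    recordings, truth = simulate_session(schedule, synth)
    features = extract_session_features(recordings, schedule, config)
    surveys = surveys_from_truth(truth, schedule)
    results = fit_participant(features, surveys, schedule, config, participant)
    if config.output_dir:
        out = Path(config.output_dir) / f"participant_{participant:02d}"
        out.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            eio.write_recording(rec, out / f"{rec.phase}.csv")
        eio.write_surveys(surveys, out / "surveys.csv")
        eio.write_features(features, out / "features.csv")
    return results, features


def run_cohort(
    config: RunConfig, schedule: SessionSchedule | None = None
) -> tuple[AggregateReport, list[EvalResult]]:
    """Run every participant and aggregate mean +/- SEM per cell."""
    schedule = schedule or build_default_schedule()
    seeds = participant_seeds(config.seed, config.n_participants)
    all_results: list[EvalResult] = []
    for i, s in enumerate(seeds):
        res, _ = run_participant(config, s, participant=i, schedule=schedule)
        all_results.extend(res)
    report = aggregate(all_results, survey_ids=tuple(schedule.survey_ids))
    if config.output_dir:
        out = Path(config.output_dir)
        eio.write_report(report, out)
        (out / "manifest.yaml").write_text(yaml.safe_dump(config.to_manifest(), sort_keys=False))
    return report, all_results
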