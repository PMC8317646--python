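"""Spectral features per 2-s epoch: band powers, relative gamma, asymmetry.

Seven features per epoch: channel-averaged power in the five canonical
bands — Delta (1-4 Hz), Theta (4-8), Alpha (8-13), Beta (13-25),
Gamma (25-45) — plus two composite stress markers:

* relative gamma, RG = P_Gamma / (P_Alpha + P_Theta), a proposed index
  of arousal/stress;
* frontal alpha asymmetry, AA = P_Alpha(F6) - P_Alpha(F5), a proposed
  marker of affective lateralization.

Powers come from a Tukey-windowed single-segment periodogram of each
512-sample epoch, integrated over the band edges. A centered 30-s
moving average then smooths each feature within its phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import EpochArray
from .schedule import EPOCH_S

#: canonical EEG bands, ascending, edges in Hz
BANDS: tuple[tuple[str, float, float], ...] = (
    ("Delta", 1.0, 4.0),
    ("Theta", 4.0, 8.0),
    ("Alpha", 8.0, 13.0),
    ("Beta", 13.0, 25.0),
    ("Gamma", 25.0, 45.0),
)
BAND_NAMES = tuple(b[0] for b in BANDS)
FEATURE_COLUMNS = ("P_Delta", "P_Theta", "P_Alpha", "P_Beta", "P_Gamma", "RG", "AA")

DEFAULT_TUKEY_ALPHA = 0.25
DEFAULT_SMOOTH_WINDOW_S = 30.0


@dataclass
class FeatureMatrix:
    """Epochs x 7 feature values with the epoch timeline alongside.

    values is (n_epochs, 7) ordered as FEATURE_COLUMNS; phase and
    epoch_start_s locate each row on the session timeline; mask flags
    rows from zeroed (outlier) epochs.
    """

    values: np.ndarray
    phase: np.ndarray
    epoch_start_s: np.ndarray
    mask: np.ndarray
    columns: tuple[str, ...] = field(default=FEATURE_COLUMNS)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError(f"values must be (n_epochs, {len(self.columns)})")
        n = self.values.shape[0]
        self.phase = np.asarray(self.phase)
        self.epoch_start_s = np.asarray(self.epoch_start_s, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.phase) == len(self.epoch_start_s) == len(self.mask) == n):
            raise ValueError("timeline arrays must match the number of rows")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.columns))
        df.insert(0, "phase", self.phase)
        df.insert(1, "epoch_start_s", self.epoch_start_s)
        df["is_outlier"] = self.mask
        return df


def epoch_band_powers(ep: EpochArray, tukey_alpha: float = DEFAULT_TUKEY_ALPHA) -> np.ndarray:
    """Band power per epoch and channel: (n_epochs, n_channels, n_bands).

    Single-segment periodogram of the Tukey-windowed epoch (epochs are
    already short; no sub-segmentation), integrated by the trapezoidal
    rule over PSD bins whose centers fall in [low, high). Zeroed epochs
    yield zero power in every band.
    """
    fs = ep.sampling_rate_hz
    freqs, psd = signal.periodogram(
        ep.epochs, fs=fs, window=("tukey", tukey_alpha), axis=-1, detrend=False
    )
    out = np.empty(ep.epochs.shape[:2] + (len(BANDS),))
    for b, (_, lo, hi) in enumerate(BANDS):
        sel = (freqs >= lo) & (freqs < hi)
        out[..., b] = np.trapezoid(psd[..., sel], freqs[sel], axis=-1)
    return out


def relative_gamma(p_gamma, p_alpha, p_theta):
    """RG = P_Gamma / (P_Alpha + P_Theta); 0 where the denominator is 0."""
    p_gamma = np.asarray(p_gamma, dtype=float)
    denom = np.asarray(p_alpha, dtype=float) + np.asarray(p_theta, dtype=float)
    out = np.divide(p_gamma, denom, out=np.zeros_like(p_gamma + denom), where=denom > 0)
    return float(out) if out.ndim == 0 else out


def alpha_asymmetry(p_alpha_f6, p_alpha_f5):
    """AA = P_Alpha(F6) - P_Alpha(F5): right-minus-left frontal alpha."""
    return np.asarray(p_alpha_f6, dtype=float) - np.asarray(p_alpha_f5, dtype=float)


def assemble_features(
    ep: EpochArray,
    powers: np.ndarray | None = None,
    phase_offset_s: float = 0.0,
    tukey_alpha: float = DEFAULT_TUKEY_ALPHA,
) -> FeatureMatrix:
    """Build the per-phase feature matrix from an epoch array.

    Band-power columns are the mean over the four channels; RG uses the
    channel-averaged powers; AA uses the channel-specific alpha powers
    at F6 and F5.
    """
    for required in ("F5", "F6"):
        if required not in ep.channels:
            raise ValueError(f"channel {required!r} required for alpha asymmetry")
    if powers is None:
        powers = epoch_band_powers(ep, tukey_alpha)
    mean_powers = powers.mean(axis=1)  # (n_epochs, n_bands)
    band_idx = {name: i for i, name in enumerate(BAND_NAMES)}
    rg = relative_gamma(
        mean_powers[:, band_idx["Gamma"]],
        mean_powers[:, band_idx["Alpha"]],
        mean_powers[:, band_idx["Theta"]],
    )
    i_f5, i_f6 = ep.channels.index("F5"), ep.channels.index("F6")
    aa = alpha_asymmetry(powers[:, i_f6, band_idx["Alpha"]], powers[:, i_f5, band_idx["Alpha"]])
    values = np.column_stack([mean_powers, rg, aa])
    starts = phase_offset_s + np.arange(ep.n_epochs) * ep.epoch_s
    return FeatureMatrix(
        values=values,
        phase=np.full(ep.n_epochs, ep.phase, dtype=object),
        epoch_start_s=starts,
        mask=ep.outlier_mask.copy(),
    )


def concat_features(matrices: list[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate per-phase feature matrices in session order."""
    return FeatureMatrix(
        values=np.vstack([m.values for m in matrices]),
        phase=np.concatenate([m.phase for m in matrices]),
        epoch_start_s=np.concatenate([m.epoch_start_s for m in matrices]),
        mask=np.concatenate([m.mask for m in matrices]),
    )


def smooth_features(
    fm: FeatureMatrix, window_s: float = DEFAULT_SMOOTH_WINDOW_S, epoch_s: float = EPOCH_S
) -> FeatureMatrix:
    """Centered moving average of each feature column, per phase.

    The 30-s default spans 15 epochs. The window is truncated (shrinks)
    at phase boundaries, so smoothing never mixes values across
    recordings and introduces no phase lag.
    """
    window = int(round(window_s / epoch_s))
    if window < 1:
        raise ValueError("smoothing window must cover at least one epoch")
    out = np.empty_like(fm.values)
    for ph in pd.unique(fm.phase):
        rows = fm.phase == ph
        block = pd.DataFrame(fm.values[rows])
        out[rows] = block.rolling(window, center=True, min_periods=1).mean().to_numpy()
    return FeatureMatrix(out, fm.phase.copy(), fm.epoch_start_s.copy(), fm.mask.copy())
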