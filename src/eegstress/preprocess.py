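"""Per-recording EEG conditioning, from raw microvolts to clean 2-s epochs.

The chain, applied independently to each phase recording, is:

    notch (48-52 Hz) -> bandpass (2-48 Hz, zero-phase Butterworth)
    -> [central-minute trim, final rest only] -> resample to nominal length
    -> split into 2-s epochs -> zero epochs exceeding 75 uV
    -> per-epoch linear detrend + standardization

Filtering is zero-phase (forward-backward), so features stay aligned in
time with the self-report surveys. Recording lengths differ by a few
seconds because session onsets are marked manually; resampling forces
every phase to its nominal sample count so epoch counts are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .schedule import EPOCH_S, SAMPLING_RATE_HZ

OUTLIER_THRESHOLD_UV: float = 75.0
CHANNELS = ("Fp1", "Fp2", "F5", "F6")


@dataclass
class Recording:
    """One phase's continuous multichannel EEG.

    data is (n_channels, n_samples) in microvolts; nominal_duration_s is
    the processed duration the phase should span after resampling.
    """

    data: np.ndarray
    sampling_rate_hz: float
    channels: tuple[str, ...]
    phase: str
    nominal_duration_s: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, n_samples)")
        self.channels = tuple(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class EpochArray:
    """Non-overlapping 2-s epochs: (n_epochs, n_channels, samples_per_epoch).

    outlier_mask flags epochs zeroed by amplitude rejection (or degenerate
    zero-variance epochs); masked epochs are identically zero.
    """

    epochs: np.ndarray
    outlier_mask: np.ndarray
    channels: tuple[str, ...]
    phase: str
    epoch_s: float = EPOCH_S
    sampling_rate_hz: float = SAMPLING_RATE_HZ

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if self.outlier_mask.shape != (self.epochs.shape[0],):
            raise ValueError("outlier_mask must have one flag per epoch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def _check_finite(rec: Recording) -> None:
    if not np.isfinite(rec.data).all():
        raise ValueError(f"non-finite samples in {rec.phase!r} recording")


def notch_filter(rec: Recording, stopband_hz: tuple[float, float] = (48.0, 52.0)) -> Recording:
    """Suppress power-line coupling with a zero-phase band-stop filter.

    A 2nd-order Butterworth band-stop over the stopband, applied
    forward-backward; 50 Hz is attenuated by far more than 20 dB while
    the EEG passband is left essentially untouched.
    """
    _check_finite(rec)
    sos = signal.butter(2, stopband_hz, btype="bandstop", fs=rec.sampling_rate_hz, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=out)


def bandpass_filter(rec: Recording, band_hz: tuple[float, float] = (2.0, 48.0)) -> Recording:
    """Retain EEG spectral content with a 4th-order zero-phase Butterworth.

    The 4th-order design is applied forward-backward (zero phase shift,
    effective 8th-order magnitude response), removing slow drifts below
    2 Hz and content above 48 Hz.
    """
    _check_finite(rec)
    sos = signal.butter(4, band_hz, btype="bandpass", fs=rec.sampling_rate_hz, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=out)


def resample_to_nominal(rec: Recording, tolerance: float = 0.10) -> Recording:
    """Resample so the recording spans exactly its nominal duration.

    Rational-factor polyphase resampling to hit the exact nominal sample
    count (nominal_duration_s * sampling_rate). Lengths further than
    ``tolerance`` (fraction) from nominal indicate a corrupt recording
    and are rejected.
    """
    target = int(round(rec.nominal_duration_s * rec.sampling_rate_hz))
    current = rec.n_samples
    if current == target:
        return replace(rec, data=rec.data.copy())
    if abs(current - target) / target > tolerance:
        raise ValueError(
            f"{rec.phase!r} recording spans {current / rec.sampling_rate_hz:.1f} s; "
            f"outside ±{tolerance:.0%} of nominal {rec.nominal_duration_s:.1f} s"
        )
    g = math.gcd(target, current)
    up, down = target // g, current // g
    if max(up, down) <= 4096:
        out = signal.resample_poly(rec.data, up, down, axis=1)
    else:  # irrational-looking ratio: Fourier resampling, identical band content
        out = signal.resample(rec.data, target, axis=1)
    out = out[:, :target]
    if out.shape[1] != target:  # pragma: no cover - resample_poly guarantees ceil
        raise RuntimeError("resampling failed to reach nominal length")
    return replace(rec, data=out)


def extract_central_minute(rec: Recording, window_s: float = 60.0) -> Recording:
    """Return the centered 60-s window of a final-rest recording."""
    n_window = int(round(window_s * rec.sampling_rate_hz))
    if rec.n_samples < n_window:
        raise ValueError(
            f"recording spans {rec.duration_s:.1f} s; cannot extract {window_s:.0f}-s central window"
        )
    start = (rec.n_samples - n_window) // 2
    return replace(rec, data=rec.data[:, start : start + n_window].copy())


def epoch(rec: Recording, epoch_s: float = EPOCH_S) -> EpochArray:
    """Split a resampled recording into consecutive, non-overlapping epochs."""
    samples_per_epoch = int(round(epoch_s * rec.sampling_rate_hz))
    if rec.n_samples % samples_per_epoch != 0:
        raise ValueError(
            f"{rec.phase!r} length {rec.n_samples} is not a multiple of the "
            f"{samples_per_epoch}-sample epoch; resample to nominal first"
        )
    n_epochs = rec.n_samples // samples_per_epoch
    epochs = rec.data.reshape(len(rec.channels), n_epochs, samples_per_epoch).swapaxes(0, 1).copy()
    return EpochArray(
        epochs=epochs,
        outlier_mask=np.zeros(n_epochs, dtype=bool),
        channels=rec.channels,
        phase=rec.phase,
        epoch_s=epoch_s,
        sampling_rate_hz=rec.sampling_rate_hz,
    )


def zero_outlier_epochs(ep: EpochArray, threshold_uv: float = OUTLIER_THRESHOLD_UV) -> EpochArray:
    """Zero (and flag) every epoch whose amplitude exceeds the threshold.

    Exceedance on any channel zeroes the whole epoch across channels:
    the artifact rejection acts on epochs, not channel-epochs.
    """
    peak = np.abs(ep.epochs).max(axis=(1, 2))
    mask = peak > threshold_uv
    out = ep.epochs.copy()
    out[mask] = 0.0
    return EpochArray(out, ep.outlier_mask | mask, ep.channels, ep.phase, ep.epoch_s, ep.sampling_rate_hz)


def detrend_standardize(ep: EpochArray, atol: float = 1e-12) -> EpochArray:
    """Per channel-epoch: remove the least-squares line, then z-score.

    Masked (zeroed) epochs pass through unchanged. A channel-epoch that is
    constant after detrending (zero variance, e.g. a pure ramp) is
    degenerate: the whole epoch is zeroed and added to the outlier mask
    rather than dividing by zero.
    """
    out = ep.epochs.copy()
    mask = ep.outlier_mask.copy()
    live = ~mask
    if live.any():
        x = out[live]  # (m, ch, n)
        x = signal.detrend(x, axis=-1, type="linear")
        x -= x.mean(axis=-1, keepdims=True)
        sd = x.std(axis=-1, keepdims=True)
        degenerate = (sd.squeeze(-1) <= atol).any(axis=-1)  # any flat channel
        sd[sd <= atol] = 1.0
        x /= sd
        x[degenerate] = 0.0
        out[live] = x
        idx = np.flatnonzero(live)[degenerate]
        mask[idx] = True
    return EpochArray(out, mask, ep.channels, ep.phase, ep.epoch_s, ep.sampling_rate_hz)


def preprocess_recording(
    rec: Recording,
    threshold_uv: float = OUTLIER_THRESHOLD_UV,
    notch_hz: tuple[float, float] = (48.0, 52.0),
    band_hz: tuple[float, float] = (2.0, 48.0),
) -> EpochArray:
    """Run the full per-recording chain and return clean standardized epochs.

    Final-rest recordings (longer than their nominal processed duration by
    more than the resampling tolerance) are trimmed to their central
    minute after filtering and before resampling.
    """
    rec = notch_filter(rec, notch_hz)
    rec = bandpass_filter(rec, band_hz)
    if rec.duration_s > rec.nominal_duration_s * 1.5:
        rec = extract_central_minute(rec, rec.nominal_duration_s)
    rec = resample_to_nominal(rec)
    ep = epoch(rec)
    ep = zero_outlier_epochs(ep, threshold_uv)
    return detrend_standardize(ep)
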