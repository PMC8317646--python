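"""Protocol-faithful synthetic stress-relax sessions.

Real sessions from the study are not deposited, so this module generates
surrogate sessions with the same structure: one EEG recording per phase
(4 frontal channels at 256 Hz, microvolts), a latent stress trajectory
that rises through the arithmetic stressor and decays through VR
relaxation, and the eight 1-5 self-report survey answers that quantize
that trajectory.

The EEG is a sum of band-limited noise components whose per-band
variance follows ``baseline * (1 + coupling * normalized_stress)``, plus
a 50 Hz line-noise sinusoid and sporadic high-amplitude artifact bursts
(> 75 uV) injected on the nominal epoch grid. Recording lengths carry a
few seconds of jitter, as in the study, to exercise resampling.

This generator makes no attempt at cortical source realism, blink/EMG
artifact morphology, or inter-channel covariance; every channel is an
independent noise mixture sharing only the stress coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .features import BAND_NAMES, BANDS
from .preprocess import CHANNELS, OUTLIER_THRESHOLD_UV, Recording
from .schedule import RAW_DURATIONS_S, SessionSchedule

#: default per-band baseline power, uV^2 (variance of the band component)
DEFAULT_BASELINE = {"Delta": 30.0, "Theta": 20.0, "Alpha": 25.0, "Beta": 15.0, "Gamma": 10.0}
#: default stress -> band-power coupling (gain per unit normalized stress)
DEFAULT_COUPLING = {"Delta": 0.0, "Theta": 0.0, "Alpha": -0.5, "Beta": 0.8, "Gamma": 1.5}
#: piecewise-linear latent stress anchors: (session time s, SPSL 1-5).
#: Rest baseline ~1.4, monotone rise to a peak of 4.6 at the end of the
#: MIST test (T4), decay through relaxation, settling near baseline.
#: Anchor levels avoid half-integers so quantized answers are unambiguous.
DEFAULT_TRAJECTORY = ((0.0, 1.4), (360.0, 4.6), (660.0, 1.8), (720.0, 1.6))


@dataclass
class SynthConfig:
    """Knobs of the synthetic session generator.

    seed drives every random draw; artifact_amplitude_uv must exceed the
    75 uV rejection threshold so injected bursts are recoverable;
    survey_jitter_prob adds +/-1 reporting noise to the quantized survey
    answers; length_jitter_s draws a whole-second offset per recording.
    """

    seed: int = 0
    baseline_power: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    coupling: dict = field(default_factory=lambda: dict(DEFAULT_COUPLING))
    line_noise_uv: float = 5.0
    line_noise_hz: float = 50.0
    artifact_prob: float = 0.05
    artifact_amplitude_uv: float = 150.0
    survey_jitter_prob: float = 0.0
    length_jitter_s: float = 3.0
    trajectory: tuple = DEFAULT_TRAJECTORY
    channel_band_gain: dict | None = None  # e.g. {"F6": {"Alpha": 2.0}}

    def __post_init__(self):
        coup = np.array([self.coupling.get(b, 0.0) for b in BAND_NAMES], dtype=float)
        if not np.isfinite(coup).all():
            raise ValueError("coupling coefficients must be finite")
        base = np.array([self.baseline_power.get(b, 0.0) for b in BAND_NAMES], dtype=float)
        if (base < 0).any() or not np.isfinite(base).all():
            raise ValueError("baseline powers must be finite and non-negative")
        if self.artifact_prob > 0 and self.artifact_amplitude_uv <= OUTLIER_THRESHOLD_UV:
            raise ValueError(
                f"artifact amplitude must exceed the {OUTLIER_THRESHOLD_UV:.0f} uV outlier threshold"
            )
        levels = np.array([v for _, v in self.trajectory], dtype=float)
        if (levels < 1).any() or (levels > 5).any():
            raise ValueError("stress trajectory values must lie in [1, 5]")
        times = np.array([t for t, _ in self.trajectory], dtype=float)
        if (np.diff(times) <= 0).any():
            raise ValueError("trajectory anchor times must be strictly increasing")

    @classmethod
    def strong_coupling(cls, seed: int = 0) -> "SynthConfig":
        """A low-noise, strongly coupled condition for recovery studies:
        no line noise or artifacts, no survey jitter, amplified couplings."""
        return cls(
            seed=seed,
            coupling={"Delta": 0.0, "Theta": -0.3, "Alpha": -0.7, "Beta": 1.2, "Gamma": 2.5},
            line_noise_uv=0.0,
            artifact_prob=0.0,
            survey_jitter_prob=0.0,
        )


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline tries to recover."""

    trajectory: np.ndarray  # latent stress at each nominal epoch center, length n_epochs
    survey_answers: np.ndarray  # 8 integers in [1, 5]
    survey_times_s: np.ndarray
    artifact_epochs: dict  # phase -> sorted nominal epoch indices with injected bursts
    phase_epochs: dict = field(default_factory=dict)  # phase -> nominal epoch count

    @property
    def session_artifact_epochs(self) -> np.ndarray:
        """Artifact epoch indices on the concatenated session grid."""
        out, offset = [], 0
        for phase, n in self.phase_epochs.items():
            out.extend(offset + np.asarray(self.artifact_epochs.get(phase, []), dtype=int))
            offset += n
        return np.array(sorted(out), dtype=int)


def stress_at(times_s, trajectory=DEFAULT_TRAJECTORY) -> np.ndarray:
    """Latent stress level at session times, by piecewise-linear anchors."""
    t = np.array([a for a, _ in trajectory])
    v = np.array([b for _, b in trajectory])
    return np.interp(np.asarray(times_s, dtype=float), t, v)


def _band_noise(rng: np.random.Generator, n: int, lo: float, hi: float, fs: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (4th-order Butterworth)."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _artifact_burst(n_burst: int, fs: float, amplitude: float) -> np.ndarray:
    """A Tukey-tapered 10 Hz burst that survives the 2-48 Hz bandpass."""
    t = np.arange(n_burst) / fs
    return amplitude * signal.windows.tukey(n_burst, 0.5) * np.sin(2 * np.pi * 10.0 * t)


def simulate_session(
    schedule: SessionSchedule, config: SynthConfig
) -> tuple[list[Recording], GroundTruth]:
    """Generate one synthetic session: one Recording per phase + ground truth.

    Determinism: identical (schedule, config) give bit-identical output.
    Artifact bursts are positioned on the nominal epoch grid (scaled by
    the actual/nominal length ratio), so after resampling each burst
    lands exactly in its intended 2-s epoch.
    """
    rng = np.random.default_rng(config.seed)
    fs = schedule.sampling_rate_hz
    recordings: list[Recording] = []
    artifact_epochs: dict[str, list[int]] = {}
    phase_epochs: dict[str, int] = {}

    for ph in schedule.phases:
        raw_nominal = RAW_DURATIONS_S.get(ph.name, ph.duration_s)
        j = int(config.length_jitter_s)
        jitter = int(rng.integers(-j, j + 1)) if j else 0
        duration = raw_nominal + jitter
        n = int(round(duration * fs))
        # Session time of each raw sample after trimming+resampling. Phases
        # longer than nominal keep a centered nominal-length window (central
        # minute of the final rest); others map linearly onto the nominal
        # span via resampling. Samples outside the kept window are clamped.
        if raw_nominal > ph.duration_s:
            window, start = ph.duration_s, (duration - ph.duration_s) / 2.0
        else:
            window, start = float(duration), 0.0
        t_raw = np.arange(n) / fs
        t_nominal = (t_raw - start) * (ph.duration_s / window)
        t_session = schedule.phase_offset_s(ph.name) + np.clip(t_nominal, 0.0, ph.duration_s)
        s_norm = (stress_at(t_session, config.trajectory) - 1.0) / 4.0

        data = np.empty((len(CHANNELS), n))
        for c, ch in enumerate(CHANNELS):
            x = np.zeros(n)
            for (band, lo, hi) in BANDS:
                base = config.baseline_power.get(band, 0.0)
                if base == 0.0:
                    continue
                coup = config.coupling.get(band, 0.0)
                gain = 1.0
                if config.channel_band_gain:
                    gain = config.channel_band_gain.get(ch, {}).get(band, 1.0)
                variance = base * gain * np.clip(1.0 + coup * s_norm, 0.0, None)
                x += np.sqrt(variance) * _band_noise(rng, n, lo, hi, fs)
            if config.line_noise_uv:
                x += config.line_noise_uv * np.sin(2 * np.pi * config.line_noise_hz * t_raw)
            data[c] = x

        # artifact injection on the nominal epoch grid of this phase
        hit: list[int] = []
        n_ep = ph.n_epochs
        draws = rng.random(n_ep)
        if config.artifact_prob > 0:
            scale = window / ph.duration_s  # nominal seconds -> raw seconds
            burst_s = 1.2
            for k in np.flatnonzero(draws < config.artifact_prob):
                center_raw = start + ((k + 0.5) * schedule.epoch_s) * scale
                n_burst = int(round(burst_s * scale * fs))
                i0 = int(round(center_raw * fs)) - n_burst // 2
                if i0 < 0 or i0 + n_burst > n:
                    continue
                data[:, i0 : i0 + n_burst] += _artifact_burst(n_burst, fs, config.artifact_amplitude_uv)
                hit.append(int(k))
        artifact_epochs[ph.name] = sorted(hit)
        phase_epochs[ph.name] = n_ep

        recordings.append(
            Recording(
                data=data,
                sampling_rate_hz=fs,
                channels=CHANNELS,
                phase=ph.name,
                nominal_duration_s=ph.duration_s,
            )
        )

    epoch_centers = (np.arange(schedule.n_epochs) + 0.5) * schedule.epoch_s
    trajectory = stress_at(epoch_centers, config.trajectory)
    survey_times = np.asarray(schedule.survey_times_s)
    answers = np.clip(np.rint(stress_at(survey_times, config.trajectory)), 1, 5).astype(int)
    if config.survey_jitter_prob > 0:
        flips = rng.random(len(answers)) < config.survey_jitter_prob
        steps = rng.choice([-1, 1], size=len(answers))
        answers = np.clip(answers + flips * steps, 1, 5).astype(int)

    truth = GroundTruth(
        trajectory=trajectory,
        survey_answers=answers,
        survey_times_s=survey_times,
        artifact_epochs=artifact_epochs,
        phase_epochs=phase_epochs,
    )
    return recordings, truth
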