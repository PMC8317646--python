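"""Session schedule: phases, survey instants and the epoch timeline.

A stress-relax session is processed as three consecutive recordings —
a 6-min arithmetic stressor (MIST test), a 5-min relaxation phase, and
the central minute of a final eyes-closed rest — for 12 min of signal
in total. Eight self-perceived stress level (SPSL) surveys, T1..T8, are
anchored to instants of this timeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

EPOCH_S: float = 2.0
SAMPLING_RATE_HZ: float = 256.0

#: raw recording duration per phase, before any trimming (seconds).
#: The final rest is captured at ~120 s; only its central minute is kept.
RAW_DURATIONS_S = {"mist_test": 360.0, "relax": 300.0, "rest2_central": 120.0}


@dataclass(frozen=True)
class Phase:
    """One processed phase: name and nominal processed duration in seconds."""

    name: str
    duration_s: float

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_s / EPOCH_S))


@dataclass(frozen=True)
class Survey:
    """A survey instant, anchored as an offset into one phase."""

    survey_id: str
    phase: str
    offset_s: float


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered phases plus the survey instants on the session timeline."""

    phases: tuple[Phase, ...]
    surveys: tuple[Survey, ...]
    epoch_s: float = EPOCH_S
    sampling_rate_hz: float = SAMPLING_RATE_HZ
    _offsets: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        names = [p.name for p in self.phases]
        if len(set(names)) != len(names):
            raise ValueError("phase names must be unique")
        offsets, t = {}, 0.0
        for p in self.phases:
            offsets[p.name] = t
            t += p.duration_s
        object.__setattr__(self, "_offsets", offsets)
        for s in self.surveys:
            if s.phase not in offsets:
                raise ValueError(f"survey {s.survey_id} references unknown phase {s.phase!r}")
            dur = self.phase(s.phase).duration_s
            if not 0.0 <= s.offset_s <= dur:
                raise ValueError(f"survey {s.survey_id} offset {s.offset_s} outside phase {s.phase!r}")
        times = [self.survey_time_s(s.survey_id) for s in self.surveys]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("survey times must be strictly increasing")

    def phase(self, name: str) -> Phase:
        for p in self.phases:
            if p.name == name:
                return p
        raise KeyError(name)

    def phase_offset_s(self, name: str) -> float:
        """Start of a phase on the concatenated (processed) session timeline."""
        return self._offsets[name]

    @property
    def total_duration_s(self) -> float:
        return sum(p.duration_s for p in self.phases)

    @property
    def n_epochs(self) -> int:
        return sum(p.n_epochs for p in self.phases)

    def survey_time_s(self, survey_id: str) -> float:
        for s in self.surveys:
            if s.survey_id == survey_id:
                return self.phase_offset_s(s.phase) + s.offset_s
        raise KeyError(survey_id)

    @property
    def survey_times_s(self) -> list[float]:
        return [self.survey_time_s(s.survey_id) for s in self.surveys]

    @property
    def survey_ids(self) -> list[str]:
        return [s.survey_id for s in self.surveys]


def build_default_schedule() -> SessionSchedule:
    """The study's schedule: 360 s MIST test + 300 s relaxation + 60 s rest.

    T1 was answered at the end of the (withdrawn) initial rest and is
    anchored to the start of the processed timeline; T4/T7/T8 at the end
    of their phase; T2/T3 at 120/240 s into the MIST test; T5/T6 at
    90/180 s into relaxation.
    """
    phases = (
        Phase("mist_test", 360.0),
        Phase("relax", 300.0),
        Phase("rest2_central", 60.0),
    )
    surveys = (
        Survey("T1", "mist_test", 0.0),
        Survey("T2", "mist_test", 120.0),
        Survey("T3", "mist_test", 240.0),
        Survey("T4", "mist_test", 360.0),
        Survey("T5", "relax", 90.0),
        Survey("T6", "relax", 180.0),
        Survey("T7", "relax", 300.0),
        Survey("T8", "rest2_central", 60.0),
    )
    return SessionSchedule(phases=phases, surveys=surveys)
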