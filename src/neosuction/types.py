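"""Domain types for resuscitation episodes.

Time is measured in seconds since birth; intervals are half-open
``[start, stop)`` so that an event ending at *t* and one starting at *t* do
not overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence


class EventKind(str, Enum):
    SUCTION_INSERTION = "suction_insertion"
    VENTILATION = "ventilation"
    STIMULATION = "stimulation"
    COVERING = "covering"


class Site(str, Enum):
    MOUTH = "mouth"
    NOSE = "nose"
    UNKNOWN = "unknown"


class Device(str, Enum):
    BULB = "bulb"
    CATHETER = "catheter"
    UNKNOWN = "unknown"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class Outcome(str, Enum):
    DIED_3D = "died_3d"
    SURVIVED = "survived"


class AmnioticFluid(str, Enum):
    """Amniotic fluid category; thick meconium and blood-stained are pooled."""

    CLEAR = "clear"
    SLIGHT = "slight"
    THICK_BLOOD = "thick_blood"


class ResponseLabel(str, Enum):
    SUCTION_RELATED_FALL = "SUCTION_RELATED_FALL"
    SUCTION_RELATED_ARRHYTHMIA = "SUCTION_RELATED_ARRHYTHMIA"
    VENT_CESSATION_FALL = "VENT_CESSATION_FALL"
    NO_CHANGE = "NO_CHANGE"
    INDETERMINATE = "INDETERMINATE"

    @property
    def suction_related(self) -> bool:
        return self in (
            ResponseLabel.SUCTION_RELATED_FALL,
            ResponseLabel.SUCTION_RELATED_ARRHYTHMIA,
        )


@dataclass(frozen=True)
class IntervalEvent:
    """One annotated interval: a suction insertion, ventilation bout,
    stimulation bout or covering period, in seconds since birth."""

    kind: EventKind
    start_s: float
    stop_s: float
    site: Site = Site.UNKNOWN
    device: Device = Device.UNKNOWN
    obscured: bool = False

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s

    def overlaps(self, start: float, stop: float) -> bool:
        """True iff the half-open interval [start, stop) intersects this event."""
        return self.start_s < stop and start < self.stop_s


@dataclass(frozen=True)
class HRSample:
    t_s: float
    hr_bpm: float


@dataclass(frozen=True)
class BeatSeries:
    """Beat (QRS) times in seconds; RR intervals are successive differences."""

    beat_times_s: tuple[float, ...]

    def __init__(self, beat_times_s: Sequence[float]):
        object.__setattr__(self, "beat_times_s", tuple(float(t) for t in beat_times_s))

    def rr_intervals(self) -> list[float]:
        t = self.beat_times_s
        return [t[i + 1] - t[i] for i in range(len(t) - 1)]


@dataclass
class EpisodeRecord:
    """One newborn: covariates, outcome, annotation timeline and signals."""

    newborn_id: str
    outcome: Outcome
    birthweight_g: float
    ga_weeks: float
    sex: Sex
    amniotic_fluid: AmnioticFluid
    first_hr_bpm: float
    ventilated_flag: bool
    events: list[IntervalEvent] = field(default_factory=list)
    hr_series: list[HRSample] = field(default_factory=list)
    beats: Optional[BeatSeries] = None

    @property
    def duration_s(self) -> float:
        """Episode span: latest of last event stop and last HR sample time."""
        stops = [e.stop_s for e in self.events] + [s.t_s for s in self.hr_series]
        return max(stops) if stops else 0.0

    def events_of_kind(self, kind: EventKind) -> list[IntervalEvent]:
        return sorted(
            (e for e in self.events if e.kind is kind), key=lambda e: e.start_s
        )


@dataclass(frozen=True)
class SuctionEvent:
    """A maximal run of suction insertions separated by pauses of at most
    ``max_pause_s``; spans from the first insertion's start to the last
    insertion's stop."""

    start_s: float
    stop_s: float
    insertions: tuple[IntervalEvent, ...]

    @classmethod
    def from_insertions(cls, insertions: Sequence[IntervalEvent]) -> "SuctionEvent":
        if not insertions:
            raise ValueError("a suction event requires at least one insertion")
        ins = tuple(sorted(insertions, key=lambda e: (e.start_s, e.stop_s)))
        return cls(
            start_s=min(e.start_s for e in ins),
            stop_s=max(e.stop_s for e in ins),
            insertions=ins,
        )

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s

    @property
    def device_set(self) -> frozenset[Device]:
        return frozenset(e.device for e in self.insertions)

    @property
    def any_catheter(self) -> bool:
        return Device.CATHETER in self.device_set

    @property
    def n_mouth(self) -> int:
        return sum(1 for e in self.insertions if e.site is Site.MOUTH)

    @property
    def n_nose(self) -> int:
        return sum(1 for e in self.insertions if e.site is Site.NOSE)


@dataclass
class SEResponse:
    """Classified heart-rate response of one suction event."""

    se: SuctionEvent
    label: ResponseLabel
    pre_hr_bpm: Optional[float] = None
    post_hr_bpm: Optional[float] = None
    delta_hr_bpm: Optional[float] = None
    fall_fraction_observed: Optional[float] = None
    concurrent_ventilation: bool = False
    ventilation_prior: bool = False
    stimulation_prior: bool = False


_SUCTION_ONLY = "site/device may only be set on suction insertions"


def _check_interval(i: int, e: IntervalEvent, out: list[str]) -> None:
    if not (0 <= e.start_s < e.stop_s):
        out.append(
            f"event[{i}] ({e.kind.value}): requires 0 <= start_s < stop_s, "
            f"got [{e.start_s}, {e.stop_s})"
        )
    if e.kind is not EventKind.SUCTION_INSERTION and (
        e.site is not Site.UNKNOWN or e.device is not Device.UNKNOWN
    ):
        out.append(f"event[{i}] ({e.kind.value}): {_SUCTION_ONLY}")


def validate_episode(episode: EpisodeRecord) -> list[str]:
    """Check all type invariants; return human-readable violations.

    Pure and non-mutating: an empty list means the episode is well formed.
    """
    v: list[str] = []
    if not episode.newborn_id:
        v.append("newborn_id is empty")
    if not 1000 <= episode.birthweight_g <= 6000:
        v.append(f"birthweight_g {episode.birthweight_g} outside plausible 1000-6000 g")
    if not episode.ga_weeks >= 34:
        v.append(f"ga_weeks {episode.ga_weeks} below study threshold of 34 weeks")
    if not 0 < episode.first_hr_bpm <= 300:
        v.append(f"first_hr_bpm {episode.first_hr_bpm} outside (0, 300]")
    for i, e in enumerate(episode.events):
        _check_interval(i, e, v)
    last_t = -math.inf
    for i, s in enumerate(episode.hr_series):
        if not 0 < s.hr_bpm <= 300:
            v.append(f"hr_series[{i}]: hr_bpm {s.hr_bpm} outside (0, 300]")
        if s.t_s <= last_t:
            v.append(
                f"hr_series[{i}]: t_s {s.t_s} not strictly increasing "
                f"(previous {last_t})"
            )
        last_t = s.t_s
    if episode.beats is not None:
        rr = episode.beats.rr_intervals()
        for i, d in enumerate(rr):
            if d <= 0:
                v.append(f"beats: interval {i} non-increasing (rr={d})")
            elif not 0.2 < d < 3.0:
                v.append(f"beats: rr interval {i} = {d:.3f} s outside (0.2, 3) s")
    return v
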