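"""Seeded synthetic workers: ground-truth diaries and noisy GPS traces.

No real fix streams ship with the package, so this module simulates the
data regime the pipeline is built for: a phone sampling location every 10
minutes while its owner commutes between home, one or more hospital
campuses, lunch spots, and on-call nights.  From a persona (resident,
nurse, visiting staff, or non-healthcare office worker) it draws

* a ground-truth diary — exact presence blocks at each workplace, with
  arrival/departure jitter, overtime tails, sub-8-hour lunch or lecture
  excursions, and overnight presence on first-line on-call duty — plus the
  matching declared :class:`~staffhours.schedule.ScheduleSpec`;
* a GPS trace — fixes on a regular cadence located at the active workplace
  (or home, or an excursion point) with isotropic Gaussian positional noise
  and independent dropout.

Everything is driven by one integer seed: the same
:class:`SimulationParams` always reproduce the same diary and trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Optional, Sequence

import numpy as np

from .geo import EARTH_RADIUS_KM, GeofenceSet, GeoPoint, Workplace
from .intervals import WorkInterval
from .schedule import OnCallAssignment, RegularSchedule, ScheduleSpec
from .sessions import GpsFix, merge_sessions
from .validation import DiaryEntry

__all__ = [
    "Persona",
    "PERSONAS",
    "SimulationParams",
    "PresenceBlock",
    "GroundTruthDiary",
    "default_layout",
    "generate_diary",
    "sample_trace",
]

#: metres of arc per degree of latitude on the reference sphere
_M_PER_DEG_LAT = EARTH_RADIUS_KM * 1000.0 * math.pi / 180.0


@dataclass(frozen=True)
class Persona:
    """Distributional presence/on-call tendencies of an occupation group."""

    regular_start: time
    regular_end: time
    workdays: frozenset[int]
    #: inclusive bounds on on-call duties per 28 days
    oncall_per_28: tuple[int, int]
    #: probability an on-call duty is first-line (in-house overnight)
    p_first_line: float
    #: probability of a lunch/lecture excursion outside the fence on a workday
    p_excursion: float
    #: mean of the exponential overtime tail after regular end, hours
    overtime_mean_h: float
    #: SD of arrival jitter around regular start, minutes
    arrival_jitter_min: float
    #: probability the post-lunch block moves to a second campus (if one exists)
    p_second_site: float


PERSONAS: dict[str, Persona] = {
    "resident": Persona(
        regular_start=time(8, 0), regular_end=time(18, 0),
        workdays=frozenset(range(5)), oncall_per_28=(4, 8),
        p_first_line=0.8, p_excursion=0.6, overtime_mean_h=1.5,
        arrival_jitter_min=10.0, p_second_site=0.2,
    ),
    "nurse": Persona(
        regular_start=time(8, 0), regular_end=time(16, 0),
        workdays=frozenset(range(5)), oncall_per_28=(0, 3),
        p_first_line=0.5, p_excursion=0.4, overtime_mean_h=0.7,
        arrival_jitter_min=8.0, p_second_site=0.0,
    ),
    "visiting": Persona(
        regular_start=time(8, 0), regular_end=time(17, 0),
        workdays=frozenset(range(5)), oncall_per_28=(1, 4),
        p_first_line=0.2, p_excursion=0.5, overtime_mean_h=1.0,
        arrival_jitter_min=12.0, p_second_site=0.3,
    ),
    "non_hcp": Persona(
        regular_start=time(9, 0), regular_end=time(18, 0),
        workdays=frozenset(range(5)), oncall_per_28=(0, 0),
        p_first_line=0.0, p_excursion=0.5, overtime_mean_h=0.5,
        arrival_jitter_min=10.0, p_second_site=0.0,
    ),
}


def default_layout() -> tuple[GeofenceSet, GeoPoint]:
    """Two hospital campuses ~2.5 km apart and a home ~5 km from both."""
    fences = GeofenceSet((
        Workplace("hospital_A", GeoPoint(25.0410, 121.5190), 1.0),
        Workplace("hospital_B", GeoPoint(25.0630, 121.5250), 1.0),
    ))
    home = GeoPoint(25.0050, 121.4650)
    return fences, home


@dataclass(frozen=True)
class SimulationParams:
    """Everything that determines one simulated worker-period."""

    seed: int
    n_days: int = 28
    cadence_minutes: float = 10.0
    noise_sigma_m: float = 50.0
    dropout_rate: float = 0.05
    persona: str = "resident"
    fences: Optional[GeofenceSet] = None
    home: Optional[GeoPoint] = None
    #: first simulated day; the default is a Monday so weeks align
    start_date: date = date(2022, 6, 6)

    def __post_init__(self) -> None:
        if self.persona not in PERSONAS:
            raise ValueError(f"unknown persona {self.persona!r}; choose from {sorted(PERSONAS)}")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1], got {self.dropout_rate}")
        if not self.cadence_minutes > 0:
            raise ValueError("cadence_minutes must be positive")
        if self.noise_sigma_m < 0:
            raise ValueError("noise_sigma_m must be nonnegative")
        if self.n_days < 1:
            raise ValueError("n_days must be at least 1")
        if self.fences is None or self.home is None:
            fences, home = default_layout()
            if self.fences is None:
                object.__setattr__(self, "fences", fences)
            if self.home is None:
                object.__setattr__(self, "home", home)


@dataclass(frozen=True)
class PresenceBlock:
    """A contiguous ground-truth stay at one workplace."""

    start: datetime
    end: datetime
    workplace_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"presence block requires start < end: {self}")


@dataclass(frozen=True)
class GroundTruthDiary:
    """The simulated truth: presence blocks plus the declared schedule."""

    blocks: tuple[PresenceBlock, ...]
    schedule: ScheduleSpec
    start_date: date
    n_days: int

    @property
    def t0(self) -> datetime:
        return datetime.combine(self.start_date, time(0, 0))

    @property
    def t1(self) -> datetime:
        return self.t0 + timedelta(days=self.n_days)

    def presence_intervals(self) -> list[WorkInterval]:
        return [WorkInterval(b.start, b.end, source="gps") for b in self.blocks]

    def work_intervals(self, merge_gap_hours: float = 8.0) -> list[WorkInterval]:
        """True presence with sub-``merge_gap_hours`` absences integrated —
        what a perfect detector should report."""
        return merge_sessions(self.presence_intervals(), merge_gap_hours)

    def to_diary_entries(self, merge_gap_hours: float = 8.0) -> list[DiaryEntry]:
        """Self-report-style entries: integrated work periods clipped at midnights."""
        per_day: dict[date, list[WorkInterval]] = {}
        for iv in self.work_intervals(merge_gap_hours):
            cur = iv.start
            while cur < iv.end:
                day_end = datetime.combine(cur.date() + timedelta(days=1), time(0, 0))
                piece_end = min(iv.end, day_end)
                per_day.setdefault(cur.date(), []).append(
                    WorkInterval(cur, piece_end, source="manual")
                )
                cur = piece_end
        return [DiaryEntry(day=d, intervals=tuple(ivs)) for d, ivs in sorted(per_day.items())]


def _round_minute(dt: datetime) -> datetime:
    return dt.replace(second=0, microsecond=0)


def generate_diary(params: SimulationParams) -> GroundTruthDiary:
    """Draw a seeded ground-truth diary and its declared schedule."""
    rng = np.random.default_rng([int(params.seed) % (2**31), 0])
    persona = PERSONAS[params.persona]
    fences = params.fences
    assert fences is not None
    primary = fences[0].id
    secondary = fences[1].id if len(fences) > 1 else None

    regular = RegularSchedule(persona.regular_start, persona.regular_end, persona.workdays)

    # on-call dates, scaled to the simulated horizon
    lo, hi = persona.oncall_per_28
    scale = params.n_days / 28.0
    lo_s, hi_s = int(round(lo * scale)), int(round(hi * scale))
    n_oncall = int(rng.integers(lo_s, hi_s + 1)) if hi_s > 0 else 0
    n_oncall = min(n_oncall, params.n_days)
    oncall_offsets = sorted(rng.choice(params.n_days, size=n_oncall, replace=False).tolist())
    assignments = []
    for off in oncall_offsets:
        line = "first_line" if rng.random() < persona.p_first_line else "second_line"
        assignments.append(OnCallAssignment(params.start_date + timedelta(days=off), line))
    spec = ScheduleSpec(regular=regular, on_call=tuple(assignments))
    first_line_dates = {a.date for a in assignments if a.line == "first_line"}

    blocks: list[PresenceBlock] = []
    for off in range(params.n_days):
        d = params.start_date + timedelta(days=off)
        workday = regular.is_workday(d)
        day_blocks: list[PresenceBlock] = []
        if workday:
            arrive = _round_minute(
                datetime.combine(d, regular.start_time)
                + timedelta(minutes=float(rng.normal(0.0, persona.arrival_jitter_min)))
            )
            depart = _round_minute(
                datetime.combine(d, regular.end_time)
                + timedelta(hours=min(float(rng.exponential(persona.overtime_mean_h)), 5.0))
            )
            if rng.random() < persona.p_excursion:
                lunch_start = _round_minute(
                    datetime.combine(d, time(11, 30))
                    + timedelta(minutes=float(rng.uniform(0.0, 90.0)))
                )
                lunch_end = _round_minute(
                    lunch_start + timedelta(minutes=float(rng.uniform(30.0, 90.0)))
                )
                pm_site = (
                    secondary
                    if secondary is not None and rng.random() < persona.p_second_site
                    else primary
                )
                if arrive < lunch_start and lunch_end < depart:
                    day_blocks.append(PresenceBlock(arrive, lunch_start, primary))
                    day_blocks.append(PresenceBlock(lunch_end, depart, pm_site))
                else:
                    day_blocks.append(PresenceBlock(arrive, depart, primary))
            else:
                day_blocks.append(PresenceBlock(arrive, depart, primary))
        if d in first_line_dates:
            # in-house overnight: physically present through the duty window
            if workday:
                duty_start = datetime.combine(d, regular.end_time)
            else:
                duty_start = datetime.combine(d, regular.start_time)
            duty_end = (
                datetime.combine(d + timedelta(days=1), regular.start_time)
                if workday
                else duty_start + timedelta(hours=24)
            )
            day_blocks.append(PresenceBlock(duty_start, duty_end, primary))
        blocks.extend(day_blocks)

    # normalize: sort and coalesce overlapping/abutting stays (e.g. overtime
    # running into an on-call night, or a duty night running into the next
    # morning's arrival)
    blocks.sort(key=lambda b: b.start)
    merged: list[PresenceBlock] = []
    for b in blocks:
        if merged and b.start <= merged[-1].end:
            prev = merged[-1]
            if b.end > prev.end:
                merged[-1] = PresenceBlock(prev.start, b.end, prev.workplace_id)
        else:
            merged.append(b)

    return GroundTruthDiary(
        blocks=tuple(merged),
        schedule=spec,
        start_date=params.start_date,
        n_days=params.n_days,
    )


def _offset_point(base: GeoPoint, east_m: float, north_m: float) -> GeoPoint:
    """Local-tangent-plane displacement; adequate at the few-km scale."""
    lat = base.latitude + north_m / _M_PER_DEG_LAT
    lon = base.longitude + east_m / (_M_PER_DEG_LAT * math.cos(math.radians(base.latitude)))
    return GeoPoint(lat, lon)


def sample_trace(diary: GroundTruthDiary, params: SimulationParams) -> list[GpsFix]:
    """Sample a noisy GPS trace of the diary at the configured cadence.

    Fix positions follow the true state at each tick: the active workplace
    centre during a presence block, a per-gap excursion point 1.2-3 km off
    campus during a sub-8-hour absence between blocks, and home otherwise.
    Isotropic Gaussian noise of scale ``noise_sigma_m`` is added per axis
    and fixes are dropped independently with probability ``dropout_rate``.
    """
    rng = np.random.default_rng([int(params.seed) % (2**31), 1])
    fences = params.fences
    home = params.home
    assert fences is not None and home is not None

    # one excursion point per sub-8-hour inter-block gap
    excursions: list[tuple[datetime, datetime, GeoPoint]] = []
    for a, b in zip(diary.blocks, diary.blocks[1:]):
        if timedelta(0) < b.start - a.start and (b.start - a.end) < timedelta(hours=8):
            dist = float(rng.uniform(1200.0, 3000.0))
            bearing = float(rng.uniform(0.0, 2.0 * math.pi))
            center = fences.by_id(a.workplace_id).center
            excursions.append(
                (a.end, b.start,
                 _offset_point(center, dist * math.sin(bearing), dist * math.cos(bearing)))
            )

    step = timedelta(minutes=params.cadence_minutes)
    n_ticks = int((diary.t1 - diary.t0) / step)
    noise = rng.normal(0.0, params.noise_sigma_m, size=(n_ticks, 2))
    keep = rng.random(n_ticks) >= params.dropout_rate

    fixes: list[GpsFix] = []
    bi = ei = 0
    blocks = diary.blocks
    for k in range(n_ticks):
        if not keep[k]:
            continue
        t = diary.t0 + k * step
        while bi < len(blocks) and blocks[bi].end <= t:
            bi += 1
        if bi < len(blocks) and blocks[bi].start <= t:
            base = fences.by_id(blocks[bi].workplace_id).center
        else:
            while ei < len(excursions) and excursions[ei][1] <= t:
                ei += 1
            if ei < len(excursions) and excursions[ei][0] <= t:
                base = excursions[ei][2]
            else:
                base = home
        p = _offset_point(base, noise[k, 0], noise[k, 1]) if params.noise_sigma_m > 0 else base
        fixes.append(GpsFix(t=t, p=p))
    return fixes
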