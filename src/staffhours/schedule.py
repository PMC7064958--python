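"""User-declared scheduled hours: weekday regular hours and dated on-call duties.

Medical rosters mix a fixed weekday shift with overnight or whole-day on-call
duties.  Two duty flavours exist: *first-line* (physically present in
hospital overnight) and *second-line* (home standby).  Both count fully
toward scheduled hours; the distinction matters for presence expectations,
not for duration.

On-call windows are derived, not entered:

* on a workday, the window runs from the end of regular hours to the start
  of regular hours the next day (e.g. 18:00 -> 08:00(+1), 14 h for an
  08:00-18:00 schedule);
* on a non-workday, the window is a full 24 h anchored at the regular
  start time (08:00 -> 08:00(+1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable, Optional

from .intervals import WorkInterval, clip, measure_hours

__all__ = [
    "RegularSchedule",
    "OnCallAssignment",
    "ScheduleSpec",
    "regular_window",
    "oncall_window",
    "scheduled_hours",
    "ON_CALL_LINES",
]

ON_CALL_LINES = ("first_line", "second_line")

#: Monday..Friday in datetime.weekday() numbering.
WEEKDAYS_MON_FRI = frozenset(range(5))


@dataclass(frozen=True)
class RegularSchedule:
    """Fixed daily start/finish clock times on a set of workdays.

    ``workdays`` uses ``datetime.weekday()`` numbering (Monday=0); the
    default is Monday-Friday.  ``start_time`` must precede ``end_time``
    within the day (overnight regular shifts are out of scope).
    """

    start_time: time
    end_time: time
    workdays: frozenset[int] = WEEKDAYS_MON_FRI

    def __post_init__(self) -> None:
        object.__setattr__(self, "workdays", frozenset(self.workdays))
        if not self.start_time < self.end_time:
            raise ValueError(
                f"regular hours require start < end within a day, "
                f"got {self.start_time}-{self.end_time}"
            )
        if not self.workdays <= set(range(7)):
            raise ValueError(f"workdays must be weekday numbers 0-6, got {self.workdays}")

    @property
    def daily_hours(self) -> float:
        d = datetime.combine(date(2000, 1, 3), self.end_time) - datetime.combine(
            date(2000, 1, 3), self.start_time
        )
        return d.total_seconds() / 3600.0

    def is_workday(self, d: date) -> bool:
        return d.weekday() in self.workdays


@dataclass(frozen=True)
class OnCallAssignment:
    """One dated on-call duty, first-line (in-house) or second-line (standby)."""

    date: date
    line: str

    def __post_init__(self) -> None:
        if self.line not in ON_CALL_LINES:
            raise ValueError(f"line must be one of {ON_CALL_LINES}, got {self.line!r}")


@dataclass(frozen=True)
class ScheduleSpec:
    """A worker's full declared schedule: regular hours plus on-call dates."""

    regular: RegularSchedule
    on_call: tuple[OnCallAssignment, ...] = field(default=())

    def __post_init__(self) -> None:
        assignments = tuple(self.on_call)
        object.__setattr__(self, "on_call", assignments)
        dates = [a.date for a in assignments]
        if len(set(dates)) != len(dates):
            raise ValueError(f"at most one on-call assignment per date; got duplicates in {dates}")

    def assignment_on(self, d: date) -> Optional[OnCallAssignment]:
        for a in self.on_call:
            if a.date == d:
                return a
        return None


def regular_window(d: date, spec: ScheduleSpec) -> Optional[WorkInterval]:
    """The regular-hours window on date ``d``, or ``None`` on a non-workday."""
    reg = spec.regular
    if not reg.is_workday(d):
        return None
    return WorkInterval(
        datetime.combine(d, reg.start_time),
        datetime.combine(d, reg.end_time),
        source="regular",
    )


def oncall_window(a: OnCallAssignment, spec: ScheduleSpec) -> WorkInterval:
    """The duty window implied by an on-call assignment.

    Workday: end of regular hours to start of regular hours next day.
    Non-workday: 24 hours from the regular start time.  The window duration
    does not depend on the duty line.
    """
    reg = spec.regular
    if reg.is_workday(a.date):
        start = datetime.combine(a.date, reg.end_time)
        end = datetime.combine(a.date + timedelta(days=1), reg.start_time)
    else:
        start = datetime.combine(a.date, reg.start_time)
        end = start + timedelta(hours=24)
    return WorkInterval(start, end, source="on_call")


def _windows_intersecting(
    t0: datetime, t1: datetime, spec: ScheduleSpec
) -> Iterable[WorkInterval]:
    """All regular and on-call windows that can intersect [t0, t1).

    Windows start no earlier than their date's 00:00 and extend at most
    24 h past the next midnight, so scanning one day on either side of the
    range covers every candidate.
    """
    d = t0.date() - timedelta(days=1)
    stop = t1.date() + timedelta(days=1)
    while d <= stop:
        w = regular_window(d, spec)
        if w is not None:
            yield w
        a = spec.assignment_on(d)
        if a is not None:
            yield oncall_window(a, spec)
        d += timedelta(days=1)


def scheduled_hours(t0: datetime, t1: datetime, spec: ScheduleSpec) -> float:
    """Union measure of regular and on-call windows clipped to ``[t0, t1)``.

    A weekday on-call window abuts that day's regular window exactly, so the
    union never double-counts; overlapping declarations would count once.
    """
    if not t0 < t1:
        raise ValueError(f"query range requires t0 < t1, got [{t0}, {t1})")
    return measure_hours(clip(_windows_intersecting(t0, t1, spec), (t0, t1)))
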