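"""Total work hours, overtime, and reports.

Total work hours are the union measure of three interval families clipped
to the query range:

1. merged GPS sessions (with any manually adjusted day's sessions replaced
   by the adjustment's intervals),
2. on-call duty windows for every assigned date — counted in full whether
   or not GPS places the worker inside a fence, because on-call duty does
   not always require physical presence,
3. the manual adjustment intervals themselves.

Overlaps count once, so the total never exceeds elapsed time.  Overtime is
the signed difference ``total - scheduled`` and may be negative.

Manual adjustments are accepted only within 7 days of the adjusted day — a
recall-bias guard that doubles as a data-integrity measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Mapping, Optional, Sequence

from .intervals import Span, WorkInterval, clip, measure_hours, subtract, union
from .schedule import ScheduleSpec, oncall_window

__all__ = [
    "ManualAdjustment",
    "AdjustmentRejected",
    "ADJUSTMENT_WINDOW_DAYS",
    "apply_adjustment",
    "total_work_hours",
    "overtime",
    "DailyHours",
    "WorkReport",
    "build_report",
]

#: Users may correct a day's hours only this many days after the fact.
ADJUSTMENT_WINDOW_DAYS = 7


class AdjustmentRejected(ValueError):
    """Raised when a manual adjustment falls outside the 7-day window."""


def _day_span(d: date) -> Span:
    start = datetime.combine(d, datetime.min.time())
    return (start, start + timedelta(days=1))


@dataclass(frozen=True)
class ManualAdjustment:
    """A user's correction of one day's work intervals.

    ``intervals`` (source ``manual``) fully replace the GPS-derived
    intervals on ``day``; an empty list zeroes the day.  ``created_at``
    records when the correction was made and must be within
    :data:`ADJUSTMENT_WINDOW_DAYS` of the end of ``day``.
    """

    day: date
    intervals: tuple[WorkInterval, ...]
    created_at: datetime

    def __post_init__(self) -> None:
        ivs = tuple(self.intervals)
        object.__setattr__(self, "intervals", ivs)
        d0, d1 = _day_span(self.day)
        for iv in ivs:
            if iv.source != "manual":
                raise ValueError(f"adjustment intervals must have source 'manual', got {iv}")
            if iv.start < d0 or iv.end > d1:
                raise ValueError(f"adjustment interval {iv} lies outside day {self.day}")
        ordered = sorted(ivs, key=lambda i: i.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError(f"adjustment intervals overlap: {a} and {b}")
        _check_window(self.day, self.created_at)


def _check_window(day: date, now: datetime) -> None:
    day_end = _day_span(day)[1]
    if now - day_end > timedelta(days=ADJUSTMENT_WINDOW_DAYS):
        raise AdjustmentRejected(
            f"day {day} is more than {ADJUSTMENT_WINDOW_DAYS} days before {now}; "
            "adjustments this old are rejected to limit recall bias"
        )
    if day > now.date():
        raise AdjustmentRejected(f"cannot adjust a future day {day} at {now}")


def apply_adjustment(
    adj: ManualAdjustment,
    now: datetime,
    adjustments: Mapping[date, ManualAdjustment] | None = None,
) -> dict[date, ManualAdjustment]:
    """Validate ``adj`` against ``now`` and fold it into the adjustment state.

    Returns a new ``{day: adjustment}`` mapping; a later adjustment for the
    same day supersedes the earlier one.  Raises
    :class:`AdjustmentRejected` outside the 7-day window (measured from
    ``now`` back to the end of the adjusted day, inclusive).
    """
    _check_window(adj.day, now)
    state = dict(adjustments or {})
    state[adj.day] = adj
    return state


def _validate_disjoint_sorted(sessions: Sequence[WorkInterval]) -> list[WorkInterval]:
    ordered = sorted(sessions, key=lambda s: s.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"gps_sessions must be disjoint (merged); {a} overlaps {b}")
    return ordered


def _adjusted_gps_spans(
    gps_sessions: Sequence[WorkInterval],
    adjustments: Sequence[ManualAdjustment],
) -> list[Span]:
    """GPS spans after per-day manual replacement (adjusted days excised first)."""
    spans: list[Span] = [s.span for s in gps_sessions]
    if adjustments:
        days = [_day_span(a.day) for a in adjustments]
        spans = subtract(spans, days)
        for a in adjustments:
            spans.extend(iv.span for iv in a.intervals)
    return union(spans)


def _oncall_windows(spec: ScheduleSpec, t0: datetime, t1: datetime) -> list[tuple[date, Span]]:
    """(assignment date, clipped window span) for windows intersecting [t0, t1)."""
    out = []
    for a in spec.on_call:
        w = oncall_window(a, spec)
        s, e = max(w.start, t0), min(w.end, t1)
        if s < e:
            out.append((a.date, (s, e)))
    return out


def total_work_hours(
    gps_sessions: Sequence[WorkInterval],
    spec: ScheduleSpec,
    t0: datetime,
    t1: datetime,
    adjustments: Sequence[ManualAdjustment] = (),
) -> tuple[float, list[Span]]:
    """Total work hours over ``[t0, t1)`` plus the contributing interval set.

    The union of adjusted GPS sessions, on-call windows, and manual
    intervals, clipped to the range; every covered instant counts exactly
    once.  ``gps_sessions`` must already be merged (disjoint) or
    ``ValueError`` is raised.
    """
    if not t0 < t1:
        raise ValueError(f"query range requires t0 < t1, got [{t0}, {t1})")
    ordered = _validate_disjoint_sorted(gps_sessions)
    spans = _adjusted_gps_spans(ordered, adjustments)
    spans += [span for _, span in _oncall_windows(spec, t0, t1)]
    contributing = clip(spans, (t0, t1))
    return measure_hours(contributing), contributing


def overtime(total: float, scheduled: float) -> float:
    """Signed overtime: total minus scheduled hours.  Negative means the
    worker logged less than scheduled."""
    if total < 0 or scheduled < 0:
        raise ValueError("hours must be nonnegative")
    return total - scheduled


@dataclass(frozen=True)
class DailyHours:
    """One row of a report's daily breakdown.

    ``on_call`` holds the hours of this date's on-call window (attributed
    wholly to the assignment date even when the window crosses midnight);
    ``gps`` holds GPS/manual union time on this calendar date outside any
    on-call window.  ``total = gps + on_call``.
    """

    date: date
    total: float
    gps: float
    on_call: float


@dataclass(frozen=True)
class WorkReport:
    """Work-hours report over a query range.

    All hour fields are full-precision decimal hours; presentation layers
    (``summary()``, JSON/CSV writers) round to 0.1 h.  Invariants:
    ``overtime_hours == total_hours - scheduled_hours`` and
    ``gps_hours + oncall_hours >= total_hours`` (overlap counts once in the
    total), and the daily breakdown totals sum to ``total_hours``.
    """

    t0: datetime
    t1: datetime
    total_hours: float
    scheduled_hours: float
    overtime_hours: float
    gps_hours: float
    oncall_hours: float
    daily_breakdown: tuple[DailyHours, ...] = field(default=())

    def summary(self) -> str:
        lines = [
            f"Work report {self.t0.isoformat()} -> {self.t1.isoformat()}",
            f"  total work hours:     {self.total_hours:7.1f}",
            f"  scheduled work hours: {self.scheduled_hours:7.1f}",
            f"  overtime work hours:  {self.overtime_hours:7.1f}",
            f"  GPS-defined hours:    {self.gps_hours:7.1f}",
            f"  on-call hours:        {self.oncall_hours:7.1f}",
            "  date        total    gps  on-call",
        ]
        for row in self.daily_breakdown:
            lines.append(
                f"  {row.date.isoformat()}  {row.total:5.1f}  {row.gps:5.1f}    {row.on_call:5.1f}"
            )
        return "\n".join(lines)

    def to_dict(self, ndigits: int = 1) -> dict:
        """JSON-ready dict with hours rounded to ``ndigits`` decimals."""
        r = lambda x: round(x, ndigits)
        return {
            "range": {"from": self.t0.isoformat(), "to": self.t1.isoformat()},
            "total_hours": r(self.total_hours),
            "scheduled_hours": r(self.scheduled_hours),
            "overtime_hours": r(self.overtime_hours),
            "gps_hours": r(self.gps_hours),
            "oncall_hours": r(self.oncall_hours),
            "daily_breakdown": [
                {
                    "date": d.date.isoformat(),
                    "total": r(d.total),
                    "gps": r(d.gps),
                    "on_call": r(d.on_call),
                }
                for d in self.daily_breakdown
            ],
        }


def build_report(
    t0: datetime,
    t1: datetime,
    gps_sessions: Sequence[WorkInterval],
    spec: ScheduleSpec,
    adjustments: Sequence[ManualAdjustment] = (),
) -> WorkReport:
    """Assemble the full report: totals, scheduled, overtime, daily split.

    Attribution in the breakdown follows on-call precedence: an instant
    covered by both a GPS session and an on-call window is attributed to
    on-call, and a window's hours are booked on its assignment date (so an
    18:00->08:00 duty shows as 14 h on the duty date, not split across
    midnight).  Breakdown totals therefore sum exactly to ``total_hours``.
    """
    from .schedule import scheduled_hours as _scheduled

    if not t0 < t1:
        raise ValueError(f"report range requires t0 < t1, got [{t0}, {t1})")
    ordered = _validate_disjoint_sorted(gps_sessions)
    gps_spans = _adjusted_gps_spans(ordered, adjustments)
    oncall = _oncall_windows(spec, t0, t1)
    oncall_spans = [span for _, span in oncall]

    total, _ = total_work_hours(ordered, spec, t0, t1, adjustments)
    sched = _scheduled(t0, t1, spec)
    gps_h = measure_hours(clip(gps_spans, (t0, t1)))
    oncall_h = measure_hours(clip(oncall_spans, (t0, t1)))

    first_day = t0.date()
    last_day = (t1 - timedelta(microseconds=1)).date()

    # on-call hours booked on the assignment date (clamped into the report
    # range so a window spilling in from before t0 still has a row to land on)
    oncall_by_day: dict[date, float] = {}
    seen: list[Span] = []
    for a_date, span in oncall:
        fresh = subtract([span], seen)  # guard against pathological overlap
        seen = union(seen + [span])
        key = min(max(a_date, first_day), last_day)
        oncall_by_day[key] = oncall_by_day.get(key, 0.0) + measure_hours(fresh)

    # GPS/manual time outside any on-call window, by calendar day
    residual = subtract(clip(gps_spans, (t0, t1)), oncall_spans)
    rows = []
    d = first_day
    while d <= last_day:
        day_clip = (max(_day_span(d)[0], t0), min(_day_span(d)[1], t1))
        gps_d = measure_hours(clip(residual, day_clip)) if day_clip[0] < day_clip[1] else 0.0
        oc_d = oncall_by_day.get(d, 0.0)
        rows.append(DailyHours(date=d, total=gps_d + oc_d, gps=gps_d, on_call=oc_d))
        d += timedelta(days=1)

    return WorkReport(
        t0=t0,
        t1=t1,
        total_hours=total,
        scheduled_hours=sched,
        overtime_hours=overtime(total, sched),
        gps_hours=gps_h,
        oncall_hours=oncall_h,
        daily_breakdown=tuple(rows),
    )
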