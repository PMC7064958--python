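"""GPS-defined work sessions: geofence labeling, dwell-confirmed detection,
and gap integration.

The detector is a two-state (at-work / off-work) hysteresis machine driven by
a stream of geofence-labeled fixes sampled nominally every 10 minutes:

* OFF -> ON when a run of consecutive in-range fixes spans at least the
  confirmation time (default 30 min; four consecutive in-range dots at the
  nominal cadence).  The session *starts at the first fix of that run* — the
  confirmation delay is not lost.
* ON -> OFF symmetrically when a run of consecutive out-of-range fixes spans
  the confirmation time; the session *ends at the first fix of that run*.
* Shorter opposite-class runs do not flip state: a 20-minute coffee run does
  not split a session, and a 20-minute drive-by creates none.

Detected sessions separated by less than ``max_gap_hours`` (default 8 h) are
then integrated into one: clinicians move between sites, step out for lunch
or lectures, and come back — those absences still count as work.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional, Sequence

from .geo import GeofenceSet, GeoPoint, in_geofence
from .intervals import WorkInterval

__all__ = [
    "GpsFix",
    "LabeledFix",
    "label_fixes",
    "detect_sessions",
    "merge_sessions",
    "DEFAULT_CONFIRM_MINUTES",
    "DEFAULT_MERGE_GAP_HOURS",
]

DEFAULT_CONFIRM_MINUTES = 30.0
DEFAULT_MERGE_GAP_HOURS = 8.0


@dataclass(frozen=True, order=True)
class GpsFix:
    """One timestamped location observation (a "dot" on the trace)."""

    t: datetime
    p: GeoPoint


@dataclass(frozen=True)
class LabeledFix:
    """A fix plus its geofence classification.

    ``workplace_id`` is set iff ``in_range`` (the matched fence's id).
    """

    fix: GpsFix
    in_range: bool
    workplace_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.in_range != (self.workplace_id is not None):
            raise ValueError("workplace_id must be present iff in_range")


def _check_sorted(times: Sequence[datetime]) -> None:
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            raise ValueError(
                f"fixes must be strictly increasing in time; "
                f"violation at index {i}: {times[i - 1]} -> {times[i]}"
            )


def label_fixes(fixes: Sequence[GpsFix], fences: GeofenceSet) -> list[LabeledFix]:
    """Classify each fix against the geofence set, preserving order.

    Raises ``ValueError`` if the stream is not strictly time-sorted.
    """
    _check_sorted([f.t for f in fixes])
    out = []
    for f in fixes:
        wid = in_geofence(f.p, fences)
        out.append(LabeledFix(fix=f, in_range=wid is not None, workplace_id=wid))
    return out


def detect_sessions(
    labels: Sequence[LabeledFix],
    confirm_minutes: float = DEFAULT_CONFIRM_MINUTES,
) -> list[WorkInterval]:
    """Run the dwell-confirmation state machine over a labeled fix stream.

    Returns disjoint, time-sorted ``WorkInterval``s with ``source="gps"``.

    Irregular cadence is handled by measuring run length in elapsed time
    (first to last fix of the run), not in fix counts.  An inter-fix silence
    longer than ``confirm_minutes`` counts as out-of-range evidence: the
    phone saw nothing inside the fence, so an open session is closed — at
    the first out-of-range fix preceding the silence if there was one,
    otherwise at the last in-range fix.  The downstream gap integration
    repairs lunch-scale outages, so this stays conservative without
    fragmenting real shifts.

    A stream that ends while a session is open yields a final session closed
    at the last in-range fix and flagged ``provisional``.
    """
    if not confirm_minutes > 0:
        raise ValueError(f"confirm_minutes must be positive, got {confirm_minutes}")
    confirm = timedelta(minutes=confirm_minutes)
    _check_sorted([lf.fix.t for lf in labels])

    sessions: list[WorkInterval] = []
    on = False
    start: Optional[datetime] = None      # open session start while ON
    run_in: Optional[tuple[datetime, datetime]] = None   # current in-range run
    run_out: Optional[tuple[datetime, datetime]] = None  # current out-of-range run
    last_in: Optional[datetime] = None
    prev_t: Optional[datetime] = None

    def close(end: datetime, provisional: bool = False) -> None:
        nonlocal on, start
        if start is not None and end > start:
            sessions.append(WorkInterval(start, end, source="gps", provisional=provisional))
        on = False
        start = None

    for lf in labels:
        t = lf.fix.t
        if prev_t is not None and (t - prev_t) > confirm:
            # silence gap: treat as confirming out-of-range evidence
            if on:
                close(run_out[0] if run_out else last_in)  # type: ignore[index,arg-type]
            run_in = run_out = None
        if lf.in_range:
            run_out = None
            run_in = (run_in[0], t) if run_in else (t, t)
            last_in = t
            if not on and run_in[1] - run_in[0] >= confirm:
                on = True
                start = run_in[0]
        else:
            run_in = None
            run_out = (run_out[0], t) if run_out else (t, t)
            if on and run_out[1] - run_out[0] >= confirm:
                close(run_out[0])
        prev_t = t

    if on:
        close(last_in, provisional=True)  # type: ignore[arg-type]
    return sessions


def merge_sessions(
    sessions: Sequence[WorkInterval],
    max_gap_hours: float = DEFAULT_MERGE_GAP_HOURS,
) -> list[WorkInterval]:
    """Integrate sessions separated by gaps strictly shorter than ``max_gap_hours``.

    Consecutive sessions whose gap is ``< max_gap_hours`` are replaced by
    their convex hull, transitively, until no such gap remains.  A gap of
    exactly ``max_gap_hours`` is *not* merged.  Input must be disjoint;
    overlap raises ``ValueError``.  Idempotent by construction.
    """
    if not max_gap_hours >= 0:
        raise ValueError(f"max_gap_hours must be nonnegative, got {max_gap_hours}")
    ordered = sorted(sessions, key=lambda s: s.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping sessions: {a} and {b}")
    gap = timedelta(hours=max_gap_hours)
    merged: list[WorkInterval] = []
    for s in ordered:
        if merged and s.start - merged[-1].end < gap:
            prev = merged[-1]
            merged[-1] = WorkInterval(
                prev.start, max(prev.end, s.end), source="gps", provisional=s.provisional
            )
        else:
            merged.append(s)
    return merged
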