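"""Half-open time intervals and measure-theoretic set operations on them.

Every duration in the package is the Lebesgue measure of a union of
half-open intervals ``[start, end)``; the half-open convention means
abutting intervals never double-count their shared boundary instant.
Timestamps are timezone-naive local time throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Sequence

__all__ = [
    "WorkInterval",
    "Span",
    "union",
    "intersect",
    "subtract",
    "clip",
    "measure_hours",
]

#: Allowed provenance tags for a WorkInterval.
SOURCES = ("gps", "on_call", "manual", "regular")

#: A bare (start, end) pair; the currency of the set operations below.
Span = tuple[datetime, datetime]


@dataclass(frozen=True, order=True)
class WorkInterval:
    """A half-open work interval ``[start, end)`` with a provenance tag.

    ``source`` records where the interval came from: ``gps`` (detected from
    location fixes), ``on_call`` (a derived on-call duty window), ``manual``
    (a user adjustment), or ``regular`` (a scheduled regular-hours window).
    ``provisional`` marks a GPS session that was still open when the fix
    stream ended, i.e. its end is a lower bound.
    """

    start: datetime
    end: datetime
    source: str = "gps"
    provisional: bool = False

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        if not self.start < self.end:
            raise ValueError(f"interval requires start < end, got [{self.start}, {self.end})")

    @property
    def duration(self) -> timedelta:
        return self.end - self.start

    @property
    def hours(self) -> float:
        return self.duration.total_seconds() / 3600.0

    @property
    def span(self) -> Span:
        return (self.start, self.end)

    def __repr__(self) -> str:  # compact, log-friendly
        flag = ", provisional" if self.provisional else ""
        return f"WorkInterval({self.start.isoformat()} -> {self.end.isoformat()}, {self.source}{flag})"


def _as_spans(intervals: Iterable) -> list[Span]:
    out = []
    for iv in intervals:
        if isinstance(iv, WorkInterval):
            out.append(iv.span)
        else:
            s, e = iv
            out.append((s, e))
    return out


def union(intervals: Iterable) -> list[Span]:
    """Normalize into disjoint, sorted spans; overlapping or abutting pieces coalesce."""
    spans = sorted(s for s in _as_spans(intervals) if s[0] < s[1])
    merged: list[Span] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def intersect(a: Iterable, b: Iterable) -> list[Span]:
    """Intersection of two interval sets, as disjoint sorted spans."""
    ua, ub = union(a), union(b)
    out: list[Span] = []
    i = j = 0
    while i < len(ua) and j < len(ub):
        s = max(ua[i][0], ub[j][0])
        e = min(ua[i][1], ub[j][1])
        if s < e:
            out.append((s, e))
        if ua[i][1] <= ub[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Iterable, b: Iterable) -> list[Span]:
    """Set difference ``a \\ b``, as disjoint sorted spans."""
    ua, ub = union(a), union(b)
    out: list[Span] = []
    j = 0
    for s, e in ua:
        cur = s
        while j < len(ub) and ub[j][1] <= cur:
            j += 1
        k = j
        while k < len(ub) and ub[k][0] < e:
            bs, be = ub[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def clip(intervals: Iterable, window: Span) -> list[Span]:
    """Restrict an interval set to a half-open window."""
    t0, t1 = window
    if not t0 < t1:
        raise ValueError(f"window requires t0 < t1, got [{t0}, {t1})")
    return intersect(intervals, [(t0, t1)])


def measure_hours(intervals: Iterable) -> float:
    """Total measure of an interval set in decimal hours (overlaps once)."""
    total = timedelta(0)
    for s, e in union(intervals):
        total += e - s
    return total.total_seconds() / 3600.0
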