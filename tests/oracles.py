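"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive and structurally different from the library code:
interval measures are computed by marking minutes on a grid, and session
detection by an explicit run-enumeration walk (itertools.groupby) rather
than the library's incremental state machine.  These functions are the
reference; they must never import from the modules they check beyond plain
data types.
"""

from __future__ import annotations

import itertools
from datetime import datetime, timedelta

import numpy as np


def grid_minutes(t0: datetime, t1: datetime) -> int:
    return int((t1 - t0).total_seconds() // 60)


def mark_grid(spans, t0: datetime, t1: datetime) -> np.ndarray:
    """Boolean minute grid of [t0, t1): minute k covered iff its start
    instant lies inside some half-open span."""
    n = grid_minutes(t0, t1)
    grid = np.zeros(n, dtype=bool)
    for s, e in spans:
        a = max(0, int((s - t0).total_seconds() // 60))
        b = min(n, int((e - t0).total_seconds() // 60))
        if b > a:
            grid[a:b] = True
    return grid


def grid_union_hours(spans, t0: datetime, t1: datetime) -> float:
    """Union measure in hours by counting covered minutes (exact for
    minute-aligned spans)."""
    return float(mark_grid(spans, t0, t1).sum()) / 60.0


def grid_confusion_hours(app_spans, diary_spans, t0: datetime, t1: datetime):
    """(tp, fp, fn, tn) in hours on the minute grid."""
    a = mark_grid(app_spans, t0, t1)
    d = mark_grid(diary_spans, t0, t1)
    return (
        float((a & d).sum()) / 60.0,
        float((a & ~d).sum()) / 60.0,
        float((~a & d).sum()) / 60.0,
        float((~a & ~d).sum()) / 60.0,
    )


def naive_detect(labeled, confirm_minutes: float = 30.0):
    """Reference two-state dwell machine over a gap-free labeled stream.

    ``labeled`` is a sequence of (datetime, in_range: bool) pairs at
    regular cadence (no inter-fix silence longer than the confirmation
    time).  Returns (start, end, provisional) triples.  Runs are enumerated
    wholesale with groupby; state flips when a run's first-to-last span
    reaches the confirmation time, boundaries timestamped at the run's
    first fix.
    """
    confirm = timedelta(minutes=confirm_minutes)
    runs = [
        (key, [t for t, _ in grp])
        for key, grp in itertools.groupby(labeled, key=lambda x: x[1])
    ]
    sessions = []
    on = False
    start = None
    last_in = None
    for in_range, times in runs:
        span = times[-1] - times[0]
        if in_range:
            last_in = times[-1]
        if not on and in_range and span >= confirm:
            on = True
            start = times[0]
        elif on and not in_range and span >= confirm:
            sessions.append((start, times[0], False))
            on = False
    if on:
        sessions.append((start, last_in, True))
    return sessions


def naive_merge(spans, max_gap_hours: float = 8.0):
    """Reference gap integration: repeatedly hull the first sub-gap pair."""
    gap = timedelta(hours=max_gap_hours)
    spans = sorted(spans)
    changed = True
    while changed:
        changed = False
        for i in range(len(spans) - 1):
            if spans[i + 1][0] - spans[i][1] < gap:
                spans[i:i + 2] = [(spans[i][0], max(spans[i][1], spans[i + 1][1]))]
                changed = True
                break
    return spans
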