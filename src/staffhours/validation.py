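"""Time-overlap validation of app-recorded work against a self-report diary.

The diary is the putative gold standard.  Instead of counting events, the
confusion matrix here is measured in *hours*: every instant of the
observation window is classified as true positive (both app and diary call
it work), false positive (app only), false negative (diary only), or true
negative (neither), and the four components always sum exactly to the
window length.  Sensitivity and specificity follow in the usual way, and a
Pearson correlation compares per person-day totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Sequence

import numpy as np

from .intervals import Span, WorkInterval, intersect, measure_hours, subtract, union

__all__ = [
    "DiaryEntry",
    "ConfusionHours",
    "confusion_hours",
    "sensitivity",
    "specificity",
    "daily_correlation",
    "UndefinedMetricError",
]


class UndefinedMetricError(ZeroDivisionError):
    """A rate whose denominator is zero, or a correlation with zero variance."""


@dataclass(frozen=True)
class DiaryEntry:
    """Self-reported work intervals for one day (disjoint, within the day)."""

    day: date
    intervals: tuple[WorkInterval, ...]

    def __post_init__(self) -> None:
        ivs = tuple(self.intervals)
        object.__setattr__(self, "intervals", ivs)
        d0 = datetime.combine(self.day, datetime.min.time())
        d1 = d0 + timedelta(days=1)
        for iv in ivs:
            if iv.start < d0 or iv.end > d1:
                raise ValueError(f"diary interval {iv} lies outside day {self.day}")
        ordered = sorted(ivs, key=lambda i: i.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError(f"diary intervals overlap: {a} and {b}")

    @property
    def hours(self) -> float:
        return measure_hours(self.intervals)


@dataclass(frozen=True)
class ConfusionHours:
    """Hour-measured confusion decomposition of an observation window.

    ``tp + fp + fn + tn == window`` by construction (conservation).
    """

    tp: float
    fp: float
    fn: float
    tn: float
    window: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"{name} must be nonnegative")
        if abs(self.tp + self.fp + self.fn + self.tn - self.window) > 1e-9:
            raise ValueError(
                "confusion components must sum to the window length: "
                f"{self.tp}+{self.fp}+{self.fn}+{self.tn} != {self.window}"
            )


def confusion_hours(
    app: Sequence[WorkInterval],
    diary: Sequence[DiaryEntry],
    t0: datetime,
    t1: datetime,
) -> ConfusionHours:
    """Decompose ``[t0, t1)`` into tp/fp/fn/tn hours.

    ``app`` is the app's recorded work intervals (GPS sessions and/or
    on-call windows); ``diary`` the gold-standard entries.  All intervals
    must lie within the window.
    """
    if not t0 < t1:
        raise ValueError(f"window requires t0 < t1, got [{t0}, {t1})")
    app_spans: list[Span] = [iv.span for iv in app]
    diary_spans: list[Span] = [iv.span for e in diary for iv in e.intervals]
    for s, e in app_spans + diary_spans:
        if s < t0 or e > t1:
            raise ValueError(f"interval [{s}, {e}) lies outside window [{t0}, {t1})")
    window_h = (t1 - t0).total_seconds() / 3600.0
    tp = measure_hours(intersect(app_spans, diary_spans))
    fp = measure_hours(subtract(app_spans, diary_spans))
    fn = measure_hours(subtract(diary_spans, app_spans))
    tn = window_h - measure_hours(union(app_spans + diary_spans))
    return ConfusionHours(tp=tp, fp=fp, fn=fn, tn=tn, window=window_h)


def sensitivity(c: ConfusionHours) -> float:
    """Percent of gold-standard work time the app also calls work: 100·tp/(tp+fn)."""
    denom = c.tp + c.fn
    if denom <= 0:
        raise UndefinedMetricError("sensitivity undefined: diary contains no work time")
    return 100.0 * c.tp / denom


def specificity(c: ConfusionHours) -> float:
    """Percent of gold-standard non-work time the app also calls non-work: 100·tn/(tn+fp)."""
    denom = c.tn + c.fp
    if denom <= 0:
        raise UndefinedMetricError("specificity undefined: diary contains no non-work time")
    return 100.0 * c.tn / denom


def daily_correlation(
    app_daily: Sequence[float], diary_daily: Sequence[float]
) -> float:
    """Pearson r between app-recorded and diary per person-day hour totals."""
    x = np.asarray(app_daily, dtype=float)
    y = np.asarray(diary_daily, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D vectors of equal length required")
    if x.size < 3:
        raise ValueError(f"need at least 3 paired observations, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedMetricError("correlation undefined: zero variance in a vector")
    return float(np.corrcoef(x, y)[0, 1])
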