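from __future__ import annotations

from datetime import date, datetime, time, timedelta

import pytest
from hypothesis import settings

from staffhours.geo import GeofenceSet, GeoPoint, Workplace
from staffhours.schedule import OnCallAssignment, RegularSchedule, ScheduleSpec
from staffhours.sessions import GpsFix

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")

#: a point comfortably outside every test fence (~25 km away)
FAR = GeoPoint(25.30, 121.70)


@pytest.fixture
def hospital_a() -> Workplace:
    return Workplace("A", GeoPoint(25.0410, 121.5190), 1.0)


@pytest.fixture
def hospital_b() -> Workplace:
    return Workplace("B", GeoPoint(25.0630, 121.5250), 1.0)


@pytest.fixture
def fences(hospital_a, hospital_b) -> GeofenceSet:
    return GeofenceSet((hospital_a, hospital_b))


@pytest.fixture
def spec_8_18() -> ScheduleSpec:
    """Mon-Fri 08:00-18:00 regular hours, no on-call."""
    return ScheduleSpec(RegularSchedule(time(8, 0), time(18, 0)))


def make_stream(day: date, segments, cadence_minutes: int = 10) -> list[GpsFix]:
    """Build a fix stream from (start_hhmm, end_hhmm, point) segments.

    Each segment emits fixes at ``point`` every ``cadence_minutes`` over
    the half-open clock-time span; segments must abut or be ordered.
    """
    fixes = []
    for start, end, p in segments:
        t = datetime.combine(day, time(*start))
        stop = datetime.combine(day, time(*end)) if end != (24, 0) else (
            datetime.combine(day + timedelta(days=1), time(0, 0)))
        while t < stop:
            fixes.append(GpsFix(t, p))
            t += timedelta(minutes=cadence_minutes)
    return fixes


@pytest.fixture
def figure_stream(hospital_a, hospital_b):
    """The canonical two-hospital morning: in fence A 9:00-9:50, out
    10:00-10:50, in fence B 11:00-11:50, out 12:00 onward."""
    d = date(2022, 6, 23)
    return make_stream(d, [
        ((9, 0), (10, 0), hospital_a.center),
        ((10, 0), (11, 0), FAR),
        ((11, 0), (12, 0), hospital_b.center),
        ((12, 0), (13, 0), FAR),
    ])
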