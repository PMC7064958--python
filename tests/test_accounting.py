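"""Total-hours union, on-call precedence, overtime, adjustments, reports."""

from __future__ import annotations

import random
from datetime import date, datetime, time, timedelta

import pytest

from oracles import grid_union_hours
from staffhours.accounting import (
    AdjustmentRejected,
    ManualAdjustment,
    WorkReport,
    apply_adjustment,
    build_report,
    overtime,
    total_work_hours,
)
from staffhours.intervals import WorkInterval
from staffhours.schedule import OnCallAssignment, RegularSchedule, ScheduleSpec

# the worked week: Thu 23rd (long day), Fri 24th (first-line duty),
# Sat 25th (morning overtime), Sun 26th (second-line duty), Mon 27th
THU, FRI, SAT, SUN, MON = (date(2022, 6, d) for d in range(23, 28))


def dt(d, h, m=0):
    return datetime.combine(d, time(0)) + timedelta(hours=h, minutes=m)


@pytest.fixture
def duty_spec(spec_8_18):
    return ScheduleSpec(
        spec_8_18.regular,
        (OnCallAssignment(FRI, "first_line"), OnCallAssignment(SUN, "second_line")),
    )


@pytest.fixture
def week_sessions():
    """Merged GPS presence for the worked week."""
    return [
        WorkInterval(dt(THU, 8), dt(THU, 21)),   # long Thursday, noon break merged
        WorkInterval(dt(FRI, 8), dt(FRI, 18)),   # leaves at 18:00 despite duty
        WorkInterval(dt(SAT, 8), dt(SAT, 12)),   # Saturday morning
        WorkInterval(dt(MON, 8), dt(MON, 18)),   # regular Monday
    ]


class TestTotalWorkHours:
    def test_long_thursday_counts_thirteen_hours(self, spec_8_18):
        sessions = [WorkInterval(dt(THU, 8), dt(THU, 21))]
        total, _ = total_work_hours(sessions, spec_8_18, dt(THU, 0), dt(FRI, 0))
        assert total == pytest.approx(13.0)

    def test_oncall_window_counts_despite_gps_absence(self, duty_spec):
        # present 8:00-18:00 only; the full 14-h duty window still counts
        sessions = [WorkInterval(dt(FRI, 8), dt(FRI, 18))]
        total, _ = total_work_hours(sessions, duty_spec, dt(FRI, 18), dt(SAT, 8))
        assert total == pytest.approx(14.0)

    def test_weekend_duty_plus_monday_regular_is_34(self, duty_spec):
        sessions = [WorkInterval(dt(MON, 8), dt(MON, 18))]
        total, _ = total_work_hours(sessions, duty_spec, dt(SUN, 8), dt(MON, 18))
        assert total == pytest.approx(34.0)

    def test_empty_inputs_give_zero(self, spec_8_18):
        total, contributing = total_work_hours([], spec_8_18, dt(THU, 0), dt(FRI, 0))
        assert total == 0.0 and contributing == []

    def test_gps_overlapping_duty_window_counts_once(self, duty_spec):
        # present through the entire duty night: union, not sum
        sessions = [WorkInterval(dt(FRI, 8), dt(SAT, 8))]
        total, _ = total_work_hours(sessions, duty_spec, dt(FRI, 0), dt(SAT, 8))
        assert total == pytest.approx(24.0)

    def test_unmerged_overlapping_sessions_rejected(self, spec_8_18):
        bad = [WorkInterval(dt(THU, 8), dt(THU, 12)), WorkInterval(dt(THU, 11), dt(THU, 13))]
        with pytest.raises(ValueError, match="disjoint"):
            total_work_hours(bad, spec_8_18, dt(THU, 0), dt(FRI, 0))

    def test_never_exceeds_elapsed_time(self, duty_spec, week_sessions):
        total, _ = total_work_hours(week_sessions, duty_spec, dt(THU, 0), dt(MON, 0))
        assert total <= 4 * 24 + 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_adding_oncall_never_decreases_total(self, seed, spec_8_18, week_sessions):
        rng = random.Random(seed)
        d = THU + timedelta(days=rng.randrange(5))
        line = rng.choice(["first_line", "second_line"])
        base, _ = total_work_hours(week_sessions, spec_8_18, dt(THU, 0), dt(MON, 18))
        spec2 = ScheduleSpec(spec_8_18.regular, (OnCallAssignment(d, line),))
        more, _ = total_work_hours(week_sessions, spec2, dt(THU, 0), dt(MON, 18))
        assert more >= base - 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_minute_grid_oracle(self, seed, duty_spec):
        rng = random.Random(seed)
        sessions, cursor = [], dt(THU, 0)
        for _ in range(rng.randrange(1, 8)):
            start = cursor + timedelta(minutes=rng.randrange(1, 900))
            end = start + timedelta(minutes=rng.randrange(1, 900))
            sessions.append(WorkInterval(start, end))
            cursor = end
        t0, t1 = dt(THU, 0), dt(MON, 18)
        total, contributing = total_work_hours(sessions, duty_spec, t0, t1)
        from staffhours.schedule import oncall_window
        spans = [s.span for s in sessions]
        spans += [oncall_window(a, duty_spec).span for a in duty_spec.on_call]
        assert total == pytest.approx(grid_union_hours(spans, t0, t1))
        assert total == pytest.approx(grid_union_hours(contributing, t0, t1))


class TestOvertime:
    def test_paper_week(self):
        assert overtime(88.1, 80.0) == pytest.approx(8.1)

    def test_zero_and_negative_branches(self):
        assert overtime(50.0, 50.0) == 0.0
        assert overtime(45.0, 50.0) == pytest.approx(-5.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            overtime(-1.0, 5.0)


class TestAdjustments:
    def test_yesterday_accepted_and_replaces_gps(self, spec_8_18):
        now = dt(FRI, 12)
        adj = ManualAdjustment(
            THU, (WorkInterval(dt(THU, 9), dt(THU, 17), source="manual"),), now)
        state = apply_adjustment(adj, now)
        assert state == {THU: adj}
        sessions = [WorkInterval(dt(THU, 8), dt(THU, 21))]
        total, _ = total_work_hours(
            sessions, spec_8_18, dt(THU, 0), dt(FRI, 0), adjustments=[adj])
        assert total == pytest.approx(8.0)

    def test_eight_days_back_rejected(self):
        created = dt(THU, 12)
        adj = ManualAdjustment(
            THU, (WorkInterval(dt(THU, 9), dt(THU, 17), source="manual"),), created)
        with pytest.raises(AdjustmentRejected):
            apply_adjustment(adj, created + timedelta(days=8, hours=13))

    def test_construction_outside_window_rejected(self):
        with pytest.raises(AdjustmentRejected):
            ManualAdjustment(THU, (), dt(THU + timedelta(days=9), 12))

    def test_empty_adjustment_zeroes_the_day(self, spec_8_18):
        adj = ManualAdjustment(THU, (), dt(FRI, 9))
        sessions = [WorkInterval(dt(THU, 8), dt(THU, 21))]
        total, _ = total_work_hours(
            sessions, spec_8_18, dt(THU, 0), dt(FRI, 0), adjustments=[adj])
        assert total == 0.0

    def test_intervals_outside_day_rejected(self):
        with pytest.raises(ValueError, match="outside day"):
            ManualAdjustment(
                THU, (WorkInterval(dt(THU, 22), dt(FRI, 2), source="manual"),), dt(FRI, 9))

    def test_adjustment_spares_other_days(self, spec_8_18):
        adj = ManualAdjustment(THU, (), dt(FRI, 9))
        sessions = [
            WorkInterval(dt(THU, 8), dt(THU, 21)),
            WorkInterval(dt(FRI, 8), dt(FRI, 18)),
        ]
        total, _ = total_work_hours(
            sessions, spec_8_18, dt(THU, 0), dt(SAT, 0), adjustments=[adj])
        assert total == pytest.approx(10.0)


class TestReport:
    def test_worked_week_daily_breakdown(self, duty_spec, week_sessions):
        rep = build_report(dt(THU, 0), dt(MON, 18), week_sessions, duty_spec)
        by_day = {row.date: row for row in rep.daily_breakdown}
        assert [round(by_day[d].total, 6) for d in (THU, FRI, SAT, SUN, MON)] == [
            13.0, 24.0, 4.0, 24.0, 10.0]
        assert by_day[FRI].on_call == pytest.approx(14.0)
        assert by_day[FRI].gps == pytest.approx(10.0)
        assert by_day[SUN].on_call == pytest.approx(24.0)

    def test_overtime_identity_and_additivity(self, duty_spec, week_sessions):
        rep = build_report(dt(THU, 0), dt(MON, 18), week_sessions, duty_spec)
        assert rep.overtime_hours == pytest.approx(rep.total_hours - rep.scheduled_hours)
        assert sum(r.total for r in rep.daily_breakdown) == pytest.approx(rep.total_hours)
        assert rep.gps_hours + rep.oncall_hours >= rep.total_hours - 1e-9

    def test_empty_inputs_give_zero_report(self, spec_8_18):
        rep = build_report(dt(THU, 0), dt(FRI, 0), [], spec_8_18)
        assert rep.total_hours == 0.0
        assert rep.oncall_hours == 0.0
        # Thursday is a workday: scheduled is the 10-h regular window
        assert rep.scheduled_hours == pytest.approx(10.0)
        assert rep.overtime_hours == pytest.approx(-10.0)

    def test_summary_prints_rounded_hours(self, duty_spec, week_sessions):
        rep = build_report(dt(THU, 0), dt(MON, 18), week_sessions, duty_spec)
        text = rep.summary()
        assert "total work hours" in text
        assert f"{rep.total_hours:.1f}" in text
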