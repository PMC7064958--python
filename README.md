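# staffhours

A work-hours engine for people whose schedules defeat ordinary time
trackers — hospital staff with regular shifts, overnight on-call duties,
and more than one campus. Instead of manual clock-in/clock-out, it derives
**GPS-defined work hours** from passive location fixes via geofencing,
overlays the worker's declared schedule, and reports total, scheduled, and
overtime hours. It is aimed at occupational-health researchers and
digital-phenotyping pipelines that need objective, real-time work-hour
measurement from smartphone location streams.

## The algorithm

A phone records a fix every 10 minutes. Each fix is classified against up
to five circular geofences (default radius 1 km, haversine distance on a
sphere of radius 6371.0088 km). Work sessions come from a two-state
hysteresis machine with 30-minute dwell confirmation:

* **off → at work** when a run of consecutive in-range fixes spans ≥ 30
  min; the session starts at the *first* fix of the run.
* **at work → off** symmetrically on a ≥ 30-min out-of-range run, ending
  the session at the *first* out-of-range fix.
* Shorter opposite runs don't flip state, so a coffee run doesn't split a
  shift and a drive-by doesn't create one.

Sessions separated by gaps of **less than 8 hours** are then integrated
into one (lunch, lectures, moving between campuses all stay "at work").

Declared schedules contribute two window types: regular weekday hours
(e.g. 08:00–18:00) and dated on-call duties. A weekday duty window runs
from the end of regular hours to the start of regular hours next day
(14 h for an 08:00–18:00 schedule); a weekend duty is 24 h from the
regular start time. Both first-line (in-house) and second-line (home
standby) duties count in full. Totals are the Lebesgue measure of the
union

> total = |GPS sessions ∪ on-call windows ∪ manual adjustments|

clipped to the query range — on-call takes precedence over GPS absence,
overlaps count once, and

> overtime = total − scheduled (may be negative).

Manual corrections are accepted only within 7 days (a recall-bias guard).
A validation module scores app-recorded work time against self-report
diaries with *hour-measured* sensitivity and specificity (tp + fp + fn +
tn equals the observation window exactly), plus per-day Pearson
correlation. A seeded synthetic module generates ground-truth diaries and
noisy, dropout-ridden GPS traces for four personas (resident, nurse,
visiting staff, non-healthcare) so the whole pipeline is testable without
real participant data.

## Worked example

Simulate one resident's week, then report it:

```bash
staffhours simulate --seed 11 --n-days 7 --persona resident --out-dir demo
staffhours report --fixes demo/fixes.csv --config demo/config.yaml \
    --from 2022-06-06 --to 2022-06-13 --format csv
```

```
Work report 2022-06-06T00:00:00 -> 2022-06-13T00:00:00
  total work hours:        73.5
  scheduled work hours:    64.0
  overtime work hours:      9.5
  GPS-defined hours:       73.5
  on-call hours:           14.0
  date        total    gps  on-call
  2022-06-06   23.7    9.7     14.0
  2022-06-07   11.5   11.5      0.0
  2022-06-08   12.3   12.3      0.0
  2022-06-09   14.5   14.5      0.0
  2022-06-10   11.5   11.5      0.0
  2022-06-11    0.0    0.0      0.0
  2022-06-12    0.0    0.0      0.0
```

This resident was scheduled for 50 regular hours plus one 14-hour weekday
duty (64 h) and actually logged 73.5 h — 9.5 h of overtime. Monday shows
the duty attribution: 14 on-call hours booked on the duty date (the
overnight window is not split across midnight) plus 9.7 daytime GPS hours
outside the window. The library equivalent:

```python
from staffhours import label_fixes, detect_sessions, merge_sessions, build_report

labels = label_fixes(fixes, config.workplaces)          # geofence classification
merged = merge_sessions(detect_sessions(labels))        # dwell + 8-h integration
report = build_report(t0, t1, merged, config.schedule)  # totals & overtime
print(report.summary())
```

Other subcommands: `detect` (sessions as JSON), `validate` (diary
sensitivity/specificity), `check-eligibility` (a worker living inside a
workplace fence cannot be tracked by geofencing and is flagged).

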