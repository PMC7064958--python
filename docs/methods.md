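# Methods

## Problem and measurement model

The package measures work hours for workers with fixed work sites from
passive smartphone location data. The underlying assumption is that for
hospital staff and most office workers, *being inside a geofence around a
work site* is a valid proxy for *working*, except during on-call duty,
where duty status overrides physical presence. All computation reduces to
measure theory on half-open time intervals `[start, end)`: work time is
the measure of a union of interval families, so abutting intervals never
double-count a boundary instant and totals can never exceed elapsed time.

Timestamps are timezone-naive local time. Daylight-saving transitions are
out of scope (a documented limitation; the deployment region of interest
does not observe DST).

## Geofencing

Distance is haversine on a sphere of mean radius 6371.0088 km. At the
1-km fence scale, the sphere-vs-ellipsoid error is below ~0.5 %, i.e.
metres — far below GPS noise. Fence membership is **inclusive** at the
boundary (distance == radius counts as inside) so float jitter at the
fence line cannot drop fixes. When fences overlap, the first workplace in
configuration order wins; this keeps labeling deterministic. A worker
whose home lies within a fence (inclusive, default exclusion radius 1 km,
configurable separately from the fence radius) is flagged ineligible:
geofencing cannot distinguish their home from their workplace.

## Session detection

The detector is a two-state hysteresis machine over the labeled fix
stream. State flips only when a run of consecutive same-class fixes
*spans* the confirmation time (default 30 min), measured first-to-last
fix of the run — at the nominal 10-minute cadence that is four
consecutive fixes, but the time-span definition stays well-posed under
irregular cadence. Session boundaries are timestamped at the **first**
fix of the confirming run (both for starts and ends), so the confirmation
delay is not lost: a worker who arrives at 9:00 and is confirmed at 9:30
is credited from 9:00.

Numerical/degenerate choices:

* **Confirmation threshold** is `>=` (a run spanning exactly 30 min
  confirms).
* **Silence** (inter-fix gap > confirmation time) counts as out-of-range
  evidence: the phone saw nothing inside the fence. An open session
  closes at the first real out-of-range fix if a short out-run
  immediately preceded the silence, otherwise at the last in-range fix.
  There is no fix inside the gap to timestamp a virtual boundary, so the
  last observed evidence is the only defensible anchor. The 8-hour
  integration step then repairs lunch-scale outages, so this conservatism
  does not fragment real shifts.
* **Stream ending while at work** yields a session closed at the last
  in-range fix, flagged `provisional` (its end is a lower bound) —
  matching a real-time reporting scenario where the day is still open.
* Workplace identity is not tracked inside sessions; any fence counts as
  "at work". Per-site attribution is a non-goal.

## Gap integration

Consecutive sessions whose gap is **strictly less than 8 hours** are
replaced by their convex hull, transitively to a fixed point (a single
left-to-right pass suffices since merging only shrinks gaps). A gap of
exactly 8 hours is not merged. The operation is idempotent and can only
increase total duration. Rationale: clinicians leave the fence for
lunches, lectures, or transfers between campuses and are still working;
an absence of 8+ hours is a genuine end of shift.

## Schedules and on-call windows

Regular hours are a fixed start/end clock time on a workday set (default
Mon–Fri); overnight regular shifts are rejected (out of scope). On-call
windows are derived: on a workday, from the end of regular hours to the
start of regular hours the next day; on a non-workday, 24 h anchored at
the regular start time. "Weekend" is generalized to *any non-workday of
the declared schedule*. Two identities follow by construction and are
property-tested: a weekday window abuts (never overlaps) that day's
regular window, and weekday window + regular day == 24 h exactly.
First-line and second-line duties produce identical windows — the line
distinguishes presence expectations, not credited duration; both count
fully toward scheduled and total hours.

Scheduled hours over a range are the union measure of all regular and
on-call windows clipped to the range, so overlapping declarations count
once and the quantity is additive over a partition of the range.

## Total hours, precedence, and reports

Total work hours over `[t0, t1)` are the union measure of (i) merged GPS
sessions, with any manually adjusted day's sessions replaced by the
adjustment's intervals first, (ii) on-call windows for every assigned
date (counted in full regardless of GPS presence), and (iii) the manual
intervals. "On-call precedence" is implemented as union with attribution
priority rather than clipping: durations are identical either way, but
the union keeps total ≤ elapsed time trivially and the attribution
(on-call wins where both cover an instant) is only a reporting concern.

The daily breakdown books an on-call window's hours wholly on its
**assignment date** — an 18:00→08:00 duty appears as 14 h on the duty
date, not split across midnight — while GPS/manual time outside any
window is booked on the calendar day of each instant. This matches how
duty rosters are read and makes breakdown totals sum exactly to the
report total (a tested invariant, along with `overtime == total −
scheduled` and `gps + on-call ≥ total`). A window spilling into the
report range from an assignment date outside it is clamped to the nearest
in-range row so additivity survives clipping.

Manual adjustments are accepted if `now` is within 7 days of the end of
the adjusted day (inclusive) and the day is not in the future; an empty
adjustment zeroes the day. Hours are full-precision floats internally and
rounded to 0.1 h only at presentation (summary tables, JSON/CSV export).

## Validation metrics

Agreement with a self-report diary is measured in hours, not events:
every instant of the observation window is tp/fp/fn/tn according to
(app says work) × (diary says work), computed by interval intersection
and subtraction. Conservation `tp+fp+fn+tn == window` holds to 1e-9 h on
every decomposition and both rates are invariant to splitting intervals
into abutting pieces. Sensitivity and specificity are pooled across
person-days (the per-day option is a matter of slicing inputs);
correlation is Pearson's r on per person-day totals, requiring ≥3 pairs
and nonzero variance. Rounding to one decimal happens only at
presentation.

## Synthetic data

The generator emulates the data regime the engine targets, not human
mobility in general. Per persona (resident, nurse, visiting staff,
non-healthcare office worker) it draws, per workday: arrival jitter
(Gaussian, SD 8–12 min around the regular start), an exponential overtime
tail (mean 0.5–1.5 h, capped at 5 h), an optional midday excursion
(probability 0.4–0.7, duration 30–90 min — deliberately far below the
8-hour merge threshold so a day's truth stays one integrated block), and
occasionally an afternoon move to a second campus. On-call duty counts
per 28 days are persona-bounded (resident 4–8, non-healthcare 0);
first-line duties add genuine overnight presence, second-line duties do
not. Defaults (10-min cadence, 1-km fences, 50 m noise, 5 % dropout,
28 days) mirror a realistic month of smartphone geofencing.

Traces place each fix at the active workplace centre, at a per-gap
excursion point 1.2–3 km off campus during sub-8-h absences, or at home;
isotropic Gaussian noise of scale `noise_sigma_m` is added per axis in a
local tangent plane (metres → degrees with latitude-dependent scaling —
adequate at kilometre scale), and fixes drop independently at
`dropout_rate`. For isotropic noise the out-of-fence probability during
true presence has the closed form `exp(−R²/2σ²)` (Rayleigh tail), which
the tests verify by Monte Carlo at σ = 500 m. All randomness flows from
one integer seed through two derived substreams (diary, trace); identical
parameters reproduce byte-identical output.

What passing synthetic tests show — and don't: they demonstrate the
engine's logic (detection, integration, precedence, accounting) is exact
and robust to Gaussian noise and missing fixes at realistic rates. They
do not capture urban-canyon multipath, map-matched travel, battery/OS
sampling pathologies, or behavioural idiosyncrasies of real staff, so
field sensitivity/specificity can differ from the synthetic figures.

## Problem sizes and test design

Oracle-equivalence checks run the interval algebra, session machine, and
confusion decomposition against independent brute-force references (a
1-minute grid; a run-enumeration walk) on 1200 randomized small
instances; parameter-recovery runs 100 seeded worker-months (28 days,
10-min cadence, noise ≤ 100 m, dropout ≤ 0.1, personas cycled) and
requires daily totals within 0.5 h of diary truth on ≥ 95 % of days plus
pooled time-overlap sensitivity ≥ 90 %. These sizes give stable
statistics while keeping the full suite fast. Cohort-scale statistics
(group means, t-tests, between-occupation comparisons) require real
participant data and are explicitly out of scope; the property-based
checks above are the package's substitute evidence.

## Known limitations

* No DST or timezone handling; naive local time throughout.
* Breaks *inside* the fence are invisible (overestimates work time).
* Activities indistinguishable from work inside the fence (e.g. education
  in the hospital) are counted as work.
* Address geocoding is not implemented; configuration carries coordinates
  directly, sidestepping geocoding inaccuracy.
* Per-workplace time attribution inside a session is not modelled.
* Rotating shift patterns, split shifts, and public holidays are not
  modelled; a date is a workday iff the schedule says so.
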