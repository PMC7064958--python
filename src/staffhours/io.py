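"""File formats: fix streams (CSV/GPX), worker config (YAML/JSON), diaries,
and report output.

All timestamps are serialized as ISO-8601 without timezone and interpreted
as local time.  Duplicate fix timestamps are collapsed keep-first with a
logged warning; malformed rows fail loudly with their line numbers.
"""

from __future__ import annotations

import csv
import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from datetime import date, datetime, time
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .accounting import WorkReport
from .geo import GeofenceSet, GeoPoint, Workplace
from .schedule import ON_CALL_LINES, OnCallAssignment, RegularSchedule, ScheduleSpec
from .sessions import GpsFix
from .validation import DiaryEntry
from .intervals import WorkInterval

__all__ = [
    "WorkerConfig",
    "ConfigError",
    "FixParseError",
    "read_fixes",
    "write_fixes",
    "read_diary",
    "write_diary",
    "load_config",
    "write_config",
    "write_report",
]

logger = logging.getLogger("staffhours")

PathLike = Union[str, Path]

_WEEKDAY_NAMES = {
    "mon": 0, "tue": 1, "wed": 2, "thu": 3, "fri": 4, "sat": 5, "sun": 6,
}
_LINE_ALIASES = {"first": "first_line", "second": "second_line"}


class ConfigError(ValueError):
    """Invalid or incomplete worker configuration."""


class FixParseError(ValueError):
    """A fix file contained rows that could not be parsed."""


@dataclass(frozen=True)
class WorkerConfig:
    """One worker's full configuration.

    The engine parameters default to the production constants: 1-km
    geofences, 30-minute dwell confirmation, 8-hour gap integration, and a
    10-minute sampling cadence.  All are overridable per worker.
    """

    home: GeoPoint
    workplaces: GeofenceSet
    schedule: ScheduleSpec
    geofence_radius_km: float = 1.0
    residence_exclusion_km: float = 1.0
    merge_gap_hours: float = 8.0
    confirm_minutes: float = 30.0
    cadence_minutes: float = 10.0

    def with_radius(self, radius_km: float) -> "WorkerConfig":
        """A copy with every workplace's fence radius replaced."""
        fences = GeofenceSet(
            tuple(Workplace(w.id, w.center, radius_km) for w in self.workplaces)
        )
        return WorkerConfig(
            home=self.home, workplaces=fences, schedule=self.schedule,
            geofence_radius_km=radius_km,
            residence_exclusion_km=self.residence_exclusion_km,
            merge_gap_hours=self.merge_gap_hours,
            confirm_minutes=self.confirm_minutes,
            cadence_minutes=self.cadence_minutes,
        )


# ---------------------------------------------------------------------------
# fixes

def read_fixes(path: PathLike, fmt: Optional[str] = None) -> list[GpsFix]:
    """Read a fix stream from CSV (``timestamp,lat,lon``) or GPX.

    The format is inferred from the extension unless ``fmt`` is given.
    Output is time-sorted with duplicate timestamps collapsed (keep first,
    warn).  Malformed rows raise :class:`FixParseError` naming the rows.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gpx" if path.suffix.lower() == ".gpx" else "csv"
    if fmt == "csv":
        fixes = _read_fixes_csv(path)
    elif fmt == "gpx":
        fixes = _read_fixes_gpx(path)
    else:
        raise ValueError(f"unknown fix format {fmt!r} (expected 'csv' or 'gpx')")
    fixes.sort(key=lambda f: f.t)
    deduped: list[GpsFix] = []
    dupes = 0
    for f in fixes:
        if deduped and f.t == deduped[-1].t:
            dupes += 1
            continue
        deduped.append(f)
    if dupes:
        logger.warning("%s: collapsed %d duplicate fix timestamp(s), kept first", path, dupes)
    if not deduped:
        logger.warning("%s: no fixes found", path)
    return deduped


def _read_fixes_csv(path: Path) -> list[GpsFix]:
    df = pd.read_csv(path)
    if df.empty:
        return []
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        ts_col = cols.get("timestamp") or cols["time"]
        lat_col = cols.get("lat") or cols["latitude"]
        lon_col = cols.get("lon") or cols.get("lng") or cols["longitude"]
    except KeyError as exc:
        raise FixParseError(
            f"{path}: expected columns timestamp/lat/lon, got {list(df.columns)}"
        ) from exc
    ts = pd.to_datetime(df[ts_col], errors="coerce", format="ISO8601")
    lat = pd.to_numeric(df[lat_col], errors="coerce")
    lon = pd.to_numeric(df[lon_col], errors="coerce")
    bad = ts.isna() | lat.isna() | lon.isna()
    if bad.any():
        # +2: 1-based line numbers plus the header row
        rows = [int(i) + 2 for i in df.index[bad][:20]]
        raise FixParseError(f"{path}: malformed rows at lines {rows}")
    out = []
    for t, la, lo in zip(ts, lat, lon):
        t = t.to_pydatetime()
        if t.tzinfo is not None:
            t = t.replace(tzinfo=None)
        out.append(GpsFix(t=t, p=GeoPoint(float(la), float(lo))))
    return out


def _read_fixes_gpx(path: Path) -> list[GpsFix]:
    tree = ET.parse(path)
    out = []
    for el in tree.iter():
        if el.tag.rsplit("}", 1)[-1] != "trkpt":
            continue
        time_el = next((c for c in el if c.tag.rsplit("}", 1)[-1] == "time"), None)
        if time_el is None or time_el.text is None:
            raise FixParseError(f"{path}: trkpt without <time> element")
        t = datetime.fromisoformat(time_el.text.strip().replace("Z", "+00:00"))
        if t.tzinfo is not None:
            t = t.replace(tzinfo=None)
        out.append(GpsFix(t=t, p=GeoPoint(float(el.get("lat")), float(el.get("lon")))))
    return out


def write_fixes(fixes: Sequence[GpsFix], path: PathLike) -> None:
    """Write a fix stream as the canonical ``timestamp,lat,lon`` CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp", "lat", "lon"])
        for f in fixes:
            w.writerow([f.t.isoformat(), f"{f.p.latitude:.6f}", f"{f.p.longitude:.6f}"])


# ---------------------------------------------------------------------------
# diaries

def read_diary(path: PathLike) -> dict[str, list[DiaryEntry]]:
    """Read a self-report diary CSV (``person_id,date,start,end``).

    ``start``/``end`` are clock times within the row's date; ``end`` may be
    ``24:00`` to denote end of day.  Returns entries grouped per person.
    """
    df = pd.read_csv(path, dtype=str)
    per: dict[str, dict[date, list[WorkInterval]]] = {}
    for i, row in df.iterrows():
        try:
            pid = str(row["person_id"])
            d = date.fromisoformat(row["date"].strip())
            iv = WorkInterval(
                _combine(d, row["start"].strip()),
                _combine(d, row["end"].strip()),
                source="manual",
            )
        except (KeyError, ValueError) as exc:
            raise FixParseError(f"{path}: malformed diary row at line {int(i) + 2}: {exc}") from exc
        per.setdefault(pid, {}).setdefault(d, []).append(iv)
    return {
        pid: [DiaryEntry(day=d, intervals=tuple(sorted(ivs, key=lambda x: x.start)))
              for d, ivs in sorted(days.items())]
        for pid, days in per.items()
    }


def _combine(d: date, hhmm: str) -> datetime:
    if hhmm in ("24:00", "24:00:00"):
        return datetime.combine(d, time(0, 0)) + pd.Timedelta(days=1).to_pytimedelta()
    return datetime.combine(d, time.fromisoformat(hhmm))


def write_diary(entries: Sequence[DiaryEntry], path: PathLike, person_id: str = "sim") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id", "date", "start", "end"])
        for e in entries:
            for iv in e.intervals:
                end = "24:00" if iv.end.date() != e.day else iv.end.strftime("%H:%M")
                w.writerow([person_id, e.day.isoformat(), iv.start.strftime("%H:%M"), end])


# ---------------------------------------------------------------------------
# config

def load_config(path: PathLike) -> WorkerConfig:
    """Load and validate a worker config from YAML (or JSON; YAML superset)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return _config_from_dict(raw, str(path))


def _config_from_dict(raw: dict, where: str) -> WorkerConfig:
    try:
        home_raw = raw["home"]
        home = GeoPoint(float(home_raw["latitude"]), float(home_raw["longitude"]))
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{where}: missing or malformed 'home' (latitude/longitude)") from exc

    default_radius = float(raw.get("geofence_radius_km", 1.0))
    wp_raw = raw.get("workplaces") or []
    if len(wp_raw) > 5:
        raise ConfigError(
            f"{where}: {len(wp_raw)} workplaces configured; the engine tracks at most 5"
        )
    try:
        fences = GeofenceSet(tuple(
            Workplace(
                str(w["id"]),
                GeoPoint(float(w["latitude"]), float(w["longitude"])),
                float(w.get("radius_km", default_radius)),
            )
            for w in wp_raw
        ))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: malformed 'workplaces': {exc}") from exc

    sched_raw = raw.get("schedule")
    if not sched_raw or "regular" not in sched_raw:
        raise ConfigError(f"{where}: missing 'schedule.regular' (start/end times required)")
    reg_raw = sched_raw["regular"]
    try:
        workdays = frozenset(
            _WEEKDAY_NAMES[d.lower()[:3]] if isinstance(d, str) else int(d)
            for d in reg_raw.get("workdays", ["mon", "tue", "wed", "thu", "fri"])
        )
        regular = RegularSchedule(
            time.fromisoformat(str(reg_raw["start"])),
            time.fromisoformat(str(reg_raw["end"])),
            workdays,
        )
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"{where}: malformed 'schedule.regular': {exc}") from exc
    assignments = []
    for entry in sched_raw.get("on_call") or []:
        try:
            line = str(entry["line"]).lower()
            line = _LINE_ALIASES.get(line, line)
            if line not in ON_CALL_LINES:
                raise ValueError(f"unknown on-call line {entry['line']!r}")
            d = entry["date"]
            d = d if isinstance(d, date) else date.fromisoformat(str(d))
            assignments.append(OnCallAssignment(d, line))
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"{where}: malformed on-call entry {entry!r}: {exc}") from exc

    return WorkerConfig(
        home=home,
        workplaces=fences,
        schedule=ScheduleSpec(regular=regular, on_call=tuple(assignments)),
        geofence_radius_km=default_radius,
        residence_exclusion_km=float(raw.get("residence_exclusion_km", 1.0)),
        merge_gap_hours=float(raw.get("merge_gap_hours", 8.0)),
        confirm_minutes=float(raw.get("confirm_minutes", 30.0)),
        cadence_minutes=float(raw.get("cadence_minutes", 10.0)),
    )


def write_config(cfg: WorkerConfig, path: PathLike) -> None:
    data = {
        "home": {"latitude": cfg.home.latitude, "longitude": cfg.home.longitude},
        "workplaces": [
            {"id": w.id, "latitude": w.center.latitude,
             "longitude": w.center.longitude, "radius_km": w.radius_km}
            for w in cfg.workplaces
        ],
        "schedule": {
            "regular": {
                "start": cfg.schedule.regular.start_time.strftime("%H:%M"),
                "end": cfg.schedule.regular.end_time.strftime("%H:%M"),
                "workdays": sorted(cfg.schedule.regular.workdays),
            },
            "on_call": [
                {"date": a.date.isoformat(), "line": a.line} for a in cfg.schedule.on_call
            ],
        },
        "geofence_radius_km": cfg.geofence_radius_km,
        "residence_exclusion_km": cfg.residence_exclusion_km,
        "merge_gap_hours": cfg.merge_gap_hours,
        "confirm_minutes": cfg.confirm_minutes,
        "cadence_minutes": cfg.cadence_minutes,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# reports

def write_report(report: WorkReport, path: PathLike, fmt: str = "json") -> None:
    """Write a report as stable-keyed JSON or as a daily-breakdown CSV.

    Hours are rounded to 0.1 in both formats; identical reports serialize
    byte-identically.
    """
    path = Path(path)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["date", "total_hours", "gps_hours", "oncall_hours"])
            for row in report.daily_breakdown:
                w.writerow([
                    row.date.isoformat(),
                    f"{row.total:.1f}", f"{row.gps:.1f}", f"{row.on_call:.1f}",
                ])
    else:
        raise ValueError(f"unknown report format {fmt!r} (expected 'json' or 'csv')")
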