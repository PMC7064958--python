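"""Geodesic distance, circular geofences, and the residence-eligibility rule.

Workplaces are modelled as circular geofences around a coordinate pair.  A
location fix is "at work" when it falls within ``radius_km`` (default 1 km)
of any configured workplace centre; distance is great-circle (haversine) on
a sphere of mean Earth radius, which is accurate to well under a metre per
kilometre at the 1-km scale geofencing operates on.

Workers who live inside one of their own workplace geofences cannot be
tracked by geofencing at all (home and work are indistinguishable), so an
eligibility check against the home coordinate is part of this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "Workplace",
    "GeofenceSet",
    "distance_km",
    "in_geofence",
    "check_eligibility",
    "EligibilityResult",
]

#: IUGG mean Earth radius.
EARTH_RADIUS_KM = 6371.0088

#: The app tracks at most this many workplaces simultaneously.
MAX_WORKPLACES = 5


@dataclass(frozen=True)
class GeoPoint:
    """A latitude/longitude pair in decimal degrees (WGS84, no altitude).

    Longitude is normalized into ``[-180, 180)`` on construction; latitude
    outside ``[-90, 90]`` raises ``ValueError``.
    """

    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.latitude) or not math.isfinite(self.longitude):
            raise ValueError(f"non-finite coordinate: ({self.latitude}, {self.longitude})")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        lon = self.longitude
        if not -180.0 <= lon < 180.0:
            lon = ((lon + 180.0) % 360.0) - 180.0
            object.__setattr__(self, "longitude", lon)


@dataclass(frozen=True)
class Workplace:
    """A named circular geofence: ``id``, centre, and radius in km."""

    id: str
    center: GeoPoint
    radius_km: float = 1.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("workplace id must be a nonempty string")
        if not (self.radius_km > 0):
            raise ValueError(f"radius_km must be positive, got {self.radius_km}")


@dataclass(frozen=True)
class GeofenceSet:
    """An ordered collection of 1-5 workplaces with unique ids.

    Order matters: when fences overlap, the first match wins.
    """

    workplaces: tuple[Workplace, ...]

    def __post_init__(self) -> None:
        wps = tuple(self.workplaces)
        object.__setattr__(self, "workplaces", wps)
        if not 1 <= len(wps) <= MAX_WORKPLACES:
            raise ValueError(
                f"a GeofenceSet holds 1-{MAX_WORKPLACES} workplaces, got {len(wps)}"
            )
        ids = [w.id for w in wps]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate workplace ids: {ids}")

    def __iter__(self) -> Iterator[Workplace]:
        return iter(self.workplaces)

    def __len__(self) -> int:
        return len(self.workplaces)

    def __getitem__(self, key: int) -> Workplace:
        return self.workplaces[key]

    def by_id(self, workplace_id: str) -> Workplace:
        for w in self.workplaces:
            if w.id == workplace_id:
                return w
        raise KeyError(workplace_id)


def distance_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points, in kilometres.

    Haversine formula on a sphere of radius :data:`EARTH_RADIUS_KM`.
    Symmetric, nonnegative, and exactly zero for identical points.
    """
    if a == b:
        return 0.0
    phi1 = math.radians(a.latitude)
    phi2 = math.radians(b.latitude)
    dphi = phi2 - phi1
    dlam = math.radians(b.longitude - a.longitude)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    # clamp guards rounding for near-antipodal pairs
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def in_geofence(p: GeoPoint, fences: GeofenceSet) -> Optional[str]:
    """Return the id of the first workplace whose fence contains ``p``.

    The boundary is inclusive: a point exactly ``radius_km`` from the centre
    counts as inside (float noise at the fence should not drop fixes).
    Returns ``None`` when no fence matches.
    """
    if not isinstance(fences, GeofenceSet):
        raise TypeError("fences must be a GeofenceSet")
    for w in fences:
        if distance_km(p, w.center) <= w.radius_km:
            return w.id
    return None


@dataclass(frozen=True)
class EligibilityResult:
    """Outcome of the residence check: eligible flag plus offending fences."""

    eligible: bool
    offending_ids: tuple[str, ...] = field(default=())


def check_eligibility(
    home: GeoPoint,
    fences: GeofenceSet,
    exclusion_km: Optional[float] = None,
) -> EligibilityResult:
    """Check whether a worker's home is far enough from every workplace.

    Geofencing cannot distinguish "at work" from "at home" for someone who
    lives inside a workplace fence, so such workers are ineligible.  With
    ``exclusion_km=None`` each workplace's own ``radius_km`` is the
    exclusion radius; pass a number to use one radius for all workplaces.
    The boundary is inclusive: exactly on the radius is ineligible.
    """
    offending = []
    for w in fences:
        radius = w.radius_km if exclusion_km is None else exclusion_km
        if distance_km(home, w.center) <= radius:
            offending.append(w.id)
    return EligibilityResult(eligible=not offending, offending_ids=tuple(offending))
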