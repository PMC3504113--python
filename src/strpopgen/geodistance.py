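"""Great-circle geography with migration-gateway waypoints.

Distances between populations on different landmasses are computed as sums
of great-circle legs through obligatory waypoints representing the likely
migration gateways between continental landmasses (Anadyr, Cairo, Istanbul,
Phnom Penh and Prince Rupert); e.g. the distance from a North American
population to East Africa is population -> Anadyr -> Cairo -> destination.
Distances within a landmass are direct great circles on a sphere of radius
6371 km.

The shipped routing table (region -> landmass -> waypoint legs) is a
documented default and fully overridable through :class:`WaypointConfig`;
the regression of within-population diversity on distance from an origin
(default Addis Ababa, for the out-of-Africa expansion) is ordinary least
squares with a t-test on the slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .amova import DistanceMatrix
from .str_io import PopulationMetadata

__all__ = [
    "EARTH_RADIUS_KM",
    "ADDIS_ABABA",
    "RoutingError",
    "WaypointConfig",
    "RegressionResult",
    "haversine_km",
    "route_distance",
    "pairwise_geo_matrix",
    "distances_from_origin",
    "diversity_distance_regression",
]

EARTH_RADIUS_KM = 6371.0

#: Default origin of the expansion: Addis Ababa, Ethiopia.
ADDIS_ABABA = (9.03, 38.74)

DEFAULT_WAYPOINTS: dict[str, tuple[float, float]] = {
    "Anadyr": (64.73, 177.51),
    "Cairo": (30.06, 31.25),
    "Istanbul": (41.01, 28.98),
    "Phnom Penh": (11.55, 104.92),
    "Prince Rupert": (54.32, -130.32),
}

#: Region label -> landmass used for waypoint routing.  The 12 geographic
#: groups double as routing regions by default; extra keys are harmless.
DEFAULT_REGION_LANDMASS: dict[str, str] = {
    "NAF": "AFRICA", "SAF": "AFRICA",
    "EUR": "EUROPE",
    "SWAS": "ASIA", "SAS": "ASIA", "CAS": "ASIA", "SEAS": "ASIA",
    "EAS": "ASIA", "NEAS": "ASIA",
    "AUS": "OCEANIA",
    "NAM": "NAMERICA", "CSAM": "SAMERICA",
    "LINE": "LINE",
}

#: Ordered waypoint legs between landmasses (origin -> destination).  The
#: reverse route is the reversed list.  Same-landmass pairs are direct.
DEFAULT_ROUTES: dict[tuple[str, str], tuple[str, ...]] = {
    ("AFRICA", "EUROPE"): ("Cairo", "Istanbul"),
    ("AFRICA", "ASIA"): ("Cairo",),
    ("AFRICA", "OCEANIA"): ("Cairo", "Phnom Penh"),
    ("AFRICA", "NAMERICA"): ("Cairo", "Anadyr"),
    ("AFRICA", "SAMERICA"): ("Cairo", "Anadyr", "Prince Rupert"),
    ("EUROPE", "ASIA"): ("Istanbul",),
    ("EUROPE", "OCEANIA"): ("Istanbul", "Phnom Penh"),
    ("EUROPE", "NAMERICA"): ("Istanbul", "Anadyr"),
    ("EUROPE", "SAMERICA"): ("Istanbul", "Anadyr", "Prince Rupert"),
    ("ASIA", "OCEANIA"): ("Phnom Penh",),
    ("ASIA", "NAMERICA"): ("Anadyr",),
    ("ASIA", "SAMERICA"): ("Anadyr", "Prince Rupert"),
    ("OCEANIA", "NAMERICA"): ("Phnom Penh", "Anadyr"),
    ("OCEANIA", "SAMERICA"): ("Phnom Penh", "Anadyr", "Prince Rupert"),
    ("NAMERICA", "SAMERICA"): (),
}


class RoutingError(KeyError):
    """A region pair cannot be resolved to a waypoint route."""


def _validate_latlon(point: Sequence[float]) -> tuple[float, float]:
    lat, lon = float(point[0]), float(point[1])
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        raise ValueError(f"invalid coordinates ({lat}, {lon})")
    return lat, lon


def haversine_km(a: Sequence[float], b: Sequence[float],
                 radius: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance between two (lat, lon) points, in km."""
    lat1, lon1 = _validate_latlon(a)
    lat2, lon2 = _validate_latlon(b)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2.0 * radius * math.asin(min(1.0, math.sqrt(h)))


@dataclass
class WaypointConfig:
    """Named waypoints plus the landmass routing table.

    ``routes`` maps an ordered (origin landmass, destination landmass) pair
    to the waypoint names to pass through, in order; only one direction
    needs to be present (the reverse is the reversed list) and routes are
    validated to be symmetric if both directions are given.
    """

    waypoints: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WAYPOINTS))
    region_landmass: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REGION_LANDMASS))
    routes: dict[tuple[str, str], tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ROUTES))
    radius: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        for name, pt in self.waypoints.items():
            _validate_latlon(pt)
        for (a, b), legs in self.routes.items():
            rev = self.routes.get((b, a))
            if rev is not None and tuple(reversed(rev)) != tuple(legs):
                raise ValueError(f"routes for ({a},{b}) and ({b},{a}) are not mirror images")
            for w in legs:
                if w not in self.waypoints:
                    raise ValueError(f"route ({a},{b}) references unknown waypoint {w!r}")

    def landmass(self, region: str) -> str:
        try:
            return self.region_landmass[region]
        except KeyError:
            raise RoutingError(f"region {region!r} has no landmass assignment")

    def route(self, origin_region: str, dest_region: str) -> list[tuple[float, float]]:
        """Waypoint coordinates, in travel order, between two regions."""
        a, b = self.landmass(origin_region), self.landmass(dest_region)
        if a == b:
            return []
        if (a, b) in self.routes:
            names = self.routes[(a, b)]
        elif (b, a) in self.routes:
            names = tuple(reversed(self.routes[(b, a)]))
        else:
            raise RoutingError(f"no route configured between landmasses {a!r} and {b!r}")
        return [self.waypoints[w] for w in names]


def route_distance(origin: Sequence[float], origin_region: str,
                   destination: Sequence[float], dest_region: str,
                   config: WaypointConfig | None = None) -> float:
    """Waypoint-constrained distance: the sum of great-circle legs through
    the configured route; with an empty route this is the direct distance."""
    cfg = config or WaypointConfig()
    points = [tuple(origin), *cfg.route(origin_region, dest_region), tuple(destination)]
    return float(sum(haversine_km(points[i], points[i + 1], cfg.radius)
                     for i in range(len(points) - 1)))


def distances_from_origin(meta: PopulationMetadata,
                          origin: Sequence[float] = ADDIS_ABABA,
                          origin_region: str = "SAF",
                          config: WaypointConfig | None = None) -> dict[str, float]:
    """Waypoint-routed distance of every population from the origin point."""
    cfg = config or WaypointConfig()
    return {pop: route_distance(meta.coords(pop), meta.region(pop), origin,
                                origin_region, cfg)
            for pop in meta.populations}


def pairwise_geo_matrix(meta: PopulationMetadata,
                        config: WaypointConfig | None = None,
                        populations: Sequence[str] | None = None) -> DistanceMatrix:
    """Symmetric matrix of waypoint-routed distances between populations.

    Same-landmass pairs use the direct great circle; cross-landmass pairs
    sum the configured waypoint legs.  Unresolvable regions raise
    :class:`RoutingError` (no silent fallback)."""
    cfg = config or WaypointConfig()
    pops = list(populations) if populations is not None else meta.populations
    n = len(pops)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = route_distance(meta.coords(pops[i]), meta.region(pops[i]),
                               meta.coords(pops[j]), meta.region(pops[j]), cfg)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(pops, mat)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    t: float
    p: float
    n: int


def diversity_distance_regression(values: Mapping[str, float] | Sequence[float],
                                  distances: Mapping[str, float] | Sequence[float]
                                  ) -> RegressionResult:
    """OLS regression of a per-population diversity index on distance from
    the origin; reports R^2 and the two-sided t-test p-value of the slope.

    Mapping inputs are paired by population id; sequence inputs positionally.
    """
    if isinstance(values, Mapping) and isinstance(distances, Mapping):
        pops = [p for p in values if p in distances]
        y = np.array([values[p] for p in pops], dtype=float)
        x = np.array([distances[p] for p in pops], dtype=float)
    else:
        y = np.asarray(values, dtype=float)
        x = np.asarray(distances, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the distance predictor")
    res = stats.linregress(x, y)
    t = res.slope / res.stderr if res.stderr > 0 else math.inf * np.sign(res.slope)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2), t=float(t),
                            p=float(res.pvalue), n=len(x))
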