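"""Shared domain types for the otolith-chemistry pipeline.

The pipeline follows one fish through several representations: an ordered
laser-ablation transect (:class:`OtolithTransect`), summary chemistry of its
nuclear and marginal otolith regions (:class:`RegionSignature`), and catch
metadata (:class:`FishRecord`).  Environmental inputs are gridded fields
(:class:`EnvField`) and sub-population polygons (:class:`AreaPolygon`).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AblationPoint",
    "OtolithTransect",
    "FishRecord",
    "RegionSignature",
    "DepthStratum",
    "EnvField",
    "AreaPolygon",
]


@dataclass
class AblationPoint:
    """One laser-ablation spot along a radial otolith transect.

    Parameters
    ----------
    index : int
        1-based position along the transect (1 = closest to the primordium).
    distance_from_core : float
        Micrometres from the otolith core; strictly increasing with ``index``.
    ratios : dict[str, float]
        Element:Ca ratios keyed by element name (unit-agnostic numbers, as in
        the input tables).  Missing values are ``nan``.
    al_ratio : float or None
        Al:Ca contamination sentinel; ``None`` when Al was not measured.
    """

    index: int
    distance_from_core: float
    ratios: dict[str, float]
    al_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"ablation index must be >= 1, got {self.index}")
        if self.distance_from_core < 0:
            raise ValueError("distance_from_core must be >= 0")


@dataclass
class OtolithTransect:
    """Ordered ablation measurements for one fish."""

    fish_id: str
    points: list[AblationPoint]

    def __post_init__(self) -> None:
        idx = [p.index for p in self.points]
        if idx != sorted(idx):
            self.points = sorted(self.points, key=lambda p: p.index)
            idx = [p.index for p in self.points]
        if len(set(idx)) != len(idx):
            raise ValueError(f"duplicate ablation index in transect for fish {self.fish_id}")
        d = [p.distance_from_core for p in self.points]
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError(
                f"distance_from_core not strictly increasing for fish {self.fish_id}"
            )

    def __len__(self) -> int:
        return len(self.points)

    def series(self, element: str) -> np.ndarray:
        """Return the element:Ca profile as a float array (nan for missing)."""
        return np.array([p.ratios.get(element, math.nan) for p in self.points], dtype=float)

    @property
    def distances(self) -> np.ndarray:
        return np.array([p.distance_from_core for p in self.points], dtype=float)


@dataclass
class FishRecord:
    """Catch metadata for one fish; age/birth-year are derived fields."""

    fish_id: str
    total_length: float  # cm
    capture_date: _dt.date
    capture_lon: float
    capture_lat: float
    capture_event_id: str
    total_weight: float | None = None  # kg
    sex: str = "unknown"  # {F, M, unknown}
    age_at_capture: float | None = None  # years
    birth_year: int | None = None

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise ValueError("total_length must be positive")
        if self.sex not in {"F", "M", "unknown"}:
            raise ValueError(f"sex must be F, M or unknown, got {self.sex!r}")

    def derive_birth_year(self) -> int:
        if self.age_at_capture is None:
            raise ValueError(f"age_at_capture not set for fish {self.fish_id}")
        self.birth_year = self.capture_date.year - round(self.age_at_capture)
        return self.birth_year


@dataclass
class RegionSignature:
    """Multivariate chemistry of one otolith region (nuclear or marginal)."""

    fish_id: str
    region: str  # {nuclear, marginal}
    elemental: dict[str, float] = field(default_factory=dict)
    d18O: float | None = None  # permil VPDB
    d13C: float | None = None  # permil VPDB

    def __post_init__(self) -> None:
        if self.region not in {"nuclear", "marginal"}:
            raise ValueError(f"region must be nuclear or marginal, got {self.region!r}")

    def vector(self, elements: list[str]) -> np.ndarray:
        return np.array([self.elemental.get(e, math.nan) for e in elements], dtype=float)


@dataclass(frozen=True)
class DepthStratum:
    """Half-open depth layer [lower, upper) in metres."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError("stratum upper bound must exceed lower bound")

    @property
    def mid(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def contains(self, depth: float) -> bool:
        return self.lower <= depth < self.upper

    def overlaps(self, lo: float, hi: float) -> bool:
        return self.lower < hi and lo < self.upper


@dataclass
class EnvField:
    """Gridded environmental field (values per cell x depth stratum).

    ``values`` has shape (n_strata, n_lat, n_lon); ``variance`` the same shape
    or ``None``.  Missing cells are ``nan``.
    """

    variable: str  # e.g. "temperature" (degC) or "salinity" (PSU)
    lon: np.ndarray  # cell centres, degrees in [-180, 180)
    lat: np.ndarray
    strata: list[DepthStratum]
    values: np.ndarray
    variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.strata), len(self.lat), len(self.lon))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {expected}"
            )
        if self.variance is not None:
            self.variance = np.asarray(self.variance, dtype=float)
            if self.variance.shape != expected:
                raise ValueError("variance shape does not match grid")
        lows = [s.lower for s in self.strata]
        if lows != sorted(lows):
            raise ValueError("strata must be ordered by depth")
        for a, b in zip(self.strata, self.strata[1:]):
            if b.lower < a.upper:
                raise ValueError("strata must not overlap")

    def stratum_index(self, depth: float) -> int:
        for k, s in enumerate(self.strata):
            if s.contains(depth):
                return k
        raise ValueError(f"depth {depth} m outside declared strata")


@dataclass
class AreaPolygon:
    """Named closed lon/lat ring delimiting a sub-population area."""

    name: str
    boundary: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.boundary) < 4 or self.boundary[0] != self.boundary[-1]:
            raise ValueError(f"polygon {self.name}: ring must be closed with >= 4 vertices")

    def to_shapely(self):
        from shapely.geometry import Polygon

        poly = Polygon(self.boundary)
        if poly.area <= 0:
            raise ValueError(f"polygon {self.name} has zero area")
        return poly


def wrap_lon(lon: float | np.ndarray) -> float | np.ndarray:
    """Normalize longitude to the [-180, 180) convention used throughout."""
    return ((np.asarray(lon) + 180.0) % 360.0) - 180.0


EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km; accepts scalars or broadcastable arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def asdict_shallow(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
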