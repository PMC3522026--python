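"""Domain types for a study region.

A region is the unit the access model operates on: census dissemination
blocks (population-bearing point centroids), physician locations (supply
points) and a road network (polylines with length, speed limit and travel
direction).  All coordinates are planar projected meters; geographic
longitude/latitude input is rejected rather than reprojected, so that
Euclidean distance math stays unambiguous throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DisseminationBlock",
    "PhysicianLocation",
    "RoadSegment",
    "Region",
    "RegionValidationError",
]


class RegionValidationError(ValueError):
    """Raised when an input feature violates a region invariant.

    The message always names the offending feature id so that bad rows in
    large input files can be located.
    """


@dataclass(frozen=True)
class DisseminationBlock:
    """Smallest census geography, represented by its centroid point.

    Parameters
    ----------
    id : str
        Unique identifier within the region.
    x, y : float
        Centroid coordinates in planar projected meters.
    population : float
        Resident population (non-negative; real-valued so synthetic
        generators may produce expectations, though census counts are
        integral).
    area_km2 : float
        Block area in square kilometers (strictly positive); drives the
        population-density eligibility filter.
    """

    id: str
    x: float
    y: float
    population: float
    area_km2: float

    def __post_init__(self) -> None:
        if not self.id:
            raise RegionValidationError("dissemination block with empty id")
        if not np.isfinite(self.x) or not np.isfinite(self.y):
            raise RegionValidationError(
                f"block {self.id!r}: non-finite centroid coordinates"
            )
        if not (self.population >= 0):
            raise RegionValidationError(
                f"block {self.id!r}: population must be >= 0, "
                f"got {self.population!r}"
            )
        if not (self.area_km2 > 0):
            raise RegionValidationError(
                f"block {self.id!r}: area_km2 must be > 0, got {self.area_km2!r}"
            )

    @property
    def density_per_km2(self) -> float:
        """Population density in persons per square kilometer."""
        return self.population / self.area_km2


@dataclass(frozen=True)
class PhysicianLocation:
    """A supply point: one or more primary-care physicians at one location."""

    id: str
    x: float
    y: float
    supply: int

    def __post_init__(self) -> None:
        if not self.id:
            raise RegionValidationError("physician location with empty id")
        if not np.isfinite(self.x) or not np.isfinite(self.y):
            raise RegionValidationError(
                f"physician {self.id!r}: non-finite coordinates"
            )
        if int(self.supply) != self.supply or self.supply < 1:
            raise RegionValidationError(
                f"physician {self.id!r}: supply must be a positive integer, "
                f"got {self.supply!r}"
            )


@dataclass(frozen=True)
class RoadSegment:
    """A road polyline with the attributes needed for travel-time weighting.

    ``direction`` follows one-way street semantics: ``both`` is a two-way
    street, ``forward`` is one-way in polyline vertex order, ``reverse``
    one-way against it.  If ``length_m`` is not supplied it defaults to the
    polyline's Euclidean length.
    """

    id: str
    polyline: tuple[tuple[float, float], ...]
    length_m: float
    speed_kmh: float
    direction: str = "both"

    DIRECTIONS = ("both", "forward", "reverse")

    def __post_init__(self) -> None:
        if not self.id:
            raise RegionValidationError("road segment with empty id")
        if len(self.polyline) < 2:
            raise RegionValidationError(
                f"road {self.id!r}: polyline must have >= 2 points"
            )
        for x, y in self.polyline:
            if not np.isfinite(x) or not np.isfinite(y):
                raise RegionValidationError(
                    f"road {self.id!r}: non-finite vertex coordinates"
                )
        if not (self.length_m > 0):
            raise RegionValidationError(
                f"road {self.id!r}: length_m must be > 0, got {self.length_m!r}"
            )
        if not (self.speed_kmh > 0):
            raise RegionValidationError(
                f"road {self.id!r}: speed_kmh must be > 0, got {self.speed_kmh!r}"
            )
        if self.direction not in self.DIRECTIONS:
            raise RegionValidationError(
                f"road {self.id!r}: direction must be one of "
                f"{self.DIRECTIONS}, got {self.direction!r}"
            )

    @property
    def euclidean_length_m(self) -> float:
        pts = np.asarray(self.polyline, dtype=float)
        return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))

    @property
    def travel_minutes(self) -> float:
        """End-to-end traversal time: (length in km / speed) * 60."""
        return (self.length_m / 1000.0) / self.speed_kmh * 60.0

    @staticmethod
    def with_default_length(
        id: str,
        polyline: Sequence[tuple[float, float]],
        speed_kmh: float,
        direction: str = "both",
        length_m: float | None = None,
    ) -> "RoadSegment":
        """Build a segment, deriving length from geometry when absent."""
        poly = tuple((float(x), float(y)) for x, y in polyline)
        if length_m is None:
            pts = np.asarray(poly, dtype=float)
            length_m = float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))
        return RoadSegment(
            id=id, polyline=poly, length_m=float(length_m),
            speed_kmh=float(speed_kmh), direction=direction,
        )


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise RegionValidationError(f"duplicate {kind} id {i!r}")
        seen.add(i)


@dataclass
class Region:
    """A validated study region: blocks, physicians and roads in one planar CRS.

    Collections may be empty — degenerate regions are legal inputs (a region
    with no physicians simply scores every origin block as having no access).
    """

    blocks: list[DisseminationBlock] = field(default_factory=list)
    physicians: list[PhysicianLocation] = field(default_factory=list)
    roads: list[RoadSegment] = field(default_factory=list)
    crs_note: str = "planar meters (unspecified projection)"

    def __post_init__(self) -> None:
        _check_unique((b.id for b in self.blocks), "dissemination block")
        _check_unique((p.id for p in self.physicians), "physician location")
        _check_unique((r.id for r in self.roads), "road segment")

    def block_by_id(self) -> dict[str, DisseminationBlock]:
        return {b.id: b for b in self.blocks}

    def physician_by_id(self) -> dict[str, PhysicianLocation]:
        return {p.id: p for p in self.physicians}
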