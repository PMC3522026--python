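"""Shared fixtures: tiny hand-built regions used across the suite."""

from __future__ import annotations

import pytest

from graviaccess import (
    DisseminationBlock,
    PhysicianLocation,
    Region,
    RoadSegment,
)


def make_line_region(
    length_m: float,
    speed_kmh: float = 60.0,
    population: float = 100.0,
    supply: int = 1,
    n_vertices: int = 2,
) -> Region:
    """One straight east-west road; block at the west end, physician at the east.

    Travel time end-to-end is (length_m/1000)/speed_kmh*60 minutes.
    """
    xs = [length_m * i / (n_vertices - 1) for i in range(n_vertices)]
    road = RoadSegment.with_default_length(
        id="r1", polyline=[(x, 0.0) for x in xs], speed_kmh=speed_kmh,
    )
    return Region(
        blocks=[DisseminationBlock(id="b1", x=0.0, y=10.0,
                                   population=population, area_km2=1.0)],
        physicians=[PhysicianLocation(id="p1", x=length_m, y=10.0,
                                      supply=supply)],
        roads=[road],
    )


@pytest.fixture
def line_region_10min() -> Region:
    """Block and physician 10 km apart at 60 km/h: exactly 10 minutes."""
    return make_line_region(10_000.0, speed_kmh=60.0)


@pytest.fixture
def line_region_130min() -> Region:
    """Block and physician 130 minutes apart: beyond the 120-minute cutoff."""
    return make_line_region(130_000.0, speed_kmh=60.0)
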