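"""Seeded synthetic study regions.

Real inputs for this kind of analysis — census block centroids with
population, a physician directory geocoded to postal centroids, and a
licensed road file with speeds and directionality — are proprietary.
This module generates regions with the same statistical anatomy so every
pipeline stage is testable without a download: clustered urban
populations with heavy-tailed block sizes, sparse low-density blocks that
trip the eligibility filter, physicians concentrated in population hubs,
and road topologies (grid, radial, sparse spine, disconnected island
hubs) that reproduce the two regimes seen on real access maps — a smooth
access gradient around metropolitan cores, and binary served/unserved
geography where settlements are road-isolated.

Everything is driven by one integer seed through per-entity-type
substreams, so the same spec always yields the same region and adding
blocks does not reshuffle physician placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .region import (
    DisseminationBlock,
    PhysicianLocation,
    Region,
    RoadSegment,
)

__all__ = ["ScenarioSpec", "generate", "scenario_presets",
           "spec_to_config", "spec_from_config"]

PATTERNS = ("urban_gradient", "binary_remote", "corridor", "uniform")
ROAD_STYLES = ("grid", "radial", "sparse_spine")


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic region.

    Attributes
    ----------
    seed : int
        Root of all randomness; identical spec + seed gives an identical
        region.
    extent_km : float
        Width and height of the square region, kilometers.
    n_blocks, n_physician_locations : int
        Entity counts (physician locations may hold several physicians).
    pattern : str
        Spatial regime: ``urban_gradient`` (metropolitan cores with rural
        hinterland), ``binary_remote`` (isolated settlement hubs),
        ``corridor`` (population strung along one spine road), or
        ``uniform``.
    urban_fraction : float
        Share of blocks placed in clustered cores/hubs/towns.
    road_style : str
        ``grid``, ``radial`` or ``sparse_spine`` (hub patterns always use
        local mini-grids).
    speed_profile : dict
        km/h per road class, keys ``arterial`` and ``local``.
    disconnect_fraction : float
        Share of settlement hubs left without any road link to a
        physician hub (only meaningful for ``binary_remote``).
    """

    seed: int
    extent_km: float = 100.0
    n_blocks: int = 200
    n_physician_locations: int = 10
    pattern: str = "urban_gradient"
    urban_fraction: float = 0.6
    road_style: str = "grid"
    speed_profile: dict[str, float] = field(
        default_factory=lambda: {"arterial": 80.0, "local": 50.0}
    )
    disconnect_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_physician_locations < 1:
            raise ValueError("entity counts must be positive")
        if self.extent_km <= 0:
            raise ValueError("extent_km must be positive")
        if not (0.0 <= self.urban_fraction <= 1.0):
            raise ValueError("urban_fraction must lie in [0, 1]")
        if not (0.0 <= self.disconnect_fraction <= 1.0):
            raise ValueError("disconnect_fraction must lie in [0, 1]")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.road_style not in ROAD_STYLES:
            raise ValueError(f"road_style must be one of {ROAD_STYLES}")
        for cls in ("arterial", "local"):
            if self.speed_profile.get(cls, 0) <= 0:
                raise ValueError(f"speed_profile[{cls!r}] must be positive")


# ---------------------------------------------------------------------------
# road builders

def _grid_roads(x0: float, y0: float, x1: float, y1: float, spacing_m: float,
                speeds: dict[str, float], prefix: str,
                arterial_every: int = 5) -> list[RoadSegment]:
    """Rectangular grid; every ``arterial_every``-th line is arterial."""
    xs = np.arange(x0, x1 + spacing_m / 2, spacing_m)
    ys = np.arange(y0, y1 + spacing_m / 2, spacing_m)
    roads: list[RoadSegment] = []
    for iy, y in enumerate(ys):
        speed = speeds["arterial"] if iy % arterial_every == 0 else speeds["local"]
        for ix in range(len(xs) - 1):
            roads.append(RoadSegment.with_default_length(
                id=f"{prefix}h{iy}-{ix}",
                polyline=[(xs[ix], y), (xs[ix + 1], y)],
                speed_kmh=speed,
            ))
    for ix, x in enumerate(xs):
        speed = speeds["arterial"] if ix % arterial_every == 0 else speeds["local"]
        for iy in range(len(ys) - 1):
            roads.append(RoadSegment.with_default_length(
                id=f"{prefix}v{ix}-{iy}",
                polyline=[(x, ys[iy]), (x, ys[iy + 1])],
                speed_kmh=speed,
            ))
    return roads


def _radial_roads(cx: float, cy: float, r_max: float, speeds: dict[str, float],
                  n_spokes: int = 12, dr_m: float = 2000.0,
                  ring_every: int = 4) -> list[RoadSegment]:
    """Spokes from a center with concentric ring roads sharing spoke nodes."""
    angles = np.linspace(0, 2 * math.pi, n_spokes, endpoint=False)
    radii = np.arange(dr_m, r_max + dr_m / 2, dr_m)
    roads: list[RoadSegment] = []
    for ia, a in enumerate(angles):
        pts = [(cx, cy)] + [(cx + r * math.cos(a), cy + r * math.sin(a))
                            for r in radii]
        roads.append(RoadSegment.with_default_length(
            id=f"spoke{ia}", polyline=pts, speed_kmh=speeds["arterial"],
        ))
    for ir, r in enumerate(radii):
        if (ir + 1) % ring_every:
            continue
        pts = [(cx + r * math.cos(a), cy + r * math.sin(a)) for a in angles]
        pts.append(pts[0])
        roads.append(RoadSegment.with_default_length(
            id=f"ring{ir}", polyline=pts, speed_kmh=speeds["local"],
        ))
    return roads


def _spine_roads(extent_m: float, y: float, speeds: dict[str, float],
                 branch_xs: Iterable[float], dr_m: float = 1000.0
                 ) -> list[RoadSegment]:
    """One horizontal arterial spine with vertical local branches."""
    xs = np.arange(0.0, extent_m + dr_m / 2, dr_m)
    pts = [(x, y) for x in xs]
    roads = [RoadSegment.with_default_length(
        id="spine", polyline=pts, speed_kmh=speeds["arterial"])]
    for i, bx in enumerate(branch_xs):
        bx = min(xs, key=lambda x: abs(x - bx))  # branch joins at a spine node
        up = [(bx, y + j * dr_m) for j in range(4)]
        dn = [(bx, y - j * dr_m) for j in range(4)]
        roads.append(RoadSegment.with_default_length(
            id=f"branch{i}u", polyline=up, speed_kmh=speeds["local"]))
        roads.append(RoadSegment.with_default_length(
            id=f"branch{i}d", polyline=dn, speed_kmh=speeds["local"]))
    return roads


def _hub_grid(cx: float, cy: float, half_span_m: float, spacing_m: float,
              speed: float, prefix: str) -> list[RoadSegment]:
    return _grid_roads(cx - half_span_m, cy - half_span_m,
                       cx + half_span_m, cy + half_span_m,
                       spacing_m, {"arterial": speed, "local": speed},
                       prefix=prefix, arterial_every=10**9)


# ---------------------------------------------------------------------------
# generation

def generate(spec: ScenarioSpec) -> Region:
    """Generate a reproducible synthetic region from a scenario spec.

    Raises
    ------
    ValueError
        For an infeasible spec (more physician locations than candidate
        sites, i.e. ``n_physician_locations > n_blocks``).
    """
    if spec.n_physician_locations > spec.n_blocks:
        raise ValueError(
            f"{spec.n_physician_locations} physician locations exceed the "
            f"{spec.n_blocks} candidate block sites"
        )
    ss = np.random.SeedSequence(spec.seed)
    ss_layout, ss_blocks, ss_phys = ss.spawn(3)
    rng_layout = np.random.default_rng(ss_layout)
    rng_blocks = np.random.default_rng(ss_blocks)
    rng_phys = np.random.default_rng(ss_phys)

    builder = {
        "urban_gradient": _gen_urban_gradient,
        "binary_remote": _gen_binary_remote,
        "corridor": _gen_corridor,
        "uniform": _gen_uniform,
    }[spec.pattern]
    blocks, physicians, roads = builder(spec, rng_layout, rng_blocks, rng_phys)
    return Region(
        blocks=blocks, physicians=physicians, roads=roads,
        crs_note=f"synthetic planar meters (seed={spec.seed}, "
                 f"pattern={spec.pattern})",
    )


def _make_blocks(rng: np.random.Generator, xy: np.ndarray, pops: np.ndarray,
                 areas: np.ndarray, prefix: str = "B") -> list[DisseminationBlock]:
    return [
        DisseminationBlock(
            id=f"{prefix}{i:04d}", x=float(x), y=float(y),
            population=float(round(p)), area_km2=float(round(a, 4)),
        )
        for i, ((x, y), p, a) in enumerate(zip(xy, pops, areas))
    ]


def _supplies(rng: np.random.Generator, n: int) -> np.ndarray:
    # 1 + heavy-ish tail: most locations solo/small group practices
    return 1 + rng.poisson(2.0, size=n)


def _gen_uniform(spec, rng_layout, rng_blocks, rng_phys):
    ext = spec.extent_km * 1000.0
    n = spec.n_blocks
    xy = rng_blocks.uniform(0.06 * ext, 0.94 * ext, size=(n, 2))
    pops = 20 + rng_blocks.lognormal(mean=4.0, sigma=0.8, size=n)
    areas = rng_blocks.uniform(0.5, 3.0, size=n)
    blocks = _make_blocks(rng_blocks, xy, pops, areas)

    sites = rng_phys.choice(n, size=spec.n_physician_locations, replace=False)
    jitter = rng_phys.normal(0, 200.0, size=(spec.n_physician_locations, 2))
    supplies = _supplies(rng_phys, spec.n_physician_locations)
    physicians = [
        PhysicianLocation(
            id=f"P{i:03d}",
            x=float(np.clip(xy[s, 0] + jitter[i, 0], 0, ext)),
            y=float(np.clip(xy[s, 1] + jitter[i, 1], 0, ext)),
            supply=int(supplies[i]),
        )
        for i, s in enumerate(sites)
    ]
    roads = _build_area_roads(spec, ext, rng_layout)
    return blocks, physicians, roads


def _build_area_roads(spec, ext, rng_layout):
    if spec.road_style == "grid":
        return _grid_roads(0, 0, ext, ext, 3000.0, spec.speed_profile, "g")
    if spec.road_style == "radial":
        return _radial_roads(ext / 2, ext / 2, 0.75 * ext, spec.speed_profile)
    towns = np.sort(rng_layout.uniform(0.1 * ext, 0.9 * ext, size=5))
    return _spine_roads(ext, ext / 2, spec.speed_profile, towns)


def _gen_urban_gradient(spec, rng_layout, rng_blocks, rng_phys):
    ext = spec.extent_km * 1000.0
    n = spec.n_blocks
    n_cores = 3
    # one dominant metropolitan core plus secondary towns
    core_xy = np.vstack([
        [ext / 2, ext / 2],
        rng_layout.uniform(0.2 * ext, 0.8 * ext, size=(n_cores - 1, 2)),
    ])
    core_w = np.array([0.6] + [0.4 / (n_cores - 1)] * (n_cores - 1))

    n_urban = int(round(spec.urban_fraction * n))
    assign = rng_blocks.choice(n_cores, size=n_urban, p=core_w)
    urban_xy = core_xy[assign] + rng_blocks.normal(0, 3000.0, size=(n_urban, 2))
    rural_xy = rng_blocks.uniform(0.03 * ext, 0.97 * ext, size=(n - n_urban, 2))
    xy = np.clip(np.vstack([urban_xy, rural_xy]), 0.0, ext)

    pops = np.empty(n)
    areas = np.empty(n)
    pops[:n_urban] = rng_blocks.lognormal(mean=5.5, sigma=0.9, size=n_urban)
    areas[:n_urban] = rng_blocks.uniform(0.2, 1.0, size=n_urban)
    pops[n_urban:] = rng_blocks.lognormal(mean=3.2, sigma=1.0, size=n - n_urban)
    areas[n_urban:] = rng_blocks.uniform(2.0, 8.0, size=n - n_urban)
    # a sliver of very-low-density blocks to exercise the eligibility filter
    n_sparse = max(1, (n - n_urban) // 20)
    sparse_idx = n - np.arange(1, n_sparse + 1)
    pops[sparse_idx] = rng_blocks.uniform(0.0, 1.0, size=n_sparse)
    areas[sparse_idx] = rng_blocks.uniform(8.0, 25.0, size=n_sparse)
    blocks = _make_blocks(rng_blocks, xy, pops, areas)

    # physicians concentrate where the people are
    n_phys = spec.n_physician_locations
    assign_p = rng_phys.choice(n_cores, size=n_phys, p=core_w)
    pxy = np.clip(
        core_xy[assign_p] + rng_phys.normal(0, 1500.0, size=(n_phys, 2)),
        0.0, ext,
    )
    supplies = _supplies(rng_phys, n_phys)
    physicians = [
        PhysicianLocation(id=f"P{i:03d}", x=float(x), y=float(y),
                          supply=int(s))
        for i, ((x, y), s) in enumerate(zip(pxy, supplies))
    ]
    roads = _build_area_roads(spec, ext, rng_layout)
    return blocks, physicians, roads


def _gen_corridor(spec, rng_layout, rng_blocks, rng_phys):
    ext = spec.extent_km * 1000.0
    mid = ext / 2
    n = spec.n_blocks
    n_towns = 5
    town_x = np.linspace(0.1 * ext, 0.9 * ext, n_towns)

    n_town_blocks = int(round(spec.urban_fraction * n))
    assign = rng_blocks.integers(0, n_towns, size=n_town_blocks)
    tb_xy = np.column_stack([
        town_x[assign] + rng_blocks.normal(0, 2000.0, size=n_town_blocks),
        mid + rng_blocks.normal(0, 1200.0, size=n_town_blocks),
    ])
    rb_xy = np.column_stack([
        rng_blocks.uniform(0.02 * ext, 0.98 * ext, size=n - n_town_blocks),
        mid + rng_blocks.normal(0, 1500.0, size=n - n_town_blocks),
    ])
    xy = np.clip(np.vstack([tb_xy, rb_xy]), 0.0, ext)
    pops = np.concatenate([
        rng_blocks.lognormal(5.0, 0.9, size=n_town_blocks),
        rng_blocks.lognormal(3.0, 1.0, size=n - n_town_blocks),
    ])
    areas = np.concatenate([
        rng_blocks.uniform(0.3, 1.5, size=n_town_blocks),
        rng_blocks.uniform(1.0, 5.0, size=n - n_town_blocks),
    ])
    blocks = _make_blocks(rng_blocks, xy, pops, areas)

    # physicians only in a subset of towns (western towns here): the far
    # end of the corridor may fall beyond the travel-time cutoff
    n_phys = spec.n_physician_locations
    phys_towns = rng_phys.choice(max(2, n_towns - 2), size=n_phys)
    pxy = np.column_stack([
        town_x[phys_towns] + rng_phys.normal(0, 800.0, size=n_phys),
        np.full(n_phys, mid) + rng_phys.normal(0, 400.0, size=n_phys),
    ])
    supplies = _supplies(rng_phys, n_phys)
    physicians = [
        PhysicianLocation(id=f"P{i:03d}", x=float(x), y=float(y),
                          supply=int(s))
        for i, ((x, y), s) in enumerate(zip(pxy, supplies))
    ]
    roads = _spine_roads(ext, mid, spec.speed_profile, town_x)
    return blocks, physicians, roads


def _gen_binary_remote(spec, rng_layout, rng_blocks, rng_phys):
    """Isolated settlement hubs; optionally some linked to physician hubs.

    Hubs carry a local road mini-grid small enough that any within-hub
    trip stays under the flat-impedance radius; ``disconnect_fraction``
    of the non-physician hubs get no link road, so their residents have
    no road path to any physician.
    """
    ext = spec.extent_km * 1000.0
    n = spec.n_blocks
    n_hubs = min(10, max(3, n // 12))
    # rejection-sample hub centers with a minimum separation, relaxing the
    # separation if the draw gets unlucky so generation always terminates
    centers: list[tuple[float, float]] = []
    sep2 = (0.18 * ext) ** 2
    attempts = 0
    while len(centers) < n_hubs:
        cand = rng_layout.uniform(0.08 * ext, 0.92 * ext, size=2)
        attempts += 1
        if attempts > 2000:
            sep2 *= 0.64
            attempts = 0
        if all((cand[0] - x) ** 2 + (cand[1] - y) ** 2 > sep2
               for x, y in centers):
            centers.append((float(cand[0]), float(cand[1])))
    centers_arr = np.asarray(centers)

    n_phys_hubs = max(1, min(2, n_hubs - 1))
    hub_w = rng_layout.dirichlet(np.full(n_hubs, 2.0))
    # physician hubs get the largest populations, like real territorial hubs
    order = np.argsort(-hub_w)
    phys_hubs = [int(order[i]) for i in range(n_phys_hubs)]

    assign = rng_blocks.choice(n_hubs, size=n, p=hub_w)
    offsets = np.clip(rng_blocks.normal(0, 1000.0, size=(n, 2)),
                      -2400.0, 2400.0)
    xy = centers_arr[assign] + offsets
    pops = rng_blocks.lognormal(4.5, 0.8, size=n)
    areas = rng_blocks.uniform(0.3, 2.0, size=n)
    blocks = _make_blocks(rng_blocks, xy, pops, areas)

    n_phys = spec.n_physician_locations
    assign_p = np.array([phys_hubs[i % n_phys_hubs] for i in range(n_phys)])
    pxy = centers_arr[assign_p] + rng_phys.normal(0, 400.0, size=(n_phys, 2))
    supplies = _supplies(rng_phys, n_phys)
    physicians = [
        PhysicianLocation(id=f"P{i:03d}", x=float(x), y=float(y),
                          supply=int(s))
        for i, ((x, y), s) in enumerate(zip(pxy, supplies))
    ]

    speed_local = spec.speed_profile["local"]
    roads: list[RoadSegment] = []
    for h, (cx, cy) in enumerate(centers):
        roads.extend(_hub_grid(cx, cy, 2000.0, 2000.0, speed_local, f"hub{h}-"))
    # link a share of the non-physician hubs to their nearest physician hub
    others = [h for h in range(n_hubs) if h not in phys_hubs]
    n_link = int(round((1.0 - spec.disconnect_fraction) * len(others)))
    linked = list(rng_layout.permutation(others)[:n_link])
    for h in linked:
        cx, cy = centers[h]
        tx, ty = min(
            (centers[p] for p in phys_hubs),
            key=lambda c: (c[0] - cx) ** 2 + (c[1] - cy) ** 2,
        )
        roads.append(RoadSegment.with_default_length(
            id=f"link{h}", polyline=[(cx, cy), (tx, ty)],
            speed_kmh=spec.speed_profile["arterial"],
        ))
    return blocks, physicians, roads


# ---------------------------------------------------------------------------
# presets

def scenario_presets() -> dict[str, ScenarioSpec]:
    """Named scenarios, each designed for a documented qualitative regime.

    - ``gradient_metropolis``: one metropolitan core plus secondary towns
      on a full road grid — access falls smoothly with travel time, so
      most of the five mapping classes are occupied.
    - ``binary_archipelago``: road-isolated settlement hubs, physicians in
      the two largest — every resident is either inside a physician hub
      (under the 10-minute flat-impedance radius) or entirely without
      road access; no intermediate class exists.
    - ``corridor_province``: population strung along one spine road with
      physicians in the western towns — a travel-time gradient along the
      corridor, with the far end at risk of falling past the cutoff.
    - ``uniform_small``: a small, fully connected province — everyone is
      within the cutoff of some physician, so no block has no_access.
    """
    return {
        "gradient_metropolis": ScenarioSpec(
            seed=0, extent_km=120.0, n_blocks=260, n_physician_locations=12,
            pattern="urban_gradient", urban_fraction=0.65, road_style="grid",
        ),
        "binary_archipelago": ScenarioSpec(
            seed=0, extent_km=300.0, n_blocks=120, n_physician_locations=3,
            pattern="binary_remote", urban_fraction=1.0, road_style="grid",
            disconnect_fraction=1.0,
        ),
        "corridor_province": ScenarioSpec(
            seed=0, extent_km=220.0, n_blocks=180, n_physician_locations=8,
            pattern="corridor", urban_fraction=0.7, road_style="sparse_spine",
        ),
        "uniform_small": ScenarioSpec(
            seed=0, extent_km=30.0, n_blocks=80, n_physician_locations=6,
            pattern="uniform", urban_fraction=0.0, road_style="grid",
        ),
    }


# ---------------------------------------------------------------------------
# flat config round-trip

def spec_to_config(spec: ScenarioSpec) -> str:
    """Serialize a spec as flat ``key = value`` lines."""
    lines = []
    for key in ("seed", "extent_km", "n_blocks", "n_physician_locations",
                "pattern", "urban_fraction", "road_style",
                "disconnect_fraction"):
        lines.append(f"{key} = {getattr(spec, key)}")
    profile = ",".join(f"{k}:{v}" for k, v in sorted(spec.speed_profile.items()))
    lines.append(f"speed_profile = {profile}")
    return "\n".join(lines) + "\n"


def spec_from_config(text: str) -> ScenarioSpec:
    """Parse the flat ``key = value`` form back into a spec."""
    raw: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        raw[key.strip()] = value.strip()
    profile = {
        k: float(v)
        for k, v in (item.split(":") for item in raw["speed_profile"].split(","))
    }
    return ScenarioSpec(
        seed=int(raw["seed"]),
        extent_km=float(raw["extent_km"]),
        n_blocks=int(raw["n_blocks"]),
        n_physician_locations=int(raw["n_physician_locations"]),
        pattern=raw["pattern"],
        urban_fraction=float(raw["urban_fraction"]),
        road_style=raw["road_style"],
        speed_profile=profile,
        disconnect_fraction=float(raw["disconnect_fraction"]),
    )
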