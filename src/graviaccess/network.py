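"""Road-network travel times.

Builds a directed graph from road segments (edge weights in minutes),
snaps off-network points to their nearest graph node, applies the origin
and destination eligibility rules, and computes the cutoff-bounded
Origin-Destination Cost Matrix (ODCM) of block-to-physician travel times.

Eligibility rules
-----------------
A dissemination block is used as an origin only if its population density
strictly exceeds 1 person per 5 km² (0.2 persons/km²) *and* its centroid
lies within 2500 m of a road.  A physician location is a destination only
if it lies within 2500 m of a road.  Blocks failing either test receive no
score; the specific reason (density first, then distance) is recorded so
map output can distinguish low-density blocks from road-remote ones.

Snapping is to graph nodes (segment endpoints and interior vertices), and
the off-road leg from a point to its snap node costs zero minutes: the
road-proximity rule defines an eligibility radius, not a priced access
leg.  That choice is recorded in the matrix metadata so it can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .region import Region, RoadSegment

__all__ = [
    "TravelGraph",
    "TravelTimeMatrix",
    "EligibilityReport",
    "build_graph",
    "snap",
    "classify_eligibility",
    "compute_odcm",
    "DENSITY_THRESHOLD_PER_KM2",
    "SNAP_MAX_M",
    "CUTOFF_MIN",
]

#: Density filter: strictly more than 1 person per 5 km².
DENSITY_THRESHOLD_PER_KM2 = 1.0 / 5.0
#: Maximum centroid-to-road distance for eligibility (inclusive), meters.
SNAP_MAX_M = 2500.0
#: Maximum travel time paired in the ODCM (inclusive), minutes.
CUTOFF_MIN = 120.0

#: Coordinates are quantized to this grid (meters) when de-duplicating
#: shared segment endpoints into single graph nodes.
SNAP_NODE_TOLERANCE_M = 1e-3

NodeId = tuple[float, float]


def _quantize(x: float, y: float) -> NodeId:
    q = SNAP_NODE_TOLERANCE_M
    return (round(x / q) * q, round(y / q) * q)


@dataclass
class TravelGraph:
    """Directed road graph with traversal minutes as edge weights.

    Node ids are quantized ``(x, y)`` coordinate tuples, so two segments
    meeting at the same endpoint share one node and lexicographic
    comparison of node ids is well defined (used as the snapping
    tie-break).
    """

    graph: nx.DiGraph
    _kdtree: cKDTree | None = field(default=None, repr=False)
    _node_order: list[NodeId] = field(default_factory=list, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[NodeId]:
        return list(self.graph.nodes)

    def _ensure_index(self) -> None:
        if self._kdtree is None and self.graph.number_of_nodes() > 0:
            # sorted order makes tie-breaking by node id a pure argmin
            self._node_order = sorted(self.graph.nodes)
            self._kdtree = cKDTree(np.asarray(self._node_order, dtype=float))

    def nearest_node(self, x: float, y: float) -> tuple[NodeId, float] | None:
        """Nearest node and its Euclidean distance; None on an empty graph.

        Equidistant candidates resolve to the lexicographically smallest
        node id.
        """
        if self.graph.number_of_nodes() == 0:
            return None
        self._ensure_index()
        assert self._kdtree is not None
        dist, idx = self._kdtree.query((x, y))
        # collect every node at the minimal distance (ties within 1e-9 m)
        tied = self._kdtree.query_ball_point((x, y), float(dist) + 1e-9)
        best = min(self._node_order[i] for i in tied)
        return best, float(dist)


def build_graph(roads: Iterable[RoadSegment]) -> TravelGraph:
    """Build the directed travel-time graph from validated road segments.

    Every polyline vertex becomes a node; consecutive vertices are joined
    by arcs whose weight is the segment's traversal time apportioned by
    Euclidean sub-length (so a stated ``length_m`` longer than the chord —
    road curvature — inflates all sub-edges proportionally).  Two-way
    segments yield opposing arc pairs; ``forward``/``reverse`` yield one
    arc per vertex pair in (or against) polyline order.
    """
    g = nx.DiGraph()
    for seg in roads:
        pts = np.asarray(seg.polyline, dtype=float)
        sub = np.hypot(*np.diff(pts, axis=0).T)
        total = float(sub.sum())
        if total <= 0:
            # degenerate zero-extent polyline: register the node, no arcs
            g.add_node(_quantize(*pts[0]))
            continue
        minutes = seg.travel_minutes * sub / total
        nodes = [_quantize(x, y) for x, y in pts]
        for a, b, w in zip(nodes[:-1], nodes[1:], minutes):
            if a == b:
                continue
            w = float(w)
            if seg.direction in ("both", "forward"):
                _add_min_edge(g, a, b, w)
            if seg.direction in ("both", "reverse"):
                _add_min_edge(g, b, a, w)
    return TravelGraph(graph=g)


def _add_min_edge(g: nx.DiGraph, a: NodeId, b: NodeId, w: float) -> None:
    # parallel roads between the same nodes: keep the fastest
    if g.has_edge(a, b):
        if w < g[a][b]["minutes"]:
            g[a][b]["minutes"] = w
    else:
        g.add_edge(a, b, minutes=w)


def snap(
    point: tuple[float, float],
    graph: TravelGraph,
    max_dist_m: float = SNAP_MAX_M,
) -> NodeId | None:
    """Snap a point to its nearest graph node within ``max_dist_m`` (inclusive).

    Returns None when the graph is empty or every node is farther away.
    """
    hit = graph.nearest_node(point[0], point[1])
    if hit is None:
        return None
    node, dist = hit
    return node if dist <= max_dist_m else None


@dataclass
class EligibilityReport:
    """Per-entity origin/destination eligibility with exclusion reasons."""

    block_status: dict[str, str]       # origin | excluded_density | excluded_far_from_road
    physician_status: dict[str, str]   # destination | excluded_far_from_road
    block_snap: dict[str, NodeId]      # snap node for every eligible origin
    physician_snap: dict[str, NodeId]  # snap node for every destination
    snap_max_m: float = SNAP_MAX_M
    density_threshold_per_km2: float = DENSITY_THRESHOLD_PER_KM2

    def origin_ids(self) -> list[str]:
        return [b for b, s in self.block_status.items() if s == "origin"]

    def destination_ids(self) -> list[str]:
        return [p for p, s in self.physician_status.items() if s == "destination"]


def classify_eligibility(
    region: Region,
    graph: TravelGraph,
    snap_max_m: float = SNAP_MAX_M,
    density_threshold_per_km2: float = DENSITY_THRESHOLD_PER_KM2,
) -> EligibilityReport:
    """Apply the origin/destination eligibility rules to a region.

    Density is tested first (strictly greater than the threshold), then
    road proximity, so a sparse *and* remote block reports
    ``excluded_density``.
    """
    block_status: dict[str, str] = {}
    block_snap: dict[str, NodeId] = {}
    for b in region.blocks:
        if not (b.density_per_km2 > density_threshold_per_km2):
            block_status[b.id] = "excluded_density"
            continue
        node = snap((b.x, b.y), graph, snap_max_m)
        if node is None:
            block_status[b.id] = "excluded_far_from_road"
        else:
            block_status[b.id] = "origin"
            block_snap[b.id] = node

    physician_status: dict[str, str] = {}
    physician_snap: dict[str, NodeId] = {}
    for p in region.physicians:
        node = snap((p.x, p.y), graph, snap_max_m)
        if node is None:
            physician_status[p.id] = "excluded_far_from_road"
        else:
            physician_status[p.id] = "destination"
            physician_snap[p.id] = node

    return EligibilityReport(
        block_status=block_status,
        physician_status=physician_status,
        block_snap=block_snap,
        physician_snap=physician_snap,
        snap_max_m=snap_max_m,
        density_threshold_per_km2=density_threshold_per_km2,
    )


@dataclass
class TravelTimeMatrix:
    """Sparse ODCM: (block_id, physician_id) -> shortest-path minutes.

    Only pairs within ``cutoff_min`` are stored; an absent pair means the
    physician is not accessible from that block.  ``metadata`` records the
    modelling decisions in force (zero-cost snap leg, thresholds) so
    downstream output can carry them.
    """

    entries: dict[tuple[str, str], float]
    cutoff_min: float = CUTOFF_MIN
    metadata: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (b, p), t in self.entries.items():
            if not (0.0 <= t <= self.cutoff_min):
                raise ValueError(
                    f"ODCM entry ({b!r}, {p!r}) = {t} min outside "
                    f"[0, {self.cutoff_min}]"
                )

    def minutes(self, block_id: str, physician_id: str) -> float | None:
        return self.entries.get((block_id, physician_id))

    def pairs_for_block(self, block_id: str) -> dict[str, float]:
        return {p: t for (b, p), t in self.entries.items() if b == block_id}

    def block_ids(self) -> set[str]:
        return {b for b, _ in self.entries}

    def physician_ids(self) -> set[str]:
        return {p for _, p in self.entries}


def compute_odcm(
    region: Region,
    graph: TravelGraph,
    report: EligibilityReport,
    cutoff_min: float = CUTOFF_MIN,
    origin_ids: Sequence[str] | None = None,
) -> TravelTimeMatrix:
    """Shortest-path travel minutes for every origin-destination pair within cutoff.

    Runs one Dijkstra per distinct origin snap node (origins sharing a
    node share the search).  A block and physician snapping to the same
    node are zero minutes apart.  Unreachable or beyond-cutoff pairs are
    simply absent.

    ``origin_ids`` optionally widens (or narrows) the origin set to any
    blocks with a known snap node — used when demand should count blocks
    that the density filter removed from scoring.
    """
    if origin_ids is None:
        origin_ids = report.origin_ids()
    else:
        origin_ids = list(origin_ids)
        missing = [b for b in origin_ids if b not in report.block_snap]
        if missing:
            raise ValueError(
                f"origin ids without a snap node (not road-reachable): {missing}"
            )

    dest_nodes: dict[NodeId, list[str]] = {}
    for pid in report.destination_ids():
        dest_nodes.setdefault(report.physician_snap[pid], []).append(pid)

    origin_nodes: dict[NodeId, list[str]] = {}
    for bid in origin_ids:
        origin_nodes.setdefault(report.block_snap[bid], []).append(bid)

    entries: dict[tuple[str, str], float] = {}
    for node, bids in origin_nodes.items():
        lengths = nx.single_source_dijkstra_path_length(
            graph.graph, node, cutoff=cutoff_min, weight="minutes"
        )
        for dnode, pids in dest_nodes.items():
            t = 0.0 if dnode == node else lengths.get(dnode)
            if t is None or t > cutoff_min:
                continue
            for bid in bids:
                for pid in pids:
                    entries[(bid, pid)] = t

    return TravelTimeMatrix(
        entries=entries,
        cutoff_min=cutoff_min,
        metadata={
            "cutoff_min": cutoff_min,
            "snap_max_m": report.snap_max_m,
            "density_threshold_per_km2": report.density_threshold_per_km2,
            "snap_leg_cost_min": 0.0,
            "snap_target": "graph nodes (segment endpoints and vertices)",
        },
    )
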