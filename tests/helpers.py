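"""Independent oracles and random-instance builders for the test suite.

Everything here deliberately avoids the library's own graph, gravity and
classification code paths: shortest paths by min-plus matrix relaxation,
gravity sums by naive double loops, Jenks by exhaustive enumeration of
contiguous partitions.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from graviaccess import (
    DisseminationBlock,
    PhysicianLocation,
    Region,
    RoadSegment,
)

# ---------------------------------------------------------------------------
# random road-network instances with entities sitting exactly on nodes


def random_node_region(
    rng: np.random.Generator,
    n_nodes: int,
    edge_prob: float = 0.3,
    both_prob: float = 0.6,
) -> tuple[Region, list[tuple[float, float]]]:
    """Random directed road network with a block and physician at every node.

    Node coordinates are spread hundreds of meters apart so endpoint
    quantization never merges distinct nodes.  Returns the region and the
    node coordinate list (block ``b{i}`` and physician ``p{i}`` sit on
    node ``i``).
    """
    # distinct cells of a 6 km lattice: nodes are >= 6 km apart, so an
    # entity on a node never snaps (2.5 km radius) to any other node
    cells = rng.choice(25, size=n_nodes, replace=False)
    pts = [(float(c % 5) * 6000.0, float(c // 5) * 6000.0) for c in cells]
    roads = []
    rid = 0
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() > edge_prob:
                continue
            direction = "both" if rng.random() < both_prob else (
                "forward" if rng.random() < 0.5 else "reverse"
            )
            speed = float(rng.choice([30.0, 50.0, 80.0]))
            roads.append(RoadSegment.with_default_length(
                id=f"r{rid}", polyline=[pts[i], pts[j]],
                speed_kmh=speed, direction=direction,
            ))
            rid += 1
    blocks = [
        DisseminationBlock(id=f"b{i}", x=x, y=y, population=10.0, area_km2=1.0)
        for i, (x, y) in enumerate(pts)
    ]
    physicians = [
        PhysicianLocation(id=f"p{i}", x=x, y=y, supply=1)
        for i, (x, y) in enumerate(pts)
    ]
    return Region(blocks=blocks, physicians=physicians, roads=roads), pts


def minplus_shortest_paths(
    region: Region, pts: list[tuple[float, float]]
) -> np.ndarray:
    """All-pairs shortest travel minutes by min-plus matrix relaxation.

    Edge weights are derived straight from the segment attributes
    (Euclidean length / speed), independently of the library's graph
    builder.
    """
    n = len(pts)
    idx = {p: i for i, p in enumerate(pts)}
    w = np.full((n, n), math.inf)
    np.fill_diagonal(w, 0.0)
    for seg in region.roads:
        a, b = seg.polyline[0], seg.polyline[-1]
        i, j = idx[a], idx[b]
        minutes = (
            math.dist(a, b) / 1000.0
        ) / seg.speed_kmh * 60.0
        if seg.direction in ("both", "forward"):
            w[i, j] = min(w[i, j], minutes)
        if seg.direction in ("both", "reverse"):
            w[j, i] = min(w[j, i], minutes)
    dist = w.copy()
    for _ in range(n):
        # relax: dist[i,j] = min_k dist[i,k] + w[k,j]
        dist = np.minimum(dist, np.min(dist[:, :, None] + w[None, :, :], axis=1))
    return dist


# ---------------------------------------------------------------------------
# naive gravity oracle


def naive_gravity(
    times: dict[tuple[str, str], float],
    populations: dict[str, float],
    supplies: dict[str, int],
) -> tuple[dict[str, float], dict[str, float]]:
    """Demand and access by explicit double loops over the pair table."""

    def f(t: float) -> float:
        if t <= 10.0:
            return 1.0
        if t <= 120.0:
            return t / 10.0
        return math.inf

    demand = {p: 0.0 for p in supplies}
    for (b, p), t in times.items():
        demand[p] += populations[b] / f(t)
    access = {b: 0.0 for b in populations}
    for (b, p), t in times.items():
        access[b] += supplies[p] / (demand[p] * f(t))
    return demand, access


# ---------------------------------------------------------------------------
# exhaustive Jenks oracle


def enumerate_jenks(values: list[float], k: int) -> tuple[float, list[list[float]]]:
    """Minimum within-class SSE over all contiguous k-partitions (exhaustive)."""
    vals = sorted(values)
    n = len(vals)

    def sse(chunk: list[float]) -> float:
        m = sum(chunk) / len(chunk)
        return sum((v - m) ** 2 for v in chunk)

    best = math.inf
    best_parts: list[list[float]] = []
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        parts = [vals[a:b] for a, b in zip(bounds, bounds[1:])]
        cost = sum(sse(p) for p in parts)
        if cost < best - 1e-12:
            best = cost
            best_parts = parts
    return best, best_parts


def within_class_sse(values: list[float], breaks: list[float]) -> float:
    """SSE of the partition induced by inclusive upper-bound breaks."""
    classes: dict[int, list[float]] = {}
    for v in values:
        c = sum(v > b for b in breaks)
        classes.setdefault(c, []).append(v)
    total = 0.0
    for chunk in classes.values():
        m = sum(chunk) / len(chunk)
        total += sum((v - m) ** 2 for v in chunk)
    return total
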