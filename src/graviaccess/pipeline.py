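"""End-to-end scoring: region in, classified access surface out.

Chains the stages in their required order — travel graph, eligibility,
ODCM, demand, access, classification, population summary — with one
consistent set of thresholds, and exposes the one genuinely open
modelling switch: whether blocks removed from scoring by the density
filter still contribute their population to physician demand
(``demand_includes_filtered``).  The default keeps one origin set for
both the demand and the access equation, which is what makes the supply
conservation identity hold when nothing is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import AccessSummary, ClassifiedSurface, classify, summarize
from .gravity import AccessSurface, DemandTable, compute_access, compute_demand
from .network import (
    CUTOFF_MIN,
    DENSITY_THRESHOLD_PER_KM2,
    SNAP_MAX_M,
    EligibilityReport,
    TravelGraph,
    TravelTimeMatrix,
    build_graph,
    classify_eligibility,
    compute_odcm,
    snap,
)
from .region import Region

__all__ = ["PipelineResult", "score_region"]


@dataclass
class PipelineResult:
    """Everything one scoring run produced, stage by stage."""

    graph: TravelGraph
    report: EligibilityReport
    odcm: TravelTimeMatrix
    demand: DemandTable
    surface: AccessSurface
    classified: ClassifiedSurface
    summary: AccessSummary


def score_region(
    region: Region,
    cutoff_min: float = CUTOFF_MIN,
    snap_max_m: float = SNAP_MAX_M,
    density_threshold_per_km2: float = DENSITY_THRESHOLD_PER_KM2,
    k: int = 5,
    demand_includes_filtered: bool = False,
) -> PipelineResult:
    """Run the full access-scoring pipeline on a region.

    Parameters
    ----------
    cutoff_min : float
        Maximum one-way road travel time paired in the ODCM (minutes).
    snap_max_m : float
        Maximum centroid-to-road distance for eligibility (meters).
    density_threshold_per_km2 : float
        Strict lower bound on population density for origin blocks.
    k : int
        Number of Jenks mapping classes.
    demand_includes_filtered : bool
        If True, blocks excluded from scoring by the density filter (but
        still within ``snap_max_m`` of a road) contribute their
        population to physician demand.  Default False: demand and
        access use one origin set, drawn from the same matrix.
    """
    graph = build_graph(region.roads)
    report = classify_eligibility(
        region, graph, snap_max_m=snap_max_m,
        density_threshold_per_km2=density_threshold_per_km2,
    )
    odcm = compute_odcm(region, graph, report, cutoff_min=cutoff_min)

    if demand_includes_filtered:
        # widen the demand-side origin set to density-filtered blocks that
        # are still road-reachable; their scores remain undefined
        extra = []
        for b in region.blocks:
            if report.block_status[b.id] == "excluded_density":
                node = snap((b.x, b.y), graph, snap_max_m)
                if node is not None:
                    report.block_snap[b.id] = node
                    extra.append(b.id)
        demand_odcm = compute_odcm(
            region, graph, report, cutoff_min=cutoff_min,
            origin_ids=report.origin_ids() + extra,
        )
    else:
        demand_odcm = odcm

    demand = compute_demand(
        demand_odcm, region.blocks,
        physician_ids=[p.id for p in region.physicians],
    )
    surface = compute_access(odcm, region.physicians, demand, report)
    surface.metadata["demand_includes_filtered"] = demand_includes_filtered
    classified = classify(surface, k=k)
    summary = summarize(region, classified)
    return PipelineResult(
        graph=graph, report=report, odcm=odcm, demand=demand,
        surface=surface, classified=classified, summary=summary,
    )
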