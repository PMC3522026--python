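"""The gravity model core: travel impedance, physician demand, block access.

The access score of dissemination block *i* is

    A_i = sum_j S_j / (D_j * f(t_ij))

where S_j is the physician count at location *j*, t_ij the road travel
time from block *i* to location *j*, and D_j the impedance-weighted
population competing for location *j*:

    D_j = sum_k P_k / f(t_kj)

Both sums run over the pairs of one Origin-Destination Cost Matrix, so the
same origin set and travel-time cutoff apply to demand and to access.  The
impedance f is piecewise linear: no penalty inside 10 minutes, t/10 up to
the 120-minute cutoff, and infinite beyond it — a pair past the cutoff
contributes exactly zero (1/inf == 0).  A block whose ODCM row is empty
has no accessible physician and scores 0, the floor of the measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .network import EligibilityReport, TravelTimeMatrix
from .region import DisseminationBlock, PhysicianLocation

__all__ = [
    "NO_ACCESS",
    "impedance",
    "DemandTable",
    "AccessSurface",
    "compute_demand",
    "compute_access",
]

#: Sentinel impedance for pairs beyond the travel-time cutoff.  IEEE
#: infinity reproduces the model's "no access" algebra exactly: any
#: population or supply divided by it contributes 0 to a sum.
NO_ACCESS = math.inf

#: Travel time (minutes) below which there is no travel penalty.
FLAT_IMPEDANCE_MIN = 10.0
#: Travel time (minutes) beyond which a pair has no access.
MAX_TRAVEL_MIN = 120.0


def impedance(t_min: float) -> float:
    """Piecewise linear travel-time impedance f(t).

    f(t) = 1        for t <= 10 minutes
    f(t) = t / 10   for 10 < t <= 120 minutes
    f(t) = inf      for t > 120 minutes  (no access: 1/inf = 0)

    Continuous at both branch points: f(10) = 1 and f(120) = 12 from
    either side.  Co-located pairs (t = 0) use the flat branch.

    Raises
    ------
    ValueError
        If ``t_min`` is negative or NaN.
    """
    if not (t_min >= 0):
        raise ValueError(f"travel time must be >= 0 minutes, got {t_min!r}")
    if t_min <= FLAT_IMPEDANCE_MIN:
        return 1.0
    if t_min <= MAX_TRAVEL_MIN:
        return t_min / FLAT_IMPEDANCE_MIN
    return NO_ACCESS


@dataclass
class DemandTable:
    """Impedance-weighted population demand per physician location.

    Demand is measured in population-equivalents; a location no eligible
    block can reach within the cutoff has demand 0.
    """

    demand: dict[str, float]

    def __post_init__(self) -> None:
        for pid, d in self.demand.items():
            if not (d >= 0):
                raise ValueError(f"demand for physician {pid!r} is negative: {d}")

    def __getitem__(self, physician_id: str) -> float:
        return self.demand[physician_id]


@dataclass
class AccessSurface:
    """Per-block access scores with scoring status.

    ``status`` is ``scored`` (eligible origin with at least one accessible
    physician), ``no_access`` (eligible origin, no physician within the
    cutoff; access is exactly 0) or ``excluded`` (failed an eligibility
    filter; no score is defined).  ``metadata`` carries the thresholds and
    modelling decisions in force when the surface was computed.
    """

    scores: dict[str, float]   # block_id -> access; excluded blocks absent
    status: dict[str, str]     # block_id -> scored | no_access | excluded
    metadata: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for bid, s in self.status.items():
            if s == "excluded":
                if bid in self.scores:
                    raise ValueError(f"excluded block {bid!r} carries a score")
            elif s == "no_access":
                if self.scores.get(bid) != 0.0:
                    raise ValueError(f"no_access block {bid!r} must score 0")
            elif s == "scored":
                if not (self.scores.get(bid, -1.0) >= 0):
                    raise ValueError(f"scored block {bid!r} lacks a valid score")
            else:
                raise ValueError(f"block {bid!r}: unknown status {s!r}")

    def block_ids(self) -> list[str]:
        return list(self.status)

    def scored_items(self) -> list[tuple[str, float]]:
        return [(b, self.scores[b]) for b, s in self.status.items() if s == "scored"]


def compute_demand(
    odcm: TravelTimeMatrix,
    blocks: Iterable[DisseminationBlock],
    physician_ids: Iterable[str] = (),
) -> DemandTable:
    """Demand D_j = sum over ODCM pairs (k, j) of P_k / f(t_kj).

    ``physician_ids`` seeds locations that should appear with demand 0
    even if no pair reaches them (so downstream lookups are total).

    Raises
    ------
    ValueError
        If the ODCM references a block id not present in ``blocks``.
    """
    pop = {b.id: b.population for b in blocks}
    missing = sorted(odcm.block_ids() - pop.keys())
    if missing:
        raise ValueError(f"ODCM references unknown block ids: {missing}")

    demand: dict[str, float] = {pid: 0.0 for pid in physician_ids}
    for (bid, pid), t in odcm.entries.items():
        demand[pid] = demand.get(pid, 0.0) + pop[bid] / impedance(t)
    return DemandTable(demand=demand)


def compute_access(
    odcm: TravelTimeMatrix,
    physicians: Iterable[PhysicianLocation],
    demand: DemandTable,
    report: EligibilityReport,
) -> AccessSurface:
    """Access A_i = sum over ODCM pairs (i, j) of S_j / (D_j * f(t_ij)).

    Eligible origin blocks with an empty ODCM row score 0 with status
    ``no_access``; blocks that failed an eligibility filter carry status
    ``excluded`` and no score.  Every physician that appears in the ODCM
    necessarily has positive demand — demand and access draw their pairs
    from the same matrix — which is asserted rather than special-cased.

    Raises
    ------
    ValueError
        If the demand table lacks a physician present in the ODCM.
    """
    supply = {p.id: p.supply for p in physicians}
    missing = sorted(odcm.physician_ids() - demand.demand.keys())
    if missing:
        raise ValueError(f"demand table missing physicians: {missing}")
    missing = sorted(odcm.physician_ids() - supply.keys())
    if missing:
        raise ValueError(f"ODCM references unknown physician ids: {missing}")

    sums: dict[str, float] = {}
    for (bid, pid), t in odcm.entries.items():
        d = demand[pid]
        # every origin passed the density filter, so its population is
        # positive and entered D_j through this same matrix
        assert d > 0, (
            f"physician {pid!r} appears in an ODCM pair but has zero demand"
        )
        sums[bid] = sums.get(bid, 0.0) + supply[pid] / (d * impedance(t))

    scores: dict[str, float] = {}
    status: dict[str, str] = {}
    for bid, st in report.block_status.items():
        if st != "origin":
            status[bid] = "excluded"
            continue
        if bid in sums:
            scores[bid] = sums[bid]
            status[bid] = "scored"
        else:
            scores[bid] = 0.0
            status[bid] = "no_access"

    meta = dict(odcm.metadata)
    meta["impedance"] = (
        "1 for t<=10 min; t/10 for 10<t<=120 min; no access beyond 120 min"
    )
    return AccessSurface(scores=scores, status=status, metadata=meta)
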