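"""Impedance function, demand, and access-score computation."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graviaccess import (
    AccessSurface,
    DisseminationBlock,
    PhysicianLocation,
    TravelTimeMatrix,
    compute_access,
    compute_demand,
    impedance,
)
from graviaccess.network import EligibilityReport

from helpers import naive_gravity


class TestImpedance:
    def test_flat_inside_ten_minutes(self):
        assert impedance(0.0) == 1.0
        assert impedance(5.0) == 1.0
        assert impedance(10.0) == 1.0

    def test_linear_branch_values(self):
        assert impedance(60.0) == pytest.approx(6.0)
        assert impedance(120.0) == pytest.approx(12.0)

    def test_eighty_vs_twenty_minute_ratio_is_four(self):
        assert impedance(80.0) / impedance(20.0) == pytest.approx(4.0)

    def test_beyond_cutoff_contributes_zero(self):
        assert impedance(121.0) == math.inf
        assert 1.0 / impedance(121.0) == 0.0
        assert 100.0 / impedance(500.0) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            impedance(-1.0)
        with pytest.raises(ValueError):
            impedance(float("nan"))

    def test_continuity_at_branch_points(self):
        eps = 1e-9
        assert impedance(10.0 + eps) == pytest.approx(1.0, abs=1e-8)
        assert impedance(120.0 - eps) == pytest.approx(12.0, abs=1e-8)

    @given(st.floats(min_value=0.0, max_value=120.0),
           st.floats(min_value=0.0, max_value=120.0))
    @settings(derandomize=True, max_examples=200)
    def test_monotone_nondecreasing_within_cutoff(self, t1, t2):
        if t1 > t2:
            t1, t2 = t2, t1
        assert impedance(t1) <= impedance(t2)


def _blocks(pops):
    return [
        DisseminationBlock(id=f"b{i}", x=0.0, y=0.0, population=p, area_km2=1.0)
        for i, p in enumerate(pops)
    ]


def _report(block_ids, phys_ids):
    return EligibilityReport(
        block_status={b: "origin" for b in block_ids},
        physician_status={p: "destination" for p in phys_ids},
        block_snap={b: (0.0, 0.0) for b in block_ids},
        physician_snap={p: (0.0, 0.0) for p in phys_ids},
    )


class TestDemand:
    def test_single_block_inside_flat_radius(self):
        odcm = TravelTimeMatrix(entries={("b0", "p"): 5.0})
        demand = compute_demand(odcm, _blocks([100.0]))
        assert demand["p"] == pytest.approx(100.0)

    def test_single_block_at_sixty_minutes(self):
        odcm = TravelTimeMatrix(entries={("b0", "p"): 60.0})
        demand = compute_demand(odcm, _blocks([100.0]))
        assert demand["p"] == pytest.approx(100.0 / 6.0)

    def test_two_block_sum(self):
        odcm = TravelTimeMatrix(entries={("b0", "p"): 5.0, ("b1", "p"): 120.0})
        demand = compute_demand(odcm, _blocks([100.0, 50.0]))
        assert demand["p"] == pytest.approx(100.0 + 50.0 / 12.0)

    def test_unpaired_physician_gets_zero(self):
        odcm = TravelTimeMatrix(entries={})
        demand = compute_demand(odcm, _blocks([100.0]), physician_ids=["p"])
        assert demand["p"] == 0.0

    def test_unknown_block_id_rejected(self):
        odcm = TravelTimeMatrix(entries={("ghost", "p"): 5.0})
        with pytest.raises(ValueError, match="ghost"):
            compute_demand(odcm, _blocks([100.0]))


class TestAccess:
    def test_single_pair_closed_form(self):
        # P=100 at 5 min from S=2: D=100, A = 2/(100*1) = 0.02
        odcm = TravelTimeMatrix(entries={("b0", "p"): 5.0})
        blocks = _blocks([100.0])
        physicians = [PhysicianLocation(id="p", x=0.0, y=0.0, supply=2)]
        demand = compute_demand(odcm, blocks, physician_ids=["p"])
        surface = compute_access(odcm, physicians, demand,
                                 _report(["b0"], ["p"]))
        assert surface.scores["b0"] == pytest.approx(0.02)
        assert surface.status["b0"] == "scored"

    def test_origin_with_no_pairs_is_no_access_zero(self):
        odcm = TravelTimeMatrix(entries={})
        physicians = [PhysicianLocation(id="p", x=0.0, y=0.0, supply=1)]
        demand = compute_demand(odcm, _blocks([100.0]), physician_ids=["p"])
        surface = compute_access(odcm, physicians, demand,
                                 _report(["b0"], ["p"]))
        assert surface.status["b0"] == "no_access"
        assert surface.scores["b0"] == 0.0

    def test_identical_equidistant_blocks_score_identically(self):
        odcm = TravelTimeMatrix(entries={("b0", "p"): 40.0, ("b1", "p"): 40.0})
        blocks = _blocks([70.0, 70.0])
        physicians = [PhysicianLocation(id="p", x=0.0, y=0.0, supply=3)]
        demand = compute_demand(odcm, blocks, physician_ids=["p"])
        surface = compute_access(odcm, physicians, demand,
                                 _report(["b0", "b1"], ["p"]))
        assert surface.scores["b0"] == surface.scores["b1"]

    def test_non_origin_blocks_pass_through_excluded(self):
        odcm = TravelTimeMatrix(entries={})
        report = EligibilityReport(
            block_status={"b0": "excluded_density"},
            physician_status={}, block_snap={}, physician_snap={},
        )
        surface = compute_access(odcm, [], compute_demand(odcm, _blocks([1.0])),
                                 report)
        assert surface.status["b0"] == "excluded"
        assert "b0" not in surface.scores

    def test_missing_demand_entry_rejected(self):
        odcm = TravelTimeMatrix(entries={("b0", "p"): 5.0})
        physicians = [PhysicianLocation(id="p", x=0.0, y=0.0, supply=1)]
        from graviaccess import DemandTable
        with pytest.raises(ValueError, match="p"):
            compute_access(odcm, physicians, DemandTable(demand={}),
                           _report(["b0"], ["p"]))

    def test_surface_invariants_enforced(self):
        with pytest.raises(ValueError):
            AccessSurface(scores={"b": 1.0}, status={"b": "no_access"})
        with pytest.raises(ValueError):
            AccessSurface(scores={"b": 1.0}, status={"b": "excluded"})


def test_matches_naive_double_loop_on_random_instances():
    """Demand and access agree exactly with an explicit-loop oracle."""
    rng = np.random.default_rng(3)
    for _ in range(60):
        nb = int(rng.integers(1, 6))
        np_ = int(rng.integers(1, 4))
        pops = rng.uniform(1.0, 500.0, size=nb)
        supplies = rng.integers(1, 9, size=np_)
        entries = {}
        for i in range(nb):
            for j in range(np_):
                if rng.random() < 0.7:
                    entries[(f"b{i}", f"p{j}")] = float(rng.uniform(0.0, 120.0))
        # oracle only defines demand/access for physicians in some pair
        blocks = _blocks(pops)
        physicians = [
            PhysicianLocation(id=f"p{j}", x=0.0, y=0.0, supply=int(s))
            for j, s in enumerate(supplies)
        ]
        odcm = TravelTimeMatrix(entries=entries)
        demand = compute_demand(odcm, blocks,
                                physician_ids=[p.id for p in physicians])
        report = _report([b.id for b in blocks], [p.id for p in physicians])
        surface = compute_access(odcm, physicians, demand, report)

        exp_demand, exp_access = naive_gravity(
            entries, {b.id: b.population for b in blocks},
            {p.id: int(p.supply) for p in physicians},
        )
        for pid, d in exp_demand.items():
            assert demand[pid] == pytest.approx(d, rel=1e-12, abs=0)
        for bid, a in exp_access.items():
            assert surface.scores[bid] == pytest.approx(a, rel=1e-12, abs=0)
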