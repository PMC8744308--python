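"""2SFCA funded access, nearest-site times, walkshed counts — checked
against a brute-force transcription of the two formulas and the standard
dollar-conservation identity."""

from __future__ import annotations

import math

import numpy as np
import pytest

import fundshed as fs
from fundshed.errors import InvalidInputError
from fundshed.travel import TravelTimeMatrix

from oracles import two_sfca_bruteforce


class TestSupplyRatio:
    def test_direct_substitution(self):
        m = TravelTimeMatrix(["b1"], ["s1"], [[10.0]])
        (r,) = fs.supply_ratio({"s1": 100.0}, m, {"b1": 50}, 30.0)
        assert r.ratio == 2.0 and r.reachable_population == 50

    def test_zero_demand_flagged(self):
        m = TravelTimeMatrix(["b1"], ["s1"], [[45.0]])
        (r,) = fs.supply_ratio({"s1": 100.0}, m, {"b1": 50}, 30.0)
        assert r.ratio == 0.0 and r.zero_demand

    def test_worked_instance_ratios(self, worked_instance):
        matrix, pops, supply = worked_instance
        ratios = {r.site_id: r.ratio
                  for r in fs.supply_ratio(supply, matrix, pops, 30.0)}
        assert ratios == {"s1": pytest.approx(4.0), "s2": pytest.approx(1.2)}

    def test_negative_population_rejected(self):
        m = TravelTimeMatrix(["b1"], ["s1"], [[10.0]])
        with pytest.raises(InvalidInputError):
            fs.supply_ratio({"s1": 1.0}, m, {"b1": -5}, 30.0)

    def test_unknown_site_rejected(self):
        m = TravelTimeMatrix(["b1"], ["s1"], [[10.0]])
        with pytest.raises(InvalidInputError):
            fs.supply_ratio({"sX": 1.0}, m, {"b1": 5}, 30.0)


class TestAccess2sfca:
    def test_worked_instance_access(self, worked_instance):
        matrix, pops, supply = worked_instance
        ratios = fs.supply_ratio(supply, matrix, pops, 30.0)
        access = {b.block_id: b.a_2sfca
                  for b in fs.access_2sfca(ratios, matrix, 30.0)}
        assert access == {"b1": pytest.approx(4.0),
                          "b2": pytest.approx(5.2),
                          "b3": pytest.approx(1.2)}

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            nb, ns = rng.integers(2, 12), rng.integers(1, 8)
            t = rng.uniform(0, 60, size=(nb, ns))
            t[rng.random(size=t.shape) < 0.1] = math.inf
            supply = rng.uniform(0, 500, size=ns)
            demand = rng.integers(0, 100, size=nb)
            m = TravelTimeMatrix([f"b{i}" for i in range(nb)],
                                 [f"s{j}" for j in range(ns)], t)
            ratios = fs.supply_ratio(
                {f"s{j}": float(supply[j]) for j in range(ns)},
                m, {f"b{i}": int(demand[i]) for i in range(nb)}, 30.0)
            access = fs.access_2sfca(ratios, m, 30.0)
            R_exp, A_exp = two_sfca_bruteforce(t.tolist(), supply.tolist(),
                                               demand.tolist(), 30.0)
            got_R = {r.site_id: r.ratio for r in ratios}
            for j in range(ns):
                assert got_R[f"s{j}"] == pytest.approx(R_exp[j], rel=1e-12)
            got_A = {b.block_id: b.a_2sfca for b in access}
            for i in range(nb):
                assert got_A[f"b{i}"] == pytest.approx(A_exp[i], rel=1e-12)

    def test_block_reaching_nothing_gets_zero(self):
        m = TravelTimeMatrix(["b1"], ["s1"], [[math.inf]])
        ratios = fs.supply_ratio({"s1": 100.0}, m, {"b1": 10}, 30.0)
        (b,) = fs.access_2sfca(ratios, m, 30.0)
        assert b.a_2sfca == 0.0 and b.n_within == 0
        assert b.nearest_minutes is None

    def test_foreign_ratio_provenance_rejected(self):
        m = TravelTimeMatrix(["b1"], ["s1"], [[5.0]])
        bad = [fs.SupplyRatio("sX", 1.0, 10)]
        with pytest.raises(InvalidInputError):
            fs.access_2sfca(bad, m, 30.0)

    def test_zero_supply_sites_change_nothing(self):
        rng = np.random.default_rng(8)
        t = rng.uniform(0, 50, size=(6, 4))
        m = TravelTimeMatrix([f"b{i}" for i in range(6)],
                             [f"s{j}" for j in range(4)], t)
        pops = {f"b{i}": 10 * (i + 1) for i in range(6)}
        base_supply = {"s0": 100.0, "s1": 200.0}
        with_zero = dict(base_supply, s2=0.0, s3=0.0)
        a1 = fs.access_2sfca(fs.supply_ratio(base_supply, m, pops, 30.0), m, 30.0)
        a2 = fs.access_2sfca(fs.supply_ratio(with_zero, m, pops, 30.0), m, 30.0)
        assert [b.a_2sfca for b in a1] == pytest.approx(
            [b.a_2sfca for b in a2], rel=1e-12)


class TestNearestAndCounts:
    def test_row_minimum(self):
        m = TravelTimeMatrix(["b1"], ["s1", "s2", "s3"], [[12.0, 45.0, 7.0]])
        assert fs.time_to_nearest(m) == {"b1": 7.0}

    def test_colocated_site_is_zero(self):
        m = TravelTimeMatrix(["b1"], ["s1"], [[0.0]])
        assert fs.time_to_nearest(m) == {"b1": 0.0}

    def test_nothing_reachable_is_flagged(self):
        m = TravelTimeMatrix(["b1"], ["s1"], [[math.inf]])
        assert fs.time_to_nearest(m) == {"b1": None}

    def test_count_strict_at_threshold(self):
        m = TravelTimeMatrix(["b1"], ["s1", "s2", "s3"], [[10.0, 29.9, 30.0]])
        assert fs.count_within(m, 30.0) == {"b1": 2}

    def test_count_no_sites(self):
        m = TravelTimeMatrix(["b1"], [], np.zeros((1, 0)))
        assert fs.count_within(m, 30.0) == {"b1": 0}

    def test_count_all_colocated(self):
        m = TravelTimeMatrix(["b1"], ["s1", "s2"], [[0.0, 0.0]])
        assert fs.count_within(m, 30.0) == {"b1": 2}


class TestPercentWithAccess:
    def test_full_coverage(self):
        m = TravelTimeMatrix(["b1", "b2"], ["s1"], [[5.0], [10.0]])
        assert fs.percent_with_access(m, {"b1": 10, "b2": 30}, 30.0) == 1.0

    def test_no_coverage(self):
        m = TravelTimeMatrix(["b1"], ["s1"], [[50.0]])
        assert fs.percent_with_access(m, {"b1": 10}, 30.0) == 0.0

    def test_partial_coverage_weighted_by_population(self):
        m = TravelTimeMatrix(["b1", "b2"], ["s1"], [[50.0], [10.0]])
        assert fs.percent_with_access(m, {"b1": 10, "b2": 30}, 30.0) == 0.75

    def test_zero_population_undefined(self):
        m = TravelTimeMatrix(["b1"], ["s1"], [[5.0]])
        assert math.isnan(fs.percent_with_access(m, {"b1": 0}, 30.0))


class TestInvariants:
    def test_conservation_identity_toytown(self, toytown):
        """sum_i D_i A_i == sum_j S_j over sites with populated catchments."""
        from conftest import run_analysis

        an = run_analysis(toytown)
        pops = toytown.block_populations()
        lhs = sum(pops[b.block_id] * b.a_2sfca for b in an.block_access)
        rhs = sum(an.supply[r.site_id] for r in an.ratios if not r.zero_demand)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_monotone_in_threshold(self, toytown):
        matrix = fs.travel_time_matrix(
            toytown.network,
            {b.block_id: b.node_id for b in toytown.blocks},
            {s.site_id: s.node_id for s in toytown.sites},
        )
        by_p: dict[str, list] = {}
        for s in toytown.sites:
            by_p.setdefault(s.provider_id, []).append(s)
        allocs = fs.allocate_all(fs.filter_contracts(toytown.contracts, by_p),
                                 toytown.sites)
        supply = fs.site_supply(allocs)
        pops = toytown.block_populations()
        prev_n = prev_pct = None
        prev_total = None
        for T in (10.0, 20.0, 30.0, 40.0):
            ratios = fs.supply_ratio(supply, matrix, pops, T)
            access = fs.access_2sfca(ratios, matrix, T)
            n = np.array([b.n_within for b in access])
            pct = fs.percent_with_access(matrix, pops, T)
            # population-weighted total access equals supply inside reach,
            # which only grows as more sites gain a populated catchment
            total = sum(pops[b.block_id] * b.a_2sfca for b in access)
            if prev_n is not None:
                assert np.all(n >= prev_n)
                assert pct >= prev_pct
                assert total >= prev_total - 1e-9 * max(1.0, abs(prev_total))
            prev_n, prev_pct, prev_total = n, pct, total

    def test_a2sfca_can_decrease_as_threshold_grows(self):
        """Binary 2SFCA is not block-monotone in T: a larger walkshed adds
        population to a site's denominator and can dilute nearby access."""
        m = TravelTimeMatrix(["near", "far"], ["s1"], [[5.0], [25.0]])
        pops = {"near": 10, "far": 90}
        supply = {"s1": 100.0}
        a10 = fs.access_2sfca(fs.supply_ratio(supply, m, pops, 10.0), m, 10.0)
        a30 = fs.access_2sfca(fs.supply_ratio(supply, m, pops, 30.0), m, 30.0)
        near10 = next(b for b in a10 if b.block_id == "near").a_2sfca
        near30 = next(b for b in a30 if b.block_id == "near").a_2sfca
        assert near10 == 10.0 and near30 == 1.0  # dilution, not an error

    def test_program_additivity(self, toytown):
        """A_i over ALL equals the sum of per-program A_i."""
        from conftest import run_analysis

        an = run_analysis(toytown)
        total = {b.block_id: b.a_2sfca for b in an.block_access}
        pops = toytown.block_populations()
        summed = {bid: 0.0 for bid in total}
        for p in fs.ProgramType:
            supply_p = fs.site_supply(an.allocations, contracts=an.in_scope,
                                      program_type=p)
            supply_p = {s: v for s, v in supply_p.items()}
            if not supply_p:
                continue
            ratios = fs.supply_ratio(supply_p, an.matrix, pops, 30.0)
            for b in fs.access_2sfca(ratios, an.matrix, 30.0, p.value):
                summed[b.block_id] += b.a_2sfca
        for bid in total:
            assert summed[bid] == pytest.approx(total[bid], rel=1e-9, abs=1e-12)
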