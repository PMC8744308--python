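"""Shared fixtures: the worked 2SFCA instance, a small city, and one
full-scale analysis of the hq_downtown preset reused across tests."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import fundshed as fs
from fundshed.travel import TravelTimeMatrix


@pytest.fixture()
def worked_instance():
    """3-block / 2-site instance with hand-computable 2SFCA values.

    t (minutes): b1 -> (10, 40), b2 -> (20, 20), b3 -> (35, 15);
    D = (10, 20, 30); S = (120, 60); T = 30.
    """
    matrix = TravelTimeMatrix(
        origin_ids=["b1", "b2", "b3"],
        dest_ids=["s1", "s2"],
        minutes=[[10.0, 40.0], [20.0, 20.0], [35.0, 15.0]],
    )
    populations = {"b1": 10, "b2": 20, "b3": 30}
    supply = {"s1": 120.0, "s2": 60.0}
    return matrix, populations, supply


@pytest.fixture(scope="session")
def toytown():
    """Small synthetic city (360 blocks, 60 tracts) for fast end-to-end checks."""
    return fs.generate_scenario(fs.preset("toytown"))


@dataclass
class Analysis:
    """In-memory result of the full analysis chain on one scenario."""

    scenario: fs.Scenario
    matrix: TravelTimeMatrix
    in_scope: list
    allocations: list
    supply: dict
    ratios: list
    block_access: list
    hardship: dict  # tract -> tercile
    tract_access: list
    funding_hq: object
    funding_all: object


def run_analysis(scenario: fs.Scenario, T: float = 30.0) -> Analysis:
    matrix = fs.travel_time_matrix(
        scenario.network,
        {b.block_id: b.node_id for b in scenario.blocks},
        {s.site_id: s.node_id for s in scenario.sites},
    )
    by_provider: dict[str, list] = {}
    for s in scenario.sites:
        by_provider.setdefault(s.provider_id, []).append(s)
    in_scope = fs.filter_contracts(scenario.contracts, by_provider)
    allocations = fs.allocate_all(in_scope, scenario.sites)
    supply = fs.site_supply(allocations)
    pops = scenario.block_populations()
    ratios = fs.supply_ratio(supply, matrix, pops, T)
    block_access = fs.access_2sfca(ratios, matrix, T)

    index = fs.hardship_index({t.tract_id: t.components for t in scenario.tracts})
    hardship = fs.tercile_classify(index)
    tract_access = fs.aggregate_to_tract(
        block_access, scenario.block_to_tract(), "unweighted", pops
    )
    fs.assign_spending_terciles(tract_access)

    node_tract = {}
    for b in scenario.blocks:
        node_tract.setdefault(b.node_id, b.tract_id)
    site_area = {s.site_id: node_tract[s.node_id] for s in scenario.sites
                 if s.node_id in node_tract}
    funding_hq = fs.container_funding(
        allocations, in_scope, scenario.sites, site_area, "hq_only"
    )
    funding_all = fs.container_funding(
        allocations, in_scope, scenario.sites, site_area, "all_sites"
    )
    return Analysis(scenario, matrix, in_scope, allocations, supply, ratios,
                    block_access, hardship, tract_access, funding_hq, funding_all)


@pytest.fixture(scope="session")
def hq_downtown_analysis():
    """Full analysis of the hq_downtown preset (600 tracts, 4800 blocks,
    150 providers, seed 7) — the study conditions for the headline checks."""
    return run_analysis(fs.generate_scenario(fs.preset("hq_downtown")))
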