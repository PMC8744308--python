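"""Synthetic-city generator: lattice structure, population moments,
hardship gradient, placement biases, determinism and integrity."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import fundshed as fs
from fundshed.errors import (
    InvalidParameterError,
    InvalidScenarioError,
    ResourceGuardError,
)
from fundshed.synth import generate_providers
from fundshed.types import ScenarioConfig

from oracles import bfs_connected


class TestStreetNetwork:
    @pytest.mark.parametrize(
        "rows,cols,n_nodes,n_edges",
        [(2, 2, 4, 4), (1, 1, 1, 0), (3, 4, 12, 17), (1, 5, 5, 4)],
    )
    def test_full_lattice_counts(self, rows, cols, n_nodes, n_edges):
        net = fs.generate_street_network(rows, cols, 100.0, 0.0, seed=0)
        assert net.n_nodes == n_nodes
        assert net.n_edges == n_edges
        assert all(
            d["length_m"] == 100.0 for *_, d in net.graph.edges(data=True)
        )

    def test_thinned_lattice_stays_connected(self):
        net = fs.generate_street_network(10, 10, 100.0, 0.2, seed=1)
        assert net.n_nodes == 100
        assert net.n_edges <= 180  # full 10x10 lattice
        assert bfs_connected(net.graph)

    def test_thinning_removes_edges(self):
        full = fs.generate_street_network(10, 10, 100.0, 0.0, seed=1)
        thinned = fs.generate_street_network(10, 10, 100.0, 0.3, seed=1)
        assert thinned.n_edges < full.n_edges

    def test_invalid_edge_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            fs.generate_street_network(2, 2, 0.0, 0.0, seed=0)
        with pytest.raises(InvalidParameterError):
            fs.generate_street_network(2, 2, -5.0, 0.0, seed=0)

    def test_deterministic_for_fixed_seed(self):
        a = fs.generate_street_network(8, 8, 50.0, 0.25, seed=42)
        b = fs.generate_street_network(8, 8, 50.0, 0.25, seed=42)
        assert sorted(a.graph.edges) == sorted(b.graph.edges)


class TestBlocks:
    def test_zero_blocks(self):
        net = fs.generate_street_network(3, 3, 100.0)
        assert fs.generate_blocks(net, 0, 50.0) == []

    def test_zero_mean_population(self):
        net = fs.generate_street_network(3, 3, 100.0)
        blocks = fs.generate_blocks(net, 20, 0.0, seed=1)
        assert all(b.population == 0 for b in blocks)

    def test_population_mean_matches_distribution(self):
        # law-of-large-numbers check: sample mean within 3 SE of the target
        net = fs.generate_street_network(5, 5, 100.0)
        mean, disp, n = 50.0, 2.0, 10_000
        blocks = fs.generate_blocks(net, n, mean, disp, seed=9)
        pops = np.array([b.population for b in blocks])
        se = np.sqrt((mean + mean**2 / disp) / n)
        assert abs(pops.mean() - mean) < 3 * se

    def test_resource_guard(self):
        net = fs.generate_street_network(2, 2, 100.0)
        with pytest.raises(ResourceGuardError):
            fs.generate_blocks(net, 1000, 10.0, max_blocks=100)

    def test_blocks_sit_on_network_nodes(self):
        net = fs.generate_street_network(4, 4, 100.0, 0.1, seed=2)
        blocks = fs.generate_blocks(net, 50, 30.0, seed=3)
        assert all(net.has_node(b.node_id) for b in blocks)


class TestTracts:
    def _blocks(self, n, net=None):
        net = net or fs.generate_street_network(10, 10, 100.0)
        return fs.generate_blocks(net, n, 40.0, seed=5), net

    def test_partition_into_tracts(self):
        blocks, _ = self._blocks(9)
        tracts = fs.generate_tracts(blocks, 3, 0.5, seed=1)
        assert len(tracts) == 3
        ids = [bid for t in tracts for bid in t.block_ids]
        assert sorted(ids) == sorted(b.block_id for b in blocks)
        assert all(b.tract_id for b in blocks)

    def test_zero_gradient_gives_no_spatial_correlation(self):
        blocks, net = self._blocks(300)
        tracts = fs.generate_tracts(blocks, 1, 0.0, seed=2, network=net)
        s = np.arange(len(tracts))  # tract order follows the spatial sweep
        pov = np.array([t.components["poverty"] for t in tracts])
        r = np.corrcoef(s, pov)[0, 1]
        assert abs(r) < 0.1

    def test_noise_free_gradient_is_strictly_monotone(self):
        blocks, net = self._blocks(40)
        tracts = fs.generate_tracts(blocks, 1, 1.0, seed=0, noise_sd=0.0,
                                    network=net)
        coord = [np.mean([sum(net.coords(bid_node))
                          for bid_node in [b.node_id for b in blocks
                                           if b.tract_id == t.tract_id]])
                 for t in tracts]
        pov = [t.components["poverty"] for t in tracts]
        order = np.argsort(coord)
        distinct = np.diff(np.array(coord)[order]) > 0
        assert all(p2 > p1 for p1, p2, d in
                   zip(np.array(pov)[order], np.array(pov)[order][1:], distinct)
                   if d)

    def test_income_anticorrelated_with_poverty(self):
        blocks, net = self._blocks(300)
        tracts = fs.generate_tracts(blocks, 1, 0.9, seed=4, network=net)
        pov = [t.components["poverty"] for t in tracts]
        inc = [t.components["per_capita_income"] for t in tracts]
        assert np.corrcoef(pov, inc)[0, 1] < -0.5


class TestProviders:
    def _city(self, seed=0):
        net = fs.generate_street_network(10, 10, 100.0)
        blocks = fs.generate_blocks(net, 300, 40.0, seed=seed)
        tracts = fs.generate_tracts(blocks, 5, 0.8, seed=seed, network=net)
        idx = fs.hardship_index({t.tract_id: t.components for t in tracts})
        labels = fs.tercile_classify(idx)
        return net, blocks, tracts, labels

    def test_no_satellites_means_all_hq(self):
        net, blocks, tracts, labels = self._city()
        cfg = ScenarioConfig(n_providers=20, satellites_per_provider_mean=0.0)
        _, sites, _ = generate_providers(cfg, tracts, blocks, net, labels, seed=1)
        assert sites and all(s.is_headquarter for s in sites)

    def test_share_prob_zero_means_no_shares(self):
        net, blocks, tracts, labels = self._city()
        cfg = ScenarioConfig(n_providers=30, share_specified_prob=0.0)
        _, _, contracts = generate_providers(cfg, tracts, blocks, net, labels, seed=1)
        assert all(c.site_shares is None for c in contracts)

    def test_unbiased_hq_placement_is_uniform(self):
        # chi-square over hardship terciles under bias 0
        net, blocks, tracts, labels = self._city()
        cfg = ScenarioConfig(n_providers=3000, hq_low_hardship_bias=0.0,
                             satellites_per_provider_mean=0.0)
        providers, sites, _ = generate_providers(cfg, tracts, blocks, net,
                                                 labels, seed=2)
        tract_of_node = {}
        for b in blocks:
            tract_of_node.setdefault(b.node_id, b.tract_id)
        counts = {"low": 0, "medium": 0, "high": 0}
        for s in sites:
            counts[labels[tract_of_node[s.node_id]]] += 1
        sizes = {g: sum(1 for v in labels.values() if v == g) for g in counts}
        n = len(sites)
        expected = [n * sizes[g] / len(labels) for g in counts]
        chi2 = sum((c - e) ** 2 / e for c, e in zip(counts.values(), expected))
        assert stats.chi2.sf(chi2, df=2) > 0.001

    def test_impossible_bias_raises(self):
        net, blocks, tracts, labels = self._city()
        all_low = {t: "low" for t in labels}
        cfg = ScenarioConfig(n_providers=5, satellite_high_hardship_bias=1.0,
                             satellites_per_provider_mean=2.0)
        with pytest.raises(InvalidScenarioError):
            generate_providers(cfg, tracts, blocks, net, all_low, seed=0)

    def test_shares_sum_to_one(self):
        net, blocks, tracts, labels = self._city()
        cfg = ScenarioConfig(n_providers=40, share_specified_prob=1.0)
        _, sites, contracts = generate_providers(cfg, tracts, blocks, net,
                                                 labels, seed=3)
        for c in contracts:
            assert abs(sum(c.site_shares.values()) - 1.0) <= 1e-9


class TestScenario:
    def test_reproducibility_bit_identical(self):
        cfg = fs.preset("toytown")
        a = fs.generate_scenario(cfg)
        b = fs.generate_scenario(fs.preset("toytown"))
        assert [(x.block_id, x.node_id, x.population, x.tract_id)
                for x in a.blocks] == \
               [(x.block_id, x.node_id, x.population, x.tract_id)
                for x in b.blocks]
        assert [(t.tract_id, t.components) for t in a.tracts] == \
               [(t.tract_id, t.components) for t in b.tracts]
        assert [(c.contract_id, c.amount, c.program_type, c.site_shares,
                 c.citywide) for c in a.contracts] == \
               [(c.contract_id, c.amount, c.program_type, c.site_shares,
                 c.citywide) for c in b.contracts]

    def test_generated_scenario_passes_validation(self, toytown):
        fs.validate_scenario(toytown)  # raises on any integrity violation

    def test_hq_downtown_hq_more_low_hardship_than_satellites(
        self, hq_downtown_analysis
    ):
        """HQs concentrate in low-hardship tracts more than satellites do."""
        scen = hq_downtown_analysis.scenario
        labels = hq_downtown_analysis.hardship
        tract_of_node = {}
        for b in scen.blocks:
            tract_of_node.setdefault(b.node_id, b.tract_id)

        def frac_low(sites):
            in_low = [labels[tract_of_node[s.node_id]] == "low" for s in sites]
            return np.mean(in_low)

        hqs = [s for s in scen.sites if s.is_headquarter]
        sats = [s for s in scen.sites if not s.is_headquarter]
        assert frac_low(hqs) > frac_low(sats)
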