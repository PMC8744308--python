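"""Synthetic-city generator.

Generates cities with the statistical structure the funded-access analysis
assumes: a connected walkable street grid, housing blocks with
over-dispersed populations, census tracts whose hardship components follow
a spatially autocorrelated gradient (income running opposite to the five
adverse components), and providers whose headquarters are biased toward
low-hardship areas while satellite service sites are biased toward
medium/high-hardship areas — the placement pattern that makes the
headquarters-only "container" view misleading.

All randomness flows from a single seed through ``numpy`` generators, so a
fixed :class:`~fundshed.types.ScenarioConfig` reproduces bit-identical
output.
"""

from __future__ import annotations

import math
from typing import Sequence

import networkx as nx
import numpy as np

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    InvalidScenarioError,
    ResourceGuardError,
)
from .types import (
    ADVERSE_COMPONENTS,
    CensusTract,
    Contract,
    HousingBlock,
    Provider,
    Scenario,
    ScenarioConfig,
    ServiceSite,
    StreetNetwork,
)

#: guard against accidentally huge block requests
MAX_BLOCKS = 1_000_000

#: ranges (lo, hi) spanned by each adverse hardship component along the gradient
_COMPONENT_RANGES = {
    "crowded_housing": (2.0, 30.0),
    "poverty": (5.0, 65.0),
    "unemployment": (3.0, 35.0),
    "low_education": (5.0, 50.0),
    "dependents": (25.0, 45.0),
}
_INCOME_RANGE = (15_000.0, 100_000.0)  # runs opposite to the adverse components

#: among biased satellite draws, weight of the high stratum vs medium
_SAT_HIGH_WEIGHT = 0.7


def generate_street_network(
    rows: int,
    cols: int,
    edge_length_m: float,
    removal_prob: float = 0.0,
    seed: int = 0,
) -> StreetNetwork:
    """Grid-lattice street network with random connectivity-preserving thinning.

    Nodes are numbered row-major (``r * cols + c``) with coordinates in
    meters. Each edge is independently proposed for removal with
    probability ``removal_prob`` but only removed if the graph stays
    connected, so every generated network is a single component.
    """
    if rows < 1 or cols < 1:
        raise InvalidParameterError("rows and cols must be >= 1")
    if edge_length_m <= 0:
        raise InvalidParameterError("edge_length_m must be > 0")
    if not 0.0 <= removal_prob < 1.0:
        raise InvalidParameterError("removal_prob must be in [0, 1)")

    g = nx.Graph()
    for r in range(rows):
        for c in range(cols):
            g.add_node(r * cols + c, x=c * edge_length_m, y=r * edge_length_m)
    for r in range(rows):
        for c in range(cols):
            n = r * cols + c
            if c + 1 < cols:
                g.add_edge(n, n + 1, length_m=edge_length_m)
            if r + 1 < rows:
                g.add_edge(n, n + cols, length_m=edge_length_m)

    if removal_prob > 0:
        rng = np.random.default_rng(seed)
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            if rng.random() < removal_prob:
                g.remove_edge(u, v)
                if not nx.is_connected(g):
                    g.add_edge(u, v, length_m=edge_length_m)
    return StreetNetwork(g)


def generate_blocks(
    network: StreetNetwork,
    n_blocks: int,
    pop_mean: float,
    pop_dispersion: float = 1.0,
    seed: int = 0,
    max_blocks: int = MAX_BLOCKS,
) -> list[HousingBlock]:
    """Housing blocks on network nodes with negative-binomial populations.

    Blocks are placed uniformly on nodes (with replacement) and then sorted
    along a diagonal spatial sweep (by node ``x + y``), so that
    contiguous-in-index groups of blocks — the tracts formed downstream —
    are spatially coherent. The population count distribution has the given
    mean and variance ``mean + mean**2 / dispersion``.
    """
    if n_blocks < 0:
        raise InvalidParameterError("n_blocks must be >= 0")
    if n_blocks > max_blocks:
        raise ResourceGuardError(f"n_blocks={n_blocks} exceeds cap {max_blocks}")
    if pop_mean < 0:
        raise InvalidParameterError("pop_mean must be >= 0")
    if pop_dispersion <= 0:
        raise InvalidParameterError("pop_dispersion must be > 0")
    if n_blocks == 0:
        return []

    rng = np.random.default_rng(seed)
    nodes = network.nodes()
    chosen = rng.choice(len(nodes), size=n_blocks, replace=True)
    if pop_mean == 0:
        pops = np.zeros(n_blocks, dtype=int)
    else:
        p = pop_dispersion / (pop_dispersion + pop_mean)
        pops = rng.negative_binomial(pop_dispersion, p, size=n_blocks)

    order = sorted(
        range(n_blocks),
        key=lambda i: (sum(network.coords(nodes[chosen[i]])), nodes[chosen[i]], i),
    )
    return [
        HousingBlock(
            block_id=f"b{k:05d}",
            node_id=nodes[chosen[i]],
            population=int(pops[i]),
        )
        for k, i in enumerate(order)
    ]


def generate_tracts(
    blocks: Sequence[HousingBlock],
    blocks_per_tract: int,
    gradient_strength: float,
    seed: int = 0,
    noise_sd: float = 0.15,
    network: StreetNetwork | None = None,
) -> list[CensusTract]:
    """Group blocks into tracts and draw spatially graded hardship components.

    Blocks are grouped contiguously in index order (``blocks_per_tract``
    per tract, last tract possibly smaller) and each block's ``tract_id``
    is filled in. Each tract gets a spatial coordinate ``s`` in [0, 1] —
    the normalised mean ``x + y`` of its block nodes when a network is
    supplied, else the normalised tract index. Every component is a
    monotone function of a latent position
    ``clip(gradient * (s - 1/2) + 1/2 + noise, 0, 1)`` with independent
    noise per component; per-capita income decreases in the position while
    the five adverse components increase.
    """
    if not blocks:
        raise InvalidInputError("blocks must be non-empty")
    if blocks_per_tract < 1:
        raise InvalidParameterError("blocks_per_tract must be >= 1")
    if not 0.0 <= gradient_strength <= 1.0:
        raise InvalidParameterError("gradient_strength must be in [0, 1]")

    groups = [
        list(blocks[i : i + blocks_per_tract])
        for i in range(0, len(blocks), blocks_per_tract)
    ]
    n = len(groups)
    if network is not None:
        raw = np.array(
            [np.mean([sum(network.coords(b.node_id)) for b in g]) for g in groups]
        )
    else:
        raw = np.arange(n, dtype=float)
    span = raw.max() - raw.min()
    s = (raw - raw.min()) / span if span > 0 else np.full(n, 0.5)

    rng = np.random.default_rng(seed)
    tracts = []
    for k, group in enumerate(groups):
        tract_id = f"t{k:04d}"
        comps: dict[str, float] = {}
        for name in ADVERSE_COMPONENTS:
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            pos = min(max(gradient_strength * (s[k] - 0.5) + 0.5 + eps, 0.0), 1.0)
            lo, hi = _COMPONENT_RANGES[name]
            comps[name] = lo + (hi - lo) * pos
        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        pos = min(max(gradient_strength * (s[k] - 0.5) + 0.5 + eps, 0.0), 1.0)
        lo, hi = _INCOME_RANGE
        comps["per_capita_income"] = hi - (hi - lo) * pos
        for b in group:
            b.tract_id = tract_id
        tracts.append(
            CensusTract(
                tract_id=tract_id,
                block_ids=tuple(b.block_id for b in group),
                components=comps,
            )
        )
    return tracts


def _pick_stratum(rng, biased: list, universe: list, bias: float, what: str):
    """Sample one tract: from the biased stratum with probability ``bias``."""
    use_biased = rng.random() < bias
    pool = biased if use_biased else universe
    if not pool:
        if use_biased:
            raise InvalidScenarioError(
                f"{what}: bias requires an empty hardship stratum"
            )
        raise InvalidScenarioError(f"{what}: no tracts available")
    return pool[rng.integers(len(pool))]


def generate_providers(
    config: ScenarioConfig,
    tracts: Sequence[CensusTract],
    blocks: Sequence[HousingBlock],
    network: StreetNetwork,
    hardship_labels: dict[str, str],
    seed: int = 0,
) -> tuple[list[Provider], list[ServiceSite], list[Contract]]:
    """Providers, their HQ/satellite sites, and one contract per provider.

    HQ tracts are drawn from the low-hardship stratum with probability
    ``hq_low_hardship_bias`` (else uniformly over all tracts); satellite
    tracts from the medium/high strata with probability
    ``satellite_high_hardship_bias`` (weighted toward high), else
    uniformly. Site nodes are sampled among the chosen tract's block
    nodes. Contract amounts are lognormal, program types follow the
    configured mixture, and site shares / citywide flags are Bernoulli.
    """
    rng = np.random.default_rng(seed)
    low = [t for t in tracts if hardship_labels.get(t.tract_id) == "low"]
    med = [t for t in tracts if hardship_labels.get(t.tract_id) == "medium"]
    high = [t for t in tracts if hardship_labels.get(t.tract_id) == "high"]
    universe = list(tracts)
    if config.hq_low_hardship_bias == 1.0 and not low:
        raise InvalidScenarioError("hq bias 1.0 but no low-hardship tracts")
    if config.satellite_high_hardship_bias == 1.0 and not (med or high):
        raise InvalidScenarioError("satellite bias 1.0 but no medium/high tracts")

    nodes_of = {
        t.tract_id: sorted({b.node_id for b in blocks if b.tract_id == t.tract_id})
        for t in tracts
    }
    programs = sorted(config.program_mix, key=lambda p: p.value)
    weights = np.array([config.program_mix[p] for p in programs])
    mu = math.log(config.amount_median)

    providers, sites, contracts = [], [], []
    for k in range(config.n_providers):
        pid = f"p{k:03d}"
        hq_sid = f"{pid}_hq"
        # headquarter placement
        if rng.random() < config.hq_low_hardship_bias and low:
            hq_tract = low[rng.integers(len(low))]
        else:
            hq_tract = universe[rng.integers(len(universe))]
        hq_node = nodes_of[hq_tract.tract_id][
            rng.integers(len(nodes_of[hq_tract.tract_id]))
        ]
        prov_sites = [
            ServiceSite(site_id=hq_sid, provider_id=pid, node_id=hq_node,
                        is_headquarter=True)
        ]
        # satellites
        n_sat = int(rng.poisson(config.satellites_per_provider_mean))
        for j in range(n_sat):
            if rng.random() < config.satellite_high_hardship_bias and (med or high):
                if high and (not med or rng.random() < _SAT_HIGH_WEIGHT):
                    s_tract = high[rng.integers(len(high))]
                else:
                    s_tract = med[rng.integers(len(med))]
            else:
                s_tract = universe[rng.integers(len(universe))]
            s_node = nodes_of[s_tract.tract_id][
                rng.integers(len(nodes_of[s_tract.tract_id]))
            ]
            prov_sites.append(
                ServiceSite(site_id=f"{pid}_s{j}", provider_id=pid,
                            node_id=s_node, is_headquarter=False)
            )
        providers.append(Provider(provider_id=pid, name=f"Provider {k}",
                                  hq_site_id=hq_sid))
        sites.extend(prov_sites)

        amount = float(rng.lognormal(mu, config.amount_sigma))
        program = programs[rng.choice(len(programs), p=weights)]
        shares = None
        if rng.random() < config.share_specified_prob:
            w = rng.dirichlet(np.ones(len(prov_sites)))
            shares = {s.site_id: float(x) for s, x in zip(prov_sites, w)}
            # exact unit sum despite float rounding
            last = prov_sites[-1].site_id
            shares[last] = 1.0 - sum(v for sid, v in shares.items() if sid != last)
        contracts.append(
            Contract(
                contract_id=f"c{k:03d}",
                provider_id=pid,
                amount=amount,
                program_type=program,
                site_shares=shares,
                citywide=bool(rng.random() < config.citywide_prob),
            )
        )
    return providers, sites, contracts


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate a full synthetic city from one config (deterministic in seed)."""
    from .classify import hardship_index, tercile_classify

    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    network = generate_street_network(
        config.rows, config.cols, config.edge_length_m, config.removal_prob, seeds[0]
    )
    blocks = generate_blocks(
        network, config.n_blocks, config.pop_mean, config.pop_dispersion, seeds[1]
    )
    tracts = generate_tracts(
        blocks, config.blocks_per_tract, config.gradient_strength, seeds[2],
        noise_sd=config.noise_sd, network=network,
    )
    index = hardship_index({t.tract_id: t.components for t in tracts})
    labels = tercile_classify(index)
    providers, sites, contracts = generate_providers(
        config, tracts, blocks, network, labels, seeds[3]
    )
    scenario = Scenario(
        config=config, network=network, blocks=blocks, tracts=tracts,
        providers=providers, sites=sites, contracts=contracts,
    )
    validate_scenario(scenario)
    return scenario


def validate_scenario(scenario: Scenario) -> None:
    """Referential-integrity pass over a generated or loaded scenario."""
    net = scenario.network
    block_ids = [b.block_id for b in scenario.blocks]
    if len(set(block_ids)) != len(block_ids):
        raise InvalidInputError("duplicate block ids")
    for b in scenario.blocks:
        if not net.has_node(b.node_id):
            raise InvalidInputError(f"block {b.block_id} on unknown node {b.node_id}")
    seen: set[str] = set()
    for t in scenario.tracts:
        overlap = seen & set(t.block_ids)
        if overlap:
            raise InvalidInputError(f"blocks in multiple tracts: {sorted(overlap)[:3]}")
        seen |= set(t.block_ids)
    if seen != set(block_ids):
        raise InvalidInputError("tracts do not partition the blocks")

    sites_by_id = {s.site_id: s for s in scenario.sites}
    for p in scenario.providers:
        hq = sites_by_id.get(p.hq_site_id)
        if hq is None or not hq.is_headquarter or hq.provider_id != p.provider_id:
            raise InvalidInputError(f"provider {p.provider_id}: bad hq_site_id")
        n_hq = sum(
            1 for s in scenario.sites
            if s.provider_id == p.provider_id and s.is_headquarter
        )
        if n_hq != 1:
            raise InvalidInputError(f"provider {p.provider_id}: {n_hq} headquarters")
    for s in scenario.sites:
        if not net.has_node(s.node_id):
            raise InvalidInputError(f"site {s.site_id} on unknown node {s.node_id}")
    provider_ids = {p.provider_id for p in scenario.providers}
    for c in scenario.contracts:
        if c.provider_id not in provider_ids:
            raise InvalidInputError(f"contract {c.contract_id}: unknown provider")
        c.validate_shares(
            [s.site_id for s in scenario.sites if s.provider_id == c.provider_id]
        )


#: named preset scenario configurations
PRESETS: dict[str, ScenarioConfig] = {
    # headquarters cluster downtown (low hardship), satellites in high/medium
    "hq_downtown": ScenarioConfig(seed=7),
    # unbiased placement: null city for falsification checks
    "uniform_city": ScenarioConfig(
        hq_low_hardship_bias=0.0, satellite_high_hardship_bias=0.0, seed=11
    ),
    # small, fast city for smoke tests and examples
    "toytown": ScenarioConfig(
        rows=12, cols=12, edge_length_m=200.0, n_blocks=360, blocks_per_tract=6,
        n_providers=25, seed=3,
    ),
}


def preset(name: str, seed: int | None = None) -> ScenarioConfig:
    """Fetch a copy of a named preset, optionally overriding its seed."""
    if name not in PRESETS:
        raise InvalidParameterError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        )
    cfg = ScenarioConfig.from_dict(PRESETS[name].to_dict())
    if seed is not None:
        cfg.seed = seed
    return cfg
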