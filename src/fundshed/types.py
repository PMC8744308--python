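"""Domain types for the funded-access analysis.

The analysis moves dollars from *contracts* (one per provider, with an
amount and a program type) onto *service sites* (a headquarter plus
optional satellite offices), measures walking times from *housing blocks*
to those sites over a *street network*, and aggregates block-level access
up to *census tracts* carrying the six socio-economic hardship components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Mapping, Sequence

import networkx as nx

from .errors import InvalidInputError, InvalidScenarioError

#: meters in one statute mile; times are carried in floating minutes.
M_PER_MILE = 1609.344

SHARE_TOL = 1e-9


class ProgramType(str, Enum):
    """CDPH-style program areas a contract can fund."""

    HIV_STI = "HIV_STI"
    HEALTH_PROMOTION = "HEALTH_PROMOTION"
    MICAH = "MICAH"
    HEALTH_PROTECTION = "HEALTH_PROTECTION"
    CHRONIC_DISEASE = "CHRONIC_DISEASE"


#: default program-type funding mix (shares of total dollars).
DEFAULT_PROGRAM_MIX: dict[ProgramType, float] = {
    ProgramType.HIV_STI: 0.70,
    ProgramType.HEALTH_PROMOTION: 0.16,
    ProgramType.MICAH: 0.06,
    ProgramType.HEALTH_PROTECTION: 0.05,
    ProgramType.CHRONIC_DISEASE: 0.03,
}

HARDSHIP_COMPONENTS = (
    "crowded_housing",
    "poverty",
    "unemployment",
    "low_education",
    "dependents",
    "per_capita_income",
)

#: components where a larger value means more hardship (income is the exception)
ADVERSE_COMPONENTS = HARDSHIP_COMPONENTS[:-1]


@dataclass
class StreetNetwork:
    """Undirected pedestrian street network.

    Wraps a :class:`networkx.Graph` whose nodes carry planar ``x``/``y``
    coordinates in meters and whose edges carry a strictly positive
    ``length_m``.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise InvalidInputError(f"self-loop at node {u!r}")
            if d.get("length_m", 0.0) <= 0:
                raise InvalidInputError(f"non-positive length on edge ({u!r}, {v!r})")
        for n, d in self.graph.nodes(data=True):
            if "x" not in d or "y" not in d:
                raise InvalidInputError(f"node {n!r} missing planar coordinates")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    def coords(self, node_id) -> tuple[float, float]:
        d = self.graph.nodes[node_id]
        return float(d["x"]), float(d["y"])

    def has_node(self, node_id) -> bool:
        return self.graph.has_node(node_id)

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)


@dataclass
class HousingBlock:
    """Demand point: a housing block snapped to a network node."""

    block_id: str
    node_id: int
    population: int
    tract_id: str = ""

    def __post_init__(self) -> None:
        if self.population < 0 or int(self.population) != self.population:
            raise InvalidInputError(
                f"block {self.block_id}: population must be a non-negative integer"
            )
        self.population = int(self.population)


@dataclass
class CensusTract:
    """Tract with its member blocks and six hardship components.

    ``components`` maps the names in :data:`HARDSHIP_COMPONENTS` to values:
    five percentages in [0, 100] plus ``per_capita_income`` in dollars.
    """

    tract_id: str
    block_ids: tuple[str, ...]
    components: dict[str, float]

    def __post_init__(self) -> None:
        if not self.block_ids:
            raise InvalidInputError(f"tract {self.tract_id}: empty block list")
        missing = [c for c in HARDSHIP_COMPONENTS if c not in self.components]
        if missing:
            raise InvalidInputError(
                f"tract {self.tract_id}: missing components {missing}"
            )
        for c in ADVERSE_COMPONENTS:
            v = self.components[c]
            if not 0.0 <= v <= 100.0:
                raise InvalidInputError(
                    f"tract {self.tract_id}: component {c}={v} outside [0, 100]"
                )
        if self.components["per_capita_income"] < 0:
            raise InvalidInputError(f"tract {self.tract_id}: negative income")


@dataclass
class Provider:
    """A delegate agency holding a contract; has exactly one headquarter site."""

    provider_id: str
    name: str
    hq_site_id: str


@dataclass
class ServiceSite:
    """Supply point: a service-delivery location of a provider."""

    site_id: str
    provider_id: str
    node_id: int
    is_headquarter: bool
    community_areas_served: tuple[str, ...] | None = None


@dataclass
class Contract:
    """A funding contract from the department to one provider.

    ``site_shares``, when present, maps site ids to fractions summing to 1;
    otherwise the amount is split equally among the provider's delivery
    sites. ``citywide`` contracts have no specific delivery sites and are
    excluded from the site-level analysis.
    """

    contract_id: str
    provider_id: str
    amount: float
    program_type: ProgramType
    site_shares: dict[str, float] | None = None
    citywide: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.amount) or self.amount < 0:
            raise InvalidInputError(
                f"contract {self.contract_id}: amount must be finite and >= 0"
            )
        self.program_type = ProgramType(self.program_type)

    def validate_shares(self, provider_site_ids: Sequence[str]) -> None:
        """Check share fractions sum to 1 and reference the provider's sites."""
        if self.site_shares is None:
            return
        from .errors import InvalidContractError

        total = sum(self.site_shares.values())
        if abs(total - 1.0) > SHARE_TOL:
            raise InvalidContractError(
                f"contract {self.contract_id}: shares sum to {total!r}, not 1"
            )
        stray = set(self.site_shares) - set(provider_site_ids)
        if stray:
            raise InvalidContractError(
                f"contract {self.contract_id}: shares reference foreign sites {sorted(stray)}"
            )


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic city.

    The defaults describe the ``hq_downtown`` study conditions: a walkable
    grid city of 600 tracts whose provider headquarters cluster in
    low-hardship areas while satellite offices cluster in medium/high
    hardship areas, with a contract mix dominated by HIV/STI funding.
    """

    # street network
    rows: int = 40
    cols: int = 40
    edge_length_m: float = 150.0
    removal_prob: float = 0.10
    # blocks
    n_blocks: int = 4800
    pop_mean: float = 60.0
    pop_dispersion: float = 2.0
    # tracts
    blocks_per_tract: int = 8
    gradient_strength: float = 0.85
    noise_sd: float = 0.15
    # providers / sites
    n_providers: int = 150
    hq_low_hardship_bias: float = 0.9
    satellites_per_provider_mean: float = 3.0
    satellite_high_hardship_bias: float = 0.8
    # contracts
    program_mix: dict[ProgramType, float] = field(
        default_factory=lambda: dict(DEFAULT_PROGRAM_MIX)
    )
    amount_median: float = 200_000.0
    amount_sigma: float = 1.0
    share_specified_prob: float = 0.3
    citywide_prob: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "removal_prob": self.removal_prob,
            "hq_low_hardship_bias": self.hq_low_hardship_bias,
            "satellite_high_hardship_bias": self.satellite_high_hardship_bias,
            "share_specified_prob": self.share_specified_prob,
            "citywide_prob": self.citywide_prob,
        }
        bad = [k for k, v in probs.items() if not 0.0 <= v <= 1.0]
        if bad:
            raise InvalidScenarioError(f"probabilities outside [0,1]: {bad}")
        if abs(sum(self.program_mix.values()) - 1.0) > 1e-9:
            raise InvalidScenarioError("program_mix weights must sum to 1")
        if self.edge_length_m <= 0:
            raise InvalidScenarioError("edge_length_m must be > 0")

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "program_mix":
                v = {ProgramType(k).value: float(w) for k, w in v.items()}
            d[f.name] = v
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        if "program_mix" in d:
            d["program_mix"] = {
                ProgramType(k): float(v) for k, v in d["program_mix"].items()
            }
        known = {f.name for f in fields(cls)}
        stray = set(d) - known
        if stray:
            from .errors import SchemaError

            raise SchemaError(f"unknown config keys: {sorted(stray)}", sorted(stray))
        return cls(**d)


@dataclass
class Scenario:
    """A fully generated synthetic city, ready for the analysis stages."""

    config: ScenarioConfig
    network: StreetNetwork
    blocks: list[HousingBlock]
    tracts: list[CensusTract]
    providers: list[Provider]
    sites: list[ServiceSite]
    contracts: list[Contract]

    def sites_of_provider(self, provider_id: str) -> list[ServiceSite]:
        return [s for s in self.sites if s.provider_id == provider_id]

    def block_populations(self) -> dict[str, int]:
        return {b.block_id: b.population for b in self.blocks}

    def block_to_tract(self) -> dict[str, str]:
        return {b.block_id: b.tract_id for b in self.blocks}
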