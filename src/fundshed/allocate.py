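"""Contract filtering and dollar allocation to service sites.

The conventional open-data ("container") view sums each contract's full
amount at the provider's headquarters. The site-level view divides each
contract across its actual delivery sites — by the recorded site shares
when present, otherwise equally among the headquarter and all satellite
offices. Dollars are conserved at every stage: filtering, allocation,
per-site supply and per-area sums never create or destroy in-scope money.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import InvalidContractError, InvalidInputError
from .types import Contract, ProgramType, ServiceSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiteAllocation:
    """Dollars of one contract allocated to one delivery site."""

    site_id: str
    contract_id: str
    amount: float


@dataclass
class AreaFunding:
    """Funding summed within one area, with optional per-capita standardisation."""

    area_id: str
    dollars: float
    population: int | None = None
    dollars_per_capita: float | None = None


@dataclass
class ContainerFunding:
    """Result of the container aggregation, with skipped-site diagnostics."""

    areas: list[AreaFunding]
    mode: str
    skipped_sites: int = 0

    def total(self) -> float:
        return sum(a.dollars for a in self.areas)

    def by_area(self) -> dict[str, float]:
        return {a.area_id: a.dollars for a in self.areas}


def filter_contracts(
    contracts: Iterable[Contract],
    provider_sites: Mapping[str, Sequence[ServiceSite]] | None = None,
) -> list[Contract]:
    """Keep site-specific contracts: not citywide, and (when site data is
    supplied) with at least one delivery site. Each exclusion is logged."""
    kept = []
    for c in contracts:
        if c.citywide:
            logger.info("contract %s excluded: citywide", c.contract_id)
            continue
        if provider_sites is not None and not provider_sites.get(c.provider_id):
            logger.info("contract %s excluded: provider has no sites", c.contract_id)
            continue
        kept.append(c)
    return kept


def allocate_contract(
    contract: Contract,
    sites: Sequence[ServiceSite],
    hq_delivers: bool = True,
) -> list[SiteAllocation]:
    """Divide one contract's dollars across the provider's sites.

    With recorded shares the amount is split proportionally. Without
    shares it is split equally among the headquarter and all satellites —
    or among satellites only when ``hq_delivers`` is false, in which case
    the headquarter still appears with an explicit $0 allocation.
    """
    if not sites:
        raise InvalidContractError(
            f"contract {contract.contract_id}: empty site list"
        )
    if contract.site_shares is not None:
        contract.validate_shares([s.site_id for s in sites])
        return [
            SiteAllocation(site_id=sid, contract_id=contract.contract_id,
                           amount=contract.amount * share)
            for sid, share in sorted(contract.site_shares.items())
        ]
    delivering = [s for s in sites if hq_delivers or not s.is_headquarter]
    if not delivering:
        raise InvalidContractError(
            f"contract {contract.contract_id}: no delivering sites "
            "(hq_delivers=False and no satellites)"
        )
    each = contract.amount / len(delivering)
    out = [
        SiteAllocation(site_id=s.site_id, contract_id=contract.contract_id,
                       amount=each)
        for s in delivering
    ]
    out += [
        SiteAllocation(site_id=s.site_id, contract_id=contract.contract_id,
                       amount=0.0)
        for s in sites if s not in delivering
    ]
    return out


def allocate_all(
    contracts: Iterable[Contract],
    sites: Sequence[ServiceSite],
    hq_delivers: bool = True,
) -> list[SiteAllocation]:
    """Allocate every (already filtered) contract across its provider's sites."""
    by_provider: dict[str, list[ServiceSite]] = {}
    for s in sites:
        by_provider.setdefault(s.provider_id, []).append(s)
    out: list[SiteAllocation] = []
    for c in contracts:
        out.extend(allocate_contract(c, by_provider.get(c.provider_id, []), hq_delivers))
    return out


def site_supply(
    allocations: Iterable[SiteAllocation],
    contracts: Sequence[Contract] | None = None,
    program_type: ProgramType | str | None = None,
) -> dict[str, float]:
    """Total supply S_j per site, optionally restricted to one program type."""
    if program_type is not None:
        if contracts is None:
            raise InvalidInputError("program filtering requires the contracts")
        program_type = ProgramType(program_type)
        wanted = {c.contract_id for c in contracts if c.program_type == program_type}
        allocations = [a for a in allocations if a.contract_id in wanted]
    supply: dict[str, float] = {}
    for a in allocations:
        supply[a.site_id] = supply.get(a.site_id, 0.0) + a.amount
    return supply


def container_funding(
    allocations: Iterable[SiteAllocation],
    contracts: Sequence[Contract],
    sites: Sequence[ServiceSite],
    area_of_site: Mapping[str, str],
    mode: str = "all_sites",
    area_population: Mapping[str, int] | None = None,
) -> ContainerFunding:
    """Sum funding inside each area ("container" aggregation).

    ``hq_only`` attributes each contract's *full* amount to the area of
    the provider's headquarters — the view an open contracts portal gives.
    ``all_sites`` sums the site-level allocations by the area containing
    each site. Sites without an area are skipped with a warning count.
    """
    if mode not in ("hq_only", "all_sites"):
        raise InvalidInputError(f"mode must be hq_only or all_sites, got {mode!r}")
    dollars: dict[str, float] = {}
    skipped = 0

    if mode == "hq_only":
        hq_of = {s.provider_id: s.site_id for s in sites if s.is_headquarter}
        for c in contracts:
            sid = hq_of.get(c.provider_id)
            area = area_of_site.get(sid) if sid else None
            if area is None:
                skipped += 1
                logger.warning("contract %s: HQ site has no area", c.contract_id)
                continue
            dollars[area] = dollars.get(area, 0.0) + c.amount
    else:
        for a in allocations:
            area = area_of_site.get(a.site_id)
            if area is None:
                skipped += 1
                logger.warning("site %s has no area; skipped", a.site_id)
                continue
            dollars[area] = dollars.get(area, 0.0) + a.amount

    areas = []
    all_area_ids = set(dollars)
    if area_population is not None:
        all_area_ids |= set(area_population)
    for area_id in sorted(all_area_ids):
        d = dollars.get(area_id, 0.0)
        pop = None if area_population is None else int(area_population.get(area_id, 0))
        per_cap = d / pop if pop else None
        areas.append(AreaFunding(area_id=area_id, dollars=d, population=pop,
                                 dollars_per_capita=per_cap))
    return ContainerFunding(areas=areas, mode=mode, skipped_sites=skipped)


def funding_share_by_group(
    area_funding: Sequence[AreaFunding],
    group_labels: Mapping[str, str],
) -> dict[str, float]:
    """Percent of total dollars falling in each group of areas (sums to 100)."""
    unlabeled = [a.area_id for a in area_funding if a.area_id not in group_labels]
    if unlabeled:
        raise InvalidInputError(f"areas without a group label: {unlabeled[:5]}")
    totals: dict[str, float] = {g: 0.0 for g in dict.fromkeys(group_labels.values())}
    for a in area_funding:
        totals[group_labels[a.area_id]] += a.dollars
    grand = sum(totals.values())
    if grand == 0:
        return {g: 0.0 for g in totals}
    return {g: 100.0 * v / grand for g, v in totals.items()}
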