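"""Block-level spatial access measures.

Three measures per housing block:

* funded access ``A_i`` by the two-step floating catchment area (2SFCA)
  method: each site's supply ``S_j`` (dollars) is divided by the total
  population that can reach it within the walking threshold, giving a
  supply-demand ratio ``R_j = S_j / sum_i D_i I(t_ij < T)``; each block
  then sums the ratios of the sites it can reach,
  ``A_i = sum_j R_j I(t_ij < T)`` — dollars per person within walkable
  reach;
* minutes to the nearest reachable site;
* the count of sites within the threshold.

All catchments use the strict indicator ``t < T``. With binary catchment
weights these definitions conserve dollars exactly:
``sum_i D_i A_i = sum_j S_j`` over sites whose catchment contains at
least one populated block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidInputError
from .travel import DEFAULT_THRESHOLD_MIN, TravelTimeMatrix


@dataclass(frozen=True)
class SupplyRatio:
    """Step-one ratio at one site: dollars per person able to reach it.

    Sites no populated block can reach get ``ratio = 0`` with
    ``zero_demand = True`` so they can be excluded from conservation
    accounting.
    """

    site_id: str
    ratio: float
    reachable_population: int
    zero_demand: bool = False


@dataclass
class BlockAccess:
    """All three access measures for one block (one program type or ALL)."""

    block_id: str
    a_2sfca: float
    nearest_minutes: float | None  # None = no site reachable at any time
    n_within: int
    program_type: str = "ALL"


def supply_ratio(
    site_supply: Mapping[str, float],
    matrix: TravelTimeMatrix,
    block_populations: Mapping[str, int],
    T: float = DEFAULT_THRESHOLD_MIN,
) -> list[SupplyRatio]:
    """Step one of 2SFCA: supply-demand ratio per site.

    ``matrix`` rows are blocks, columns are sites; the denominator sums
    block populations with ``t_ij < T``.
    """
    if T <= 0:
        raise InvalidInputError("threshold T must be > 0")
    missing = [s for s in site_supply if s not in matrix.dest_ids]
    if missing:
        raise InvalidInputError(f"sites not in travel matrix: {missing[:5]}")
    pops = np.array(
        [block_populations.get(b, 0) for b in matrix.origin_ids], dtype=float
    )
    if np.any(pops < 0):
        raise InvalidInputError("negative block population")
    inside = matrix.within(T)
    out = []
    for j, sid in enumerate(matrix.dest_ids):
        if sid not in site_supply:
            continue
        demand = float(pops[inside[:, j]].sum())
        if demand > 0:
            out.append(SupplyRatio(site_id=sid, ratio=site_supply[sid] / demand,
                                   reachable_population=int(demand)))
        else:
            out.append(SupplyRatio(site_id=sid, ratio=0.0, reachable_population=0,
                                   zero_demand=True))
    return out


def access_2sfca(
    supply_ratios: Sequence[SupplyRatio],
    matrix: TravelTimeMatrix,
    T: float = DEFAULT_THRESHOLD_MIN,
    program_type: str = "ALL",
) -> list[BlockAccess]:
    """Step two of 2SFCA: sum reachable supply ratios per block.

    Also fills the nearest-site time and within-threshold count so one
    pass yields the full block-access record.
    """
    if T <= 0:
        raise InvalidInputError("threshold T must be > 0")
    ratio_of = {r.site_id: r.ratio for r in supply_ratios}
    missing = [s for s in ratio_of if s not in matrix.dest_ids]
    if missing:
        raise InvalidInputError(
            f"supply ratios for sites absent from the matrix: {missing[:5]}"
        )
    cols = [j for j, sid in enumerate(matrix.dest_ids) if sid in ratio_of]
    ratios = np.array([ratio_of[matrix.dest_ids[j]] for j in cols])
    t = matrix.minutes[:, cols]
    inside = t < T

    out = []
    for i, bid in enumerate(matrix.origin_ids):
        finite = np.isfinite(t[i])
        nearest = float(t[i][finite].min()) if finite.any() else None
        out.append(
            BlockAccess(
                block_id=bid,
                a_2sfca=float(ratios[inside[i]].sum()),
                nearest_minutes=nearest,
                n_within=int(inside[i].sum()),
                program_type=program_type,
            )
        )
    return out


def time_to_nearest(matrix: TravelTimeMatrix) -> dict[str, float | None]:
    """Row-wise minimum over reachable sites; ``None`` when nothing is reachable."""
    out: dict[str, float | None] = {}
    for i, bid in enumerate(matrix.origin_ids):
        row = matrix.minutes[i]
        finite = np.isfinite(row)
        out[bid] = float(row[finite].min()) if finite.any() else None
    return out


def count_within(
    matrix: TravelTimeMatrix, T: float = DEFAULT_THRESHOLD_MIN
) -> dict[str, int]:
    """Number of sites strictly within ``T`` minutes of each block."""
    inside = matrix.within(T)
    return {bid: int(inside[i].sum()) for i, bid in enumerate(matrix.origin_ids)}


def percent_with_access(
    matrix: TravelTimeMatrix,
    block_populations: Mapping[str, int],
    T: float = DEFAULT_THRESHOLD_MIN,
    block_ids: Sequence[str] | None = None,
) -> float:
    """Fraction of population with >= 1 site within ``T`` minutes.

    Restricted to ``block_ids`` when given (e.g. one tract or hardship
    group). Returns ``nan`` when the total population is zero.
    """
    inside = matrix.within(T)
    keep = set(block_ids) if block_ids is not None else None
    covered = total = 0.0
    for i, bid in enumerate(matrix.origin_ids):
        if keep is not None and bid not in keep:
            continue
        d = float(block_populations.get(bid, 0))
        total += d
        if inside[i].any():
            covered += d
    return covered / total if total > 0 else math.nan
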