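"""Hardship index, terciles, tract aggregation and equity summaries.

The hardship index condenses six tract-level socio-economic components —
crowded housing, poverty, unemployment, low education, dependents and
per-capita income — into one 0–100 score: each component is min-max
scaled across tracts, income is inverted (richer tracts are less
hardshipped), and the six scaled values are averaged. Tracts are then
split into low/medium/high terciles of (near-)equal size, block access
measures are averaged to tracts, and each tract is cross-classified by
its need (hardship tercile) and its funded access (spending tercile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .access import BlockAccess
from .errors import InvalidInputError
from .types import HARDSHIP_COMPONENTS

TERCILE_LABELS = ("low", "medium", "high")
SPENDING_LABELS = ("lower", "medium", "higher")


@dataclass(frozen=True)
class HardshipScore:
    tract_id: str
    index: float
    tercile: str


@dataclass
class TractAccess:
    """Access measures averaged over one tract's blocks."""

    tract_id: str
    mean_a_2sfca: float
    mean_nearest_minutes: float | None
    mean_n_within: float
    percent_with_access: float
    n_blocks: int
    n_unreachable_blocks: int = 0
    spending_tercile: str | None = None


def hardship_index(
    components: Mapping[str, Mapping[str, float]] | pd.DataFrame,
) -> dict[str, float]:
    """0–100 hardship index per tract.

    ``components`` maps tract id to the six named components (or is a
    DataFrame indexed by tract with those columns). A component constant
    across all tracts carries no ranking information and contributes 0
    after scaling (with a warning).
    """
    df = (
        components.copy()
        if isinstance(components, pd.DataFrame)
        else pd.DataFrame.from_dict(dict(components), orient="index")
    )
    missing = [c for c in HARDSHIP_COMPONENTS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"missing hardship components: {missing}")
    scaled = pd.DataFrame(index=df.index, dtype=float)
    for c in HARDSHIP_COMPONENTS:
        col = df[c].astype(float)
        span = col.max() - col.min()
        if span == 0:
            warnings.warn(
                f"hardship component {c!r} is constant across tracts; "
                "it contributes 0 to the index",
                stacklevel=2,
            )
            scaled[c] = 0.0
            continue
        s = 100.0 * (col - col.min()) / span
        scaled[c] = 100.0 - s if c == "per_capita_income" else s
    index = scaled[list(HARDSHIP_COMPONENTS)].mean(axis=1)
    return {str(t): float(v) for t, v in index.items()}


def tercile_classify(
    values: Mapping[str, float],
    labels: Sequence[str] = TERCILE_LABELS,
) -> dict[str, str]:
    """Rank-based split into three groups of (near-)equal size.

    Group sizes differ by at most one, remainders filling the lower
    groups first; ties are broken by the stable insertion order of
    ``values``. Invariant under any strictly monotone transform of the
    values.
    """
    if len(labels) != 3:
        raise InvalidInputError("exactly three labels are required")
    ids = list(values)
    n = len(ids)
    if n < 3:
        raise InvalidInputError(f"need at least 3 units to form terciles, got {n}")
    order = sorted(range(n), key=lambda i: (values[ids[i]], i))
    base, rem = divmod(n, 3)
    sizes = [base + (1 if k < rem else 0) for k in range(3)]
    out: dict[str, str] = {}
    pos = 0
    for label, size in zip(labels, sizes):
        for i in order[pos : pos + size]:
            out[ids[i]] = label
        pos += size
    return out


def hardship_scores(
    components: Mapping[str, Mapping[str, float]] | pd.DataFrame,
) -> list[HardshipScore]:
    """Convenience: index plus tercile per tract."""
    idx = hardship_index(components)
    terc = tercile_classify(idx)
    return [HardshipScore(t, idx[t], terc[t]) for t in idx]


def aggregate_to_tract(
    block_access: Sequence[BlockAccess],
    block_to_tract: Mapping[str, str],
    weighting: str = "unweighted",
    block_populations: Mapping[str, int] | None = None,
) -> list[TractAccess]:
    """Average block measures to the tract level.

    ``weighting`` is ``unweighted`` (plain mean over blocks) or
    ``population`` (blocks weighted by population; requires
    ``block_populations``). Blocks that can reach no site are excluded
    from the nearest-minutes mean and counted in
    ``n_unreachable_blocks``. ``percent_with_access`` is always the
    population share of the tract with >= 1 site within the threshold
    (count share when populations are absent).
    """
    if weighting not in ("unweighted", "population"):
        raise InvalidInputError("weighting must be 'unweighted' or 'population'")
    if weighting == "population" and block_populations is None:
        raise InvalidInputError("population weighting requires block_populations")

    by_tract: dict[str, list[BlockAccess]] = {}
    for ba in block_access:
        tid = block_to_tract.get(ba.block_id)
        if tid is None:
            raise InvalidInputError(f"block {ba.block_id} has no tract")
        by_tract.setdefault(tid, []).append(ba)

    def _w(ba: BlockAccess) -> float:
        if weighting == "unweighted":
            return 1.0
        return float(block_populations.get(ba.block_id, 0))

    out = []
    for tid in sorted(by_tract):
        blocks = by_tract[tid]
        w = np.array([_w(b) for b in blocks])
        if w.sum() == 0:  # zero-population tract under population weighting
            w = np.ones(len(blocks))
        w = w / w.sum()
        a = float(np.dot(w, [b.a_2sfca for b in blocks]))
        nw = float(np.dot(w, [b.n_within for b in blocks]))
        reach = [b for b in blocks if b.nearest_minutes is not None]
        if reach:
            wr = np.array([_w(b) for b in reach])
            wr = wr / wr.sum() if wr.sum() > 0 else np.ones(len(reach)) / len(reach)
            nearest = float(np.dot(wr, [b.nearest_minutes for b in reach]))
        else:
            nearest = None
        if block_populations is not None:
            pops = np.array([float(block_populations.get(b.block_id, 0)) for b in blocks])
            total = pops.sum()
            covered = pops[[b.n_within > 0 for b in blocks]].sum()
            pct = float(covered / total) if total > 0 else float("nan")
        else:
            pct = float(np.mean([b.n_within > 0 for b in blocks]))
        out.append(
            TractAccess(
                tract_id=tid, mean_a_2sfca=a, mean_nearest_minutes=nearest,
                mean_n_within=nw, percent_with_access=pct, n_blocks=len(blocks),
                n_unreachable_blocks=len(blocks) - len(reach),
            )
        )
    return out


def assign_spending_terciles(tract_access: Sequence[TractAccess]) -> None:
    """Label each tract lower/medium/higher by its mean funded access."""
    labels = tercile_classify(
        {t.tract_id: t.mean_a_2sfca for t in tract_access}, labels=SPENDING_LABELS
    )
    for t in tract_access:
        t.spending_tercile = labels[t.tract_id]


def group_summary(
    tract_access: Sequence[TractAccess],
    hardship: Sequence[HardshipScore] | Mapping[str, str],
    area_funding: Mapping[str, float] | None = None,
    tract_populations: Mapping[str, int] | None = None,
    program_type: str = "ALL",
) -> pd.DataFrame:
    """Per-hardship-group summary of access measures and funding.

    Returns a DataFrame indexed by hardship tercile with, per access
    measure, the mean, median and quartiles over the group's tracts, plus
    — when ``area_funding`` (tract → dollars) is supplied — the group's
    funding share in percent (summing to 100) and dollars per capita.
    """
    terc = (
        {h.tract_id: h.tercile for h in hardship}
        if not isinstance(hardship, Mapping)
        else dict(hardship)
    )
    unlabeled = [t.tract_id for t in tract_access if t.tract_id not in terc]
    if unlabeled:
        raise InvalidInputError(f"tracts without hardship tercile: {unlabeled[:5]}")

    rows = []
    metrics = {
        "a_2sfca": lambda t: t.mean_a_2sfca,
        "nearest_minutes": lambda t: t.mean_nearest_minutes,
        "n_within": lambda t: t.mean_n_within,
        "percent_with_access": lambda t: t.percent_with_access,
    }
    grand_total = sum(area_funding.values()) if area_funding else 0.0
    for group in TERCILE_LABELS:
        tracts = [t for t in tract_access if terc[t.tract_id] == group]
        row: dict[str, float | str | int] = {
            "group": group, "program_type": program_type, "n_tracts": len(tracts)
        }
        for name, get in metrics.items():
            vals = [get(t) for t in tracts if get(t) is not None]
            vals = [v for v in vals if not (isinstance(v, float) and np.isnan(v))]
            if vals:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                row.update({f"{name}_mean": float(np.mean(vals)),
                            f"{name}_median": float(med),
                            f"{name}_q1": float(q1), f"{name}_q3": float(q3)})
            else:
                row.update({f"{name}_mean": np.nan, f"{name}_median": np.nan,
                            f"{name}_q1": np.nan, f"{name}_q3": np.nan})
        if area_funding is not None:
            dollars = sum(
                area_funding.get(t.tract_id, 0.0) for t in tracts
            )
            row["dollars"] = dollars
            row["funding_share_pct"] = (
                100.0 * dollars / grand_total if grand_total > 0 else 0.0
            )
            if tract_populations is not None:
                pop = sum(tract_populations.get(t.tract_id, 0) for t in tracts)
                row["population"] = pop
                row["dollars_per_capita"] = dollars / pop if pop > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def cross_classify(
    hardship_labels: Mapping[str, str],
    spending_labels: Mapping[str, str],
) -> pd.DataFrame:
    """3×3 contingency table: hardship tercile × spending tercile.

    Cell counts sum to the number of tracts; marginals equal the tercile
    sizes.
    """
    if set(hardship_labels) != set(spending_labels):
        raise InvalidInputError("classifications cover different tract sets")
    table = pd.DataFrame(
        0, index=list(TERCILE_LABELS), columns=list(SPENDING_LABELS), dtype=int
    )
    for tid, h in hardship_labels.items():
        table.loc[h, spending_labels[tid]] += 1
    table.index.name = "hardship"
    table.columns.name = "spending"
    return table
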