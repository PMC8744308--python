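"""Walking times over the street network and catchment membership.

Times are shortest-path lengths in meters divided by the walking speed
(default 3 mph = 80.4672 m/min), carried as floating minutes and never
rounded before thresholding. A catchment at threshold ``T`` uses the
*strict* inequality ``t < T``: a pair exactly at the threshold is outside.
Unreachable pairs are represented as ``inf`` with an explicit reachability
mask, never as a large sentinel time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidInputError
from .types import M_PER_MILE, StreetNetwork

DEFAULT_WALK_SPEED_MPH = 3.0
DEFAULT_THRESHOLD_MIN = 30.0


def speed_m_per_min(walk_speed_mph: float) -> float:
    """Convert miles/hour to meters/minute (1 mile = 1609.344 m)."""
    if walk_speed_mph <= 0:
        raise InvalidInputError("walking speed must be > 0")
    return walk_speed_mph * M_PER_MILE / 60.0


@dataclass(frozen=True)
class CatchmentThreshold:
    """Walkshed definition: minutes of walking at a given speed."""

    T: float = DEFAULT_THRESHOLD_MIN
    walk_speed_mph: float = DEFAULT_WALK_SPEED_MPH

    def __post_init__(self) -> None:
        if self.T <= 0 or self.walk_speed_mph <= 0:
            raise InvalidInputError("threshold and walking speed must be > 0")


def snap_to_node(x_m: float, y_m: float, network: StreetNetwork) -> Hashable:
    """Nearest network node by Euclidean distance; ties go to the smallest id."""
    nodes = network.nodes()
    if not nodes:
        raise InvalidInputError("cannot snap to an empty network")
    xy = np.array([network.coords(n) for n in nodes])
    d2 = (xy[:, 0] - x_m) ** 2 + (xy[:, 1] - y_m) ** 2
    # nodes are sorted, so argmin's first hit is the smallest id among ties
    return nodes[int(np.argmin(d2))]


def snap_many(points: Sequence[tuple[float, float]], network: StreetNetwork) -> list:
    """Vectorised nearest-node snapping (KD-tree); same tie rule as snap_to_node."""
    nodes = network.nodes()
    if not nodes:
        raise InvalidInputError("cannot snap to an empty network")
    xy = np.array([network.coords(n) for n in nodes])
    tree = cKDTree(xy)
    dist, idx = tree.query(np.asarray(points, dtype=float))
    out = []
    for (px, py), d, i in zip(points, dist, idx):
        # KD-tree tie-breaking is arbitrary; re-check for equidistant smaller ids
        cand = tree.query_ball_point([px, py], r=float(d) + 1e-9)
        out.append(nodes[min(cand)] if cand else nodes[int(i)])
    return out


def travel_time(
    network: StreetNetwork,
    origin_node: Hashable,
    dest_node: Hashable,
    walk_speed_mph: float = DEFAULT_WALK_SPEED_MPH,
) -> float:
    """Walking minutes along the shortest path; ``inf`` if unreachable."""
    for n in (origin_node, dest_node):
        if not network.has_node(n):
            raise InvalidInputError(f"node {n!r} not in network")
    try:
        meters = nx.shortest_path_length(
            network.graph, origin_node, dest_node, weight="length_m"
        )
    except nx.NetworkXNoPath:
        return math.inf
    return meters / speed_m_per_min(walk_speed_mph)


@dataclass
class TravelTimeMatrix:
    """Origin × destination walking times in minutes.

    ``minutes[i, j]`` is the time from ``origin_ids[i]`` to ``dest_ids[j]``;
    unreachable pairs hold ``inf`` (see :meth:`reachable`).
    """

    origin_ids: list
    dest_ids: list
    minutes: np.ndarray  # shape (n_origins, n_dests), float, inf = unreachable
    walk_speed_mph: float = DEFAULT_WALK_SPEED_MPH

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=float)
        if self.minutes.shape != (len(self.origin_ids), len(self.dest_ids)):
            raise InvalidInputError("matrix shape does not match id lists")
        if np.any(self.minutes < 0):
            raise InvalidInputError("negative travel time")

    @property
    def reachable(self) -> np.ndarray:
        return np.isfinite(self.minutes)

    def row(self, origin_id) -> np.ndarray:
        return self.minutes[self.origin_ids.index(origin_id)]

    def within(self, T: float) -> np.ndarray:
        """Boolean catchment indicator I(t < T); unreachable pairs are False."""
        if T <= 0:
            raise InvalidInputError("threshold T must be > 0")
        return self.minutes < T


def travel_time_matrix(
    network: StreetNetwork,
    origins: Mapping[Hashable, Hashable] | Sequence[Hashable],
    dests: Mapping[Hashable, Hashable] | Sequence[Hashable],
    walk_speed_mph: float = DEFAULT_WALK_SPEED_MPH,
) -> TravelTimeMatrix:
    """All origin→destination walking times.

    ``origins`` / ``dests`` are either sequences of node ids (the ids then
    *are* the nodes) or mappings id → node id, so several blocks may share
    one street node. One single-source Dijkstra sweep is run per *distinct*
    origin node, not per pair.
    """
    o_items = list(origins.items()) if isinstance(origins, Mapping) else [(n, n) for n in origins]
    d_items = list(dests.items()) if isinstance(dests, Mapping) else [(n, n) for n in dests]
    for _, node in o_items + d_items:
        if not network.has_node(node):
            raise InvalidInputError(f"node {node!r} not in network")
    mpm = speed_m_per_min(walk_speed_mph)

    dest_nodes = [node for _, node in d_items]
    minutes = np.full((len(o_items), len(d_items)), math.inf)
    by_node: dict[Hashable, list[int]] = {}
    for i, (_, node) in enumerate(o_items):
        by_node.setdefault(node, []).append(i)
    for node, rows in by_node.items():
        dist = nx.single_source_dijkstra_path_length(
            network.graph, node, weight="length_m"
        )
        times = np.array([dist.get(dn, math.inf) for dn in dest_nodes]) / mpm
        for i in rows:
            minutes[i] = times
    return TravelTimeMatrix(
        origin_ids=[oid for oid, _ in o_items],
        dest_ids=[did for did, _ in d_items],
        minutes=minutes,
        walk_speed_mph=walk_speed_mph,
    )


def catchment_members(
    matrix: TravelTimeMatrix, T: float
) -> tuple[dict[Hashable, set], dict[Hashable, set]]:
    """Catchment membership at threshold ``T`` (strict ``t < T``).

    Returns ``(by_dest, by_origin)``: for each destination the set of
    origins inside its catchment, and for each origin the set of
    destinations within reach.
    """
    inside = matrix.within(T)
    by_dest = {
        did: {matrix.origin_ids[i] for i in np.nonzero(inside[:, j])[0]}
        for j, did in enumerate(matrix.dest_ids)
    }
    by_origin = {
        oid: {matrix.dest_ids[j] for j in np.nonzero(inside[i, :])[0]}
        for i, oid in enumerate(matrix.origin_ids)
    }
    return by_dest, by_origin
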