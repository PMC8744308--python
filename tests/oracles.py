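"""Independent reference implementations used only to check the package.

These deliberately avoid the library-under-test's code paths (and
networkx's shortest-path routines): a plain heapq Dijkstra and a direct
transcription of the two 2SFCA formulas evaluated pair by pair.
"""

from __future__ import annotations

import heapq
import math


def dijkstra_minutes(graph, origin, dest, m_per_min: float) -> float:
    """Single-pair shortest path by textbook Dijkstra; inf if unreachable.

    ``graph`` is a networkx graph used only as an adjacency container.
    """
    dist = {origin: 0.0}
    seen = set()
    heap = [(0.0, origin)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in seen:
            continue
        if u == dest:
            return d / m_per_min
        seen.add(u)
        for v, attrs in graph[u].items():
            nd = d + attrs["length_m"]
            if v not in seen and nd < dist.get(v, math.inf):
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return math.inf


def bfs_connected(graph) -> bool:
    """Connectivity by explicit traversal (no networkx helper)."""
    nodes = list(graph.nodes)
    if not nodes:
        return False
    seen = {nodes[0]}
    stack = [nodes[0]]
    while stack:
        u = stack.pop()
        for v in graph[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == len(nodes)


def two_sfca_bruteforce(times, supply, demand, T):
    """Direct evaluation of the two 2SFCA steps on dense inputs.

    ``times[i][j]`` minutes from block i to site j (inf = unreachable);
    returns (R per site, A per block) using the strict indicator t < T.
    """
    n_blocks = len(times)
    n_sites = len(supply)
    R = []
    for j in range(n_sites):
        dem = sum(demand[i] for i in range(n_blocks) if times[i][j] < T)
        R.append(supply[j] / dem if dem > 0 else 0.0)
    A = [
        sum(R[j] for j in range(n_sites) if times[i][j] < T)
        for i in range(n_blocks)
    ]
    return R, A
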