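"""Independent oracles used by the test suite.

These deliberately avoid the code paths (and the max-flow library) they
check: the flow oracle is exhaustive enumeration over integer allocations
via dynamic programming, and the merge oracle is connected components on an
explicit gap graph.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable, Sequence


def max_flow_by_enumeration(
    sr_caps: Sequence[int],
    se_caps: Sequence[int],
    edges: Iterable[tuple[int, int]],
) -> int:
    """Maximum total assignment over all integer allocations x[i,j] >= 0 with
    sum_j x[i,j] <= sr_caps[i], sum_i x[i,j] <= se_caps[j], and x[i,j] = 0
    off ``edges``.  Exhaustive DP over self-reports with remaining
    sensor-event capacities as state."""
    edge_set = set(edges)
    allowed = [
        tuple(j for j in range(len(se_caps)) if (i, j) in edge_set)
        for i in range(len(sr_caps))
    ]

    def allocations(budget: int, js: tuple[int, ...], caps: tuple[int, ...]):
        """All ways to split at most ``budget`` units over ``js``."""
        if not js:
            yield (), caps
            return
        j, rest = js[0], js[1:]
        for x in range(min(budget, caps[j]) + 1):
            new_caps = caps[:j] + (caps[j] - x,) + caps[j + 1:]
            for tail, final in allocations(budget - x, rest, new_caps):
                yield (x,) + tail, final

    @lru_cache(maxsize=None)
    def best(i: int, caps: tuple[int, ...]) -> int:
        if i == len(sr_caps):
            return 0
        result = 0
        for alloc, remaining in allocations(sr_caps[i], allowed[i], caps):
            result = max(result, sum(alloc) + best(i + 1, remaining))
        return result

    try:
        return best(0, tuple(int(c) for c in se_caps))
    finally:
        best.cache_clear()


def merge_by_connected_components(
    intervals: Sequence[tuple[int, int]], tau: int
) -> list[tuple[int, int]]:
    """Partition intervals by transitive closure of "gap <= tau" using an
    explicit graph, returning merged spans sorted by start."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(intervals)))
    for a in range(len(intervals)):
        for b in range(a + 1, len(intervals)):
            (s1, e1), (s2, e2) = intervals[a], intervals[b]
            gap = max(0, max(s1, s2) - min(e1, e2))
            if gap <= tau:
                g.add_edge(a, b)
    spans = []
    for comp in nx.connected_components(g):
        spans.append((min(intervals[i][0] for i in comp),
                      max(intervals[i][1] for i in comp)))
    return sorted(spans)
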