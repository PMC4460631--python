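"""Small brute-force reference implementations, independent of the package.

Everything here is deliberately naive (quadratic DP, exhaustive
enumeration) so it can serve as ground truth for the optimised code paths
in the package.
"""

import numpy as np


def edit_distance_dp(a: str, b: str) -> int:
    """Plain quadratic Levenshtein DP (row-vectorised, no libraries)."""
    prev = np.arange(len(b) + 1)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    for ch in a.encode():
        cur = np.empty_like(prev)
        cur[0] = prev[0] + 1
        sub = prev[:-1] + (arr_b != ch)
        # cur[j] = min(prev[j] + 1, sub[j-1], cur[j-1] + 1); the last term
        # needs a sequential pass
        cur[1:] = np.minimum(prev[1:] + 1, sub)
        cur = np.minimum.accumulate(
            cur + np.arange(len(cur), 0, -1)) - np.arange(len(cur), 0, -1)
        prev = cur
    return int(prev[-1])


def max_disjoint_hits(positions, k: int) -> int:
    """DP over sorted hit positions: most non-overlapping k-length intervals."""
    positions = sorted(positions)
    best = [0] * (len(positions) + 1)
    for i, p in enumerate(positions):
        take = 1
        for j in range(i - 1, -1, -1):
            if positions[j] + k <= p:
                take = best[j + 1] + 1
                break
        best[i + 1] = max(best[i], take)
    return best[-1]


def n50_sort_scan(lengths) -> int:
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc * 2 >= total:
            return L
    raise ValueError("empty input")


def best_simple_path_weight(weights, edges, source, sink):
    """Exhaustive max-vertex-weight simple path via networkx enumeration."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(weights)
    g.add_edges_from(edges)
    best = None
    if source == sink:
        return weights[source]
    for path in nx.all_simple_paths(g, source, sink):
        w = sum(weights[v] for v in path)
        if best is None or w > best:
            best = w
    return best
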