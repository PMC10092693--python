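"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (python sets, BFS, O(n²) scans) and
shares no code with the package's implementations, so agreement between the
two is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_NBRS = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def voxel_graph_summary(grid: np.ndarray, spacing_zyx: tuple[float, float, float]) -> dict:
    """Brute-force skeleton-graph summary from a voxel grid.

    Re-derives, with plain BFS over python sets, the same conventions the
    package defines for skeleton graphs: 26-connectivity; node voxels are
    skeleton voxels with a neighbour count other than 2; mutually adjacent
    node voxels merge into one node; maximal 2-neighbour chains are edges
    (the two terminal node voxels included in the length); directly adjacent
    node clusters contribute one edge per cluster pair; leftover pure cycles
    carry a self-loop on a synthetic anchor.
    """
    dz, dy, dx = spacing_zyx
    vox = {tuple(v) for v in np.argwhere(grid)}

    def nbrs(v):
        return [w for d in _NBRS if (w := (v[0] + d[0], v[1] + d[1], v[2] + d[2])) in vox]

    ncount = {v: len(nbrs(v)) for v in vox}

    # connected components of the whole skeleton
    n_components = 0
    seen = set()
    for v in sorted(vox):
        if v in seen:
            continue
        n_components += 1
        stack = [v]
        seen.add(v)
        while stack:
            cur = stack.pop()
            for w in nbrs(cur):
                if w not in seen:
                    seen.add(w)
                    stack.append(w)

    # node clusters
    node_vox = {v for v in vox if ncount[v] != 2}
    cluster_of: dict[tuple, int] = {}
    n_clusters = 0
    for v in sorted(node_vox):
        if v in cluster_of:
            continue
        cid = n_clusters
        n_clusters += 1
        stack = [v]
        cluster_of[v] = cid
        while stack:
            cur = stack.pop()
            for w in nbrs(cur):
                if w in node_vox and w not in cluster_of:
                    cluster_of[w] = cid
                    stack.append(w)

    def step_len(a, b):
        return math.sqrt(
            ((a[0] - b[0]) * dz) ** 2 + ((a[1] - b[1]) * dy) ** 2 + ((a[2] - b[2]) * dx) ** 2
        )

    # trace chains from node voxels
    edges = []  # (cluster_a, cluster_b, length)
    visited = set()
    for v in sorted(node_vox):
        for w in sorted(nbrs(v)):
            if w in node_vox or w in visited:
                continue
            length = step_len(v, w)
            visited.add(w)
            prev, cur = v, w
            while True:
                nxt = None
                for cand in sorted(nbrs(cur)):
                    if cand != prev:
                        nxt = cand
                        break
                if nxt is None:
                    end = None
                    break
                length += step_len(cur, nxt)
                if nxt in node_vox:
                    end = cluster_of[nxt]
                    break
                visited.add(nxt)
                prev, cur = cur, nxt
            if end is not None:
                edges.append((cluster_of[v], end, length))

    # direct cluster-cluster adjacency: one edge per cluster pair
    adj_pairs = set()
    for v in sorted(node_vox):
        for w in sorted(nbrs(v)):
            if w in node_vox and cluster_of[w] != cluster_of[v]:
                pair = tuple(sorted((cluster_of[v], cluster_of[w])))
                if pair not in adj_pairs:
                    adj_pairs.add(pair)
                    edges.append((pair[0], pair[1], step_len(v, w)))

    # leftover pure cycles
    n_anchors = 0
    leftovers = sorted(v for v in vox if v not in node_vox and v not in visited)
    cycled = set()
    for start in leftovers:
        if start in cycled:
            continue
        n_anchors += 1
        length = 0.0
        path = [start]
        cycled.add(start)
        prev, cur = None, start
        while True:
            nxt = None
            for cand in sorted(nbrs(cur)):
                if cand != prev and ((cand == start and len(path) > 2) or cand not in cycled):
                    nxt = cand
                    break
            if nxt is None or nxt == start:
                if nxt == start:
                    length += step_len(cur, start)
                break
            length += step_len(cur, nxt)
            path.append(nxt)
            cycled.add(nxt)
            prev, cur = cur, nxt
        edges.append((-n_anchors, -n_anchors, length))

    # per-cluster degree: number of edge endpoints incident
    degree = {c: 0 for c in range(n_clusters)}
    for a, b, _ in edges:
        for c in (a, b):
            if c >= 0:
                degree[c] += 1
    free_ends = sum(1 for c, d in degree.items() if d == 1)
    junction3 = sum(1 for c, d in degree.items() if d == 3)
    junction4 = sum(1 for c, d in degree.items() if d == 4)

    return {
        "n_components": n_components,
        "n_nodes": n_clusters,
        "n_edges": len(edges),
        "free_ends": free_ends,
        "junction3": junction3,
        "junction4": junction4,
        "total_length": sum(e[2] for e in edges),
    }


def graph_metrics_bruteforce(graph) -> dict:
    """Recompute network metrics from raw node/edge lists with naive loops."""
    g = graph.g
    nodes = list(g.nodes(data=True))
    edges = list(g.edges(keys=True, data=True))
    total = 0.0
    for _, _, _, d in edges:
        pts = np.asarray(d["polyline"])
        for i in range(len(pts) - 1):
            total += float(np.linalg.norm(pts[i + 1] - pts[i]))
    # union-find components
    parent = {n: n for n, _ in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v, _, _ in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comp_len: dict = {}
    for u, v, _, d in edges:
        comp_len[find(u)] = comp_len.get(find(u), 0.0) + d["length_um"]
    roots = {find(n) for n, _ in nodes}
    degree = {n: 0 for n, _ in nodes}
    for u, v, _, _ in edges:
        degree[u] += 1
        degree[v] += 1  # self-loop counts twice via both increments
    anchors = {n for n, d in nodes if d["kind"] == "cycle_anchor"}
    free_ends = sum(1 for n, d in degree.items() if d == 1 and n not in anchors)
    j3 = sum(1 for n, d in degree.items() if d == 3 and n not in anchors)
    j4 = sum(1 for n, d in degree.items() if d == 4 and n not in anchors)
    jh = sum(1 for n, d in degree.items() if d >= 5 and n not in anchors)
    n_real = sum(1 for n, _ in nodes if n not in anchors)
    n_all = len(nodes)
    phi = max(comp_len.values()) / total if total > 0 and comp_len else math.nan
    return {
        "total_length_um": total,
        "n_components": len(roots),
        "n_nodes": n_real,
        "n_edges": len(edges),
        "free_ends": free_ends,
        "junction3": j3,
        "junction4": j4,
        "junction_higher": jh,
        "avg_degree": sum(degree.values()) / n_all if n_all else math.nan,
        "phi": phi,
        "avg_edge_length_um": total / len(edges) if edges else math.nan,
    }
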