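"""Voxel skeletons and spatial skeleton graphs.

A binary mitochondrial mask is thinned to a one-voxel-wide
:class:`VoxelSkeleton` and converted into a :class:`SkeletonGraph`: a spatial
multigraph whose nodes are tubule endpoints (degree 1) and junctions
(degree >= 3) and whose edges are the tubules between them, carried as
polylines in micrometre coordinates with metric lengths.  This graph is the
substrate for all network metrics (total length, PHI, average degree, ...).

Conventions
-----------
* 26-connectivity throughout (neighbourhoods, components, node detection) —
  the standard for curvilinear 3D skeletons; anything less breaks diagonal
  runs.
* Node positions and polylines are (x, y, z) µm; voxel index ``(iz, iy, ix)``
  maps to ``(ix*dx, iy*dy, iz*dz)``.
* Edge length is measured along the voxel polyline, not as an
  endpoint-to-endpoint chord, matching "total network length" semantics.
* Isolated cycles (rings with no junction) receive one synthetic degree-2
  anchor node carrying a self-loop, so loops contribute length and component
  membership; anchors are excluded from free-end/junction tallies.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .io import ImageStack, VoxelSpacing, resample_isotropic

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelSkeleton",
    "SkeletonGraph",
    "skeletonize",
    "build_graph",
    "prune_spurs",
    "merge_close_junctions",
    "export_skeleton",
    "read_skeleton_vtk",
    "polyline_length",
]

# node kinds
FREE_END = "free_end"
JUNCTION = "junction"
CYCLE_ANCHOR = "cycle_anchor"
PASSTHROUGH = "passthrough"  # degree-2 non-anchor; only in constructed graphs
ISOLATED = "isolated"

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

_OFFSETS26 = sorted(
    (dz, dy, dx)
    for dz, dy, dx in itertools.product((-1, 0, 1), repeat=3)
    if (dz, dy, dx) != (0, 0, 0)
)


def polyline_length(points: np.ndarray) -> float:
    """Sum of Euclidean distances of consecutive polyline points (µm)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())


@dataclass
class VoxelSkeleton:
    """A 1-voxel-wide boolean curve grid with its voxel spacing."""

    grid: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("skeleton grid must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


class SkeletonGraph:
    """Spatial multigraph of skeleton nodes and tubule edges.

    Thin wrapper around :class:`networkx.MultiGraph`.  Node attributes:
    ``pos`` ((x, y, z) µm), ``kind``, optional ``cell``.  Edge attributes:
    ``polyline`` ((n, 3) µm array, oriented u -> v), ``length_um``,
    optional ``cell``.
    """

    def __init__(self) -> None:
        self.g = nx.MultiGraph()
        self._next_node = 0

    # -- construction -----------------------------------------------------
    def add_node(self, pos, kind: str = FREE_END, cell: int | None = None) -> int:
        nid = self._next_node
        self._next_node += 1
        self.g.add_node(nid, pos=np.asarray(pos, dtype=float), kind=kind, cell=cell)
        return nid

    def add_edge(self, u: int, v: int, polyline, cell: int | None = None) -> tuple:
        pts = np.asarray(polyline, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValueError("polyline must be an (n>=2, 3) array")
        length = polyline_length(pts)
        if length <= 0:
            raise ValueError("edge length must be > 0")
        key = self.g.add_edge(u, v, polyline=pts, length_um=length, cell=cell)
        return (u, v, key)

    def refresh_kinds(self) -> None:
        """Set node kinds from degree (anchors keep their flag)."""
        for n, d in self.g.nodes(data=True):
            if d["kind"] == CYCLE_ANCHOR:
                continue
            deg = self.g.degree(n)
            if deg == 0:
                d["kind"] = ISOLATED
            elif deg == 1:
                d["kind"] = FREE_END
            elif deg == 2:
                d["kind"] = PASSTHROUGH
            else:
                d["kind"] = JUNCTION

    def contract_node(self, n: int) -> None:
        """Remove a degree-2 node by merging its two incident edges.

        Used when fragmentation drops a junction to degree 2.  A node whose
        degree-2 comes from a single self-loop is kept as a cycle anchor.
        """
        edges = list(self.g.edges(n, keys=True, data=True))
        if self.g.degree(n) != 2:
            raise ValueError(f"node {n} has degree {self.g.degree(n)}, not 2")
        if len(edges) == 1:  # self-loop: pure cycle, keep as anchor
            self.g.nodes[n]["kind"] = CYCLE_ANCHOR
            return
        (u1, v1, k1, d1), (u2, v2, k2, d2) = edges
        o1 = v1 if u1 == n else u1
        o2 = v2 if u2 == n else u2
        pos = self.g.nodes[n]["pos"]
        # orient geometrically: multigraph edge views do not preserve the
        # insertion orientation of (u, v)
        p1 = d1["polyline"]
        if np.linalg.norm(p1[0] - pos) < np.linalg.norm(p1[-1] - pos):
            p1 = p1[::-1]  # ends at n
        p2 = d2["polyline"]
        if np.linalg.norm(p2[-1] - pos) < np.linalg.norm(p2[0] - pos):
            p2 = p2[::-1]  # starts at n
        merged = np.vstack([p1, p2[1:]])
        cell = d1.get("cell")
        self.g.remove_edge(u1, v1, key=k1)
        self.g.remove_edge(u2, v2, key=k2)
        self.g.remove_node(n)
        self.g.add_edge(o1, o2, polyline=merged, length_um=polyline_length(merged), cell=cell)

    def copy(self) -> "SkeletonGraph":
        out = SkeletonGraph()
        out.g = self.g.copy()
        for _, _, d in out.g.edges(data=True):
            d["polyline"] = d["polyline"].copy()
        for _, d in out.g.nodes(data=True):
            d["pos"] = d["pos"].copy()
        out._next_node = self._next_node
        return out

    # -- queries ----------------------------------------------------------
    @property
    def n_nodes_total(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def edges(self):
        return self.g.edges(keys=True, data=True)

    def sorted_edges(self):
        """Edges in a deterministic order (for seeded random choices)."""
        return sorted(self.g.edges(keys=True), key=lambda e: (e[0], e[1], e[2]))

    def total_length(self) -> float:
        return float(sum(d["length_um"] for _, _, d in self.g.edges(data=True)))

    def components(self):
        return list(nx.connected_components(self.g))

    def n_components(self) -> int:
        return nx.number_connected_components(self.g)

    def component_lengths(self) -> list[float]:
        out = []
        for comp in self.components():
            sub = self.g.subgraph(comp)
            out.append(float(sum(d["length_um"] for _, _, d in sub.edges(data=True))))
        return out

    def to_json_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "id": int(n),
                    "pos_um": [float(v) for v in d["pos"]],
                    "kind": d["kind"],
                    "cell": d.get("cell"),
                }
                for n, d in sorted(self.g.nodes(data=True))
            ],
            "edges": [
                {
                    "u": int(u),
                    "v": int(v),
                    "key": int(k),
                    "length_um": float(d["length_um"]),
                    "cell": d.get("cell"),
                    "polyline_um": np.asarray(d["polyline"]).round(6).tolist(),
                }
                for u, v, k, d in sorted(
                    self.g.edges(keys=True, data=True), key=lambda e: (e[0], e[1], e[2])
                )
            ],
        }


# ---------------------------------------------------------------------------
# thinning
# ---------------------------------------------------------------------------

def skeletonize(mask) -> VoxelSkeleton:
    """Topology-preserving 3D thinning of a binary mitochondrial mask.

    The mask is resampled to isotropic voxels (thinning on a raw anisotropic
    grid is geometrically meaningless when dz is ~7x dx) and thinned with the
    standard 3D medial-axis algorithm.  The skeleton is returned on that
    isotropic grid with its own isotropic spacing: nearest-neighbour mapping
    back onto a coarse z grid would destroy both thinness and topology, while
    the attached spacing keeps all downstream lengths metric-true.
    """
    grid = np.asarray(mask.grid, dtype=bool)
    spacing = mask.spacing
    if not grid.any():
        return VoxelSkeleton(np.zeros_like(grid), spacing)
    if not spacing.is_isotropic():
        target = min(spacing.zyx)
        zoom = tuple(s / target for s in spacing.zyx)
        grid = ndimage.zoom(grid.astype(np.float32), zoom, order=1, mode="nearest") > 0.5
        spacing = VoxelSpacing(target, target, target)
    thin = _sk_skeletonize(grid)
    return VoxelSkeleton(thin.astype(bool), spacing)


# ---------------------------------------------------------------------------
# graph extraction
# ---------------------------------------------------------------------------

def _neighbour_counts(grid: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3, 3), dtype=np.uint8)
    k[1, 1, 1] = 0
    return ndimage.convolve(grid.astype(np.uint8), k, mode="constant") * grid


def _check_thin(grid: np.ndarray) -> None:
    """Reject grossly non-thin input (any full 2x2x2 block of voxels)."""
    if grid.shape[0] < 2 or grid.shape[1] < 2 or grid.shape[2] < 2:
        return
    block = (
        grid[:-1, :-1, :-1] & grid[1:, :-1, :-1] & grid[:-1, 1:, :-1]
        & grid[:-1, :-1, 1:] & grid[1:, 1:, :-1] & grid[1:, :-1, 1:]
        & grid[:-1, 1:, 1:] & grid[1:, 1:, 1:]
    )
    if block.any():
        raise ValueError(
            "input is not a thin skeleton (solid 2x2x2 block found); run skeletonize first"
        )


def _vox_um(idx, spacing: VoxelSpacing) -> np.ndarray:
    iz, iy, ix = idx
    return np.array([ix * spacing.dx, iy * spacing.dy, iz * spacing.dz])


def build_graph(skel: VoxelSkeleton) -> SkeletonGraph:
    """Convert a thin voxel skeleton into a :class:`SkeletonGraph`.

    Voxels with a 26-neighbour count other than 2 become node voxels;
    mutually adjacent node voxels merge into one node at their centroid
    (thinning routinely emits 2-3 adjacent branch voxels at a true junction).
    Maximal degree-2 chains become edges with µm polylines; isolated cycles
    get a synthetic anchor node with a self-loop.  Chain tracing visits
    voxels in lexicographic (z, y, x) order, so output is reproducible.
    """
    grid = np.asarray(skel.grid, dtype=bool)
    graph = SkeletonGraph()
    if not grid.any():
        return graph
    _check_thin(grid)
    spacing = skel.spacing
    nc = _neighbour_counts(grid)
    node_mask = grid & (nc != 2)

    labels, n_clusters = ndimage.label(node_mask, structure=_STRUCT26)
    node_ids: dict[int, int] = {}
    if n_clusters:
        centroids = ndimage.center_of_mass(node_mask, labels, range(1, n_clusters + 1))
        for lab, c in zip(range(1, n_clusters + 1), centroids):
            node_ids[lab] = graph.add_node(_vox_um(c, spacing))

    vox_set = {tuple(v) for v in np.argwhere(grid)}
    node_vox = sorted(tuple(v) for v in np.argwhere(node_mask))

    def neighbours(v):
        vz, vy, vx = v
        for dz, dy, dx in _OFFSETS26:
            w = (vz + dz, vy + dy, vx + dx)
            if w in vox_set:
                yield w

    visited_chain: set[tuple] = set()
    linked_clusters: set[tuple[int, int]] = set()

    for v in node_vox:
        lab_v = labels[v]
        for w in sorted(neighbours(v)):
            if node_mask[w]:
                lab_w = labels[w]
                if lab_w != lab_v:
                    pair = (min(lab_v, lab_w), max(lab_v, lab_w))
                    if pair not in linked_clusters:
                        linked_clusters.add(pair)
                        poly = np.vstack([_vox_um(v, spacing), _vox_um(w, spacing)])
                        graph.add_edge(node_ids[lab_v], node_ids[lab_w], poly)
                continue
            if w in visited_chain:
                continue
            # trace the degree-2 chain starting at w
            path = [v, w]
            visited_chain.add(w)
            prev, cur = v, w
            while True:
                nbrs = list(neighbours(cur))
                nxt = None
                for cand in sorted(nbrs):
                    if cand != prev:
                        nxt = cand
                        break
                if nxt is None:  # dead end chain voxel (shouldn't happen on nc==2)
                    end_cluster = None
                    break
                path.append(nxt)
                if node_mask[nxt]:
                    end_cluster = labels[nxt]
                    break
                visited_chain.add(nxt)
                prev, cur = cur, nxt
            if end_cluster is None:
                continue
            poly = np.array([_vox_um(p, spacing) for p in path])
            graph.add_edge(node_ids[lab_v], node_ids[end_cluster], poly)

    # isolated cycles: remaining chain voxels, all with nc == 2
    remaining = sorted(t for t in vox_set if not node_mask[t] and t not in visited_chain)
    seen_cycle: set[tuple] = set()
    for start in remaining:
        if start in seen_cycle:
            continue
        anchor = graph.add_node(_vox_um(start, spacing), kind=CYCLE_ANCHOR)
        path = [start]
        seen_cycle.add(start)
        prev, cur = None, start
        while True:
            nxt = None
            for cand in sorted(neighbours(cur)):
                if cand != prev and (cand == start and len(path) > 2 or cand not in seen_cycle):
                    nxt = cand
                    break
            if nxt is None or nxt == start:
                break
            path.append(nxt)
            seen_cycle.add(nxt)
            prev, cur = cur, nxt
        path.append(start)  # close the loop
        poly = np.array([_vox_um(p, spacing) for p in path])
        graph.add_edge(anchor, anchor, poly)

    graph.refresh_kinds()
    # anchors must keep their flag even though refresh saw degree 2
    return graph


def merge_close_junctions(graph: SkeletonGraph, max_len_um: float) -> SkeletonGraph:
    """Collapse junction-junction edges shorter than ``max_len_um``.

    Thinning resolves a 4-way crossing inconsistently as either one X node
    or two Y nodes a voxel or two apart; which one appears flips with
    sub-voxel intensity differences and destabilises node/edge counts.
    Collapsing sub-resolution edges between junctions (default: below the
    optical resolution) canonicalises both to the X form.  The collapsed
    edge's small length is dropped.
    """
    out = graph.copy()
    g = out.g
    changed = True
    while changed:
        changed = False
        for u, v, k in sorted(g.edges(keys=True), key=lambda e: (e[0], e[1], e[2])):
            if not g.has_edge(u, v, k) or u == v:
                continue
            if g.edges[u, v, k]["length_um"] >= max_len_um:
                continue
            if g.degree(u) < 3 or g.degree(v) < 3:
                continue
            g.remove_edge(u, v, key=k)
            for a, b, kk, d in list(g.edges(v, keys=True, data=True)):
                other = b if a == v else a
                if other == v:  # self-loop on v
                    g.add_edge(u, u, **d)
                else:
                    g.add_edge(u, other, **d)
            g.remove_node(v)
            changed = True
    out.refresh_kinds()
    return out


def prune_spurs(graph: SkeletonGraph, min_spur_um: float) -> SkeletonGraph:
    """Remove terminal spur edges shorter than ``min_spur_um``.

    3D thinning emits short side branches at junctions and tube ends that
    are digitization artifacts, not tubules; they destabilise node and edge
    counts between otherwise equivalent images.  A spur is an edge with one
    free end whose other endpoint is a junction; removing it cannot
    disconnect anything.  Degree-2 nodes left behind are contracted, and
    pruning iterates to a fixed point.  Isolated short components are kept —
    discrete fragments are real objects, filtered (if at all) at the mask
    level.
    """
    out = graph.copy()
    g = out.g
    changed = True
    while changed:
        changed = False
        for u, v, k in sorted(g.edges(keys=True), key=lambda e: (e[0], e[1], e[2])):
            if not g.has_edge(u, v, k):
                continue
            d = g.edges[u, v, k]
            if d["length_um"] >= min_spur_um or u == v:
                continue
            du, dv = g.degree(u), g.degree(v)
            leaf, hub = (u, v) if (du == 1 and dv >= 3) else (v, u) if (dv == 1 and du >= 3) else (None, None)
            if leaf is None:
                continue
            g.remove_edge(u, v, key=k)
            g.remove_node(leaf)
            if g.degree(hub) == 2 and g.nodes[hub]["kind"] != CYCLE_ANCHOR:
                out.contract_node(hub)
            changed = True
    out.refresh_kinds()
    return out


# ---------------------------------------------------------------------------
# VTK export
# ---------------------------------------------------------------------------

def export_skeleton(graph: SkeletonGraph, path) -> None:
    """Write the skeleton as legacy ASCII VTK polydata.

    One polyline cell per edge, with the edge length (µm) as a cell scalar —
    loadable by standard 3D viewers for the usual length-coloured skeleton
    rendering.
    """
    edges = sorted(graph.g.edges(keys=True, data=True), key=lambda e: (e[0], e[1], e[2]))
    points: list[np.ndarray] = []
    lines: list[list[int]] = []
    lengths: list[float] = []
    for _, _, _, d in edges:
        pts = np.asarray(d["polyline"], dtype=float)
        base = len(points)
        points.extend(pts)
        lines.append(list(range(base, base + len(pts))))
        lengths.append(float(d["length_um"]))
    out = ["# vtk DataFile Version 3.0", "mitoquant skeleton", "ASCII", "DATASET POLYDATA"]
    out.append(f"POINTS {len(points)} float")
    for p in points:
        out.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    total_ints = sum(len(l) + 1 for l in lines)
    out.append(f"LINES {len(lines)} {total_ints}")
    for l in lines:
        out.append(" ".join(str(i) for i in [len(l), *l]))
    out.append(f"CELL_DATA {len(lines)}")
    out.append("SCALARS length_um float 1")
    out.append("LOOKUP_TABLE default")
    for L in lengths:
        out.append(f"{L:.6f}")
    from pathlib import Path

    Path(path).write_text("\n".join(out) + "\n")


def read_skeleton_vtk(path) -> tuple[np.ndarray, list[list[int]], np.ndarray]:
    """Minimal reader for files written by :func:`export_skeleton`.

    Returns (points (n,3) µm, polylines as point-index lists, per-cell
    lengths).  Intended for round-trip checks, not as a general VTK parser.
    """
    from pathlib import Path

    lines_txt = Path(path).read_text().splitlines()
    i = 0
    points = np.zeros((0, 3))
    polys: list[list[int]] = []
    lengths = np.zeros(0)
    while i < len(lines_txt):
        line = lines_txt[i]
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(t) for t in lines_txt[i].split())
                i += 1
            points = np.array(vals).reshape(n, 3)
            continue
        if line.startswith("LINES"):
            n = int(line.split()[1])
            i += 1
            for _ in range(n):
                ints = [int(t) for t in lines_txt[i].split()]
                polys.append(ints[1 : 1 + ints[0]])
                i += 1
            continue
        if line.startswith("SCALARS length_um"):
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while i < len(lines_txt) and lines_txt[i].strip():
                vals.extend(float(t) for t in lines_txt[i].split())
                i += 1
            lengths = np.array(vals)
            continue
        i += 1
    return points, polys, lengths
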