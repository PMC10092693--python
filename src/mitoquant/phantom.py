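"""Synthetic 3D mitochondrial-network phantoms with exact ground truth.

Every downstream stage of the pipeline (enhancement, segmentation,
skeletonization, graph metrics, cell masking) is validated against phantoms
generated here: curvilinear tubules of known geometry placed peripherally
inside ellipsoidal "cells", rendered with an anisotropic Gaussian PSF and
Poisson-Gaussian noise, optionally with a membrane channel and 1-4 touching
cells.  The generator returns the exact skeleton graph (µm polylines), so
recovered network metrics can be compared against closed-form truth.

Topology modes mimic the biological phenotypes of interest:

* ``filamentous`` — tubules fused into few components via 3-way junctions
  (the healthy, interconnected network);
* ``fragmented`` — disjoint tubules (the stressed phenotype, e.g. after
  ATP-synthase inhibition);
* ``expanded`` — a filamentous network with extra bridging tubules (the
  oxidative-stress phenotype: more length and edges, unchanged node count).

All randomness flows from the single integer ``seed`` of the spec through
``numpy.random.SeedSequence`` spawning: stream 0 drives geometry, stream 1
drives rendering noise; :func:`fragment_network` / :func:`expand_network`
take their own seeds because they model separate interventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import ImageStack, VoxelSpacing
from .skeleton import (
    CYCLE_ANCHOR,
    FREE_END,
    JUNCTION,
    PASSTHROUGH,
    SkeletonGraph,
    VoxelSkeleton,
    polyline_length,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "CellGeometry",
    "GroundTruth",
    "generate_network",
    "fragment_network",
    "expand_network",
    "rasterize",
    "rasterize_skeleton",
    "noise_for_snr",
]

_WALK_STEP_UM = 0.15


@dataclass(frozen=True)
class CellGeometry:
    """Axis-aligned ellipsoid cell: centre and semi-axes in µm (x, y, z)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def scaled(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - np.asarray(self.center)) / np.asarray(self.radii)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return (self.scaled(pts) ** 2).sum(axis=1) <= 1.0

    def mask(self, shape: tuple[int, int, int], spacing: VoxelSpacing) -> np.ndarray:
        """Boolean voxel mask of the cell interior."""
        zz, yy, xx = np.meshgrid(
            np.arange(shape[0]) * spacing.dz,
            np.arange(shape[1]) * spacing.dy,
            np.arange(shape[2]) * spacing.dx,
            indexing="ij",
        )
        cx, cy, cz = self.center
        rx, ry, rz = self.radii
        return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2 <= 1.0

    def surface_points(self, n: int = 4000) -> np.ndarray:
        """Quasi-uniform points on the ellipsoid surface (Fibonacci sphere)."""
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5**0.5) * i
        unit = np.stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
        )
        return unit * np.asarray(self.radii) + np.asarray(self.center)


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters; defaults emulate a single secondary-islet cell.

    Grid and spacing follow the acquisition defaults (0.104 µm in-plane,
    0.72 µm z step); tubule radius 0.4 µm sits inside the 0.2-0.5 µm range
    typical of mitochondrial tubules and satisfies the rasterizability bound
    radius >= max(dx, dz)/2.  Peak tubule intensity is normalised to 1, so
    ``background``, ``noise_sd`` and ``photon_scale`` are on that scale; the
    defaults give a peak SNR of roughly 7, typical of a well-exposed
    spinning-disc stack.
    """

    shape: tuple[int, int, int] = (20, 128, 128)
    spacing: VoxelSpacing = field(default_factory=VoxelSpacing)
    n_tubules: int = 12
    tubule_length_um: tuple[float, float] = (2.0, 6.0)
    tubule_radius_um: float = 0.4
    curvature: float = 0.3
    topology: str = "filamentous"
    attach_prob: float = 1.0
    n_cells: int = 1
    cell_radius_um: float = 4.5
    membrane_channel: bool = False
    psf_sigma_um: tuple[float, float] = (0.15, 0.45)  # (lateral, axial)
    background: float = 0.05
    noise_sd: float = 0.08
    photon_scale: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in ("filamentous", "fragmented", "expanded"):
            raise ValueError(f"unknown topology mode {self.topology!r}")
        if self.tubule_radius_um < max(self.spacing.dx, self.spacing.dz) / 2:
            raise ValueError(
                "tubule radius must be >= max(dx, dz)/2 to be rasterizable "
                f"(radius {self.tubule_radius_um}, spacing {self.spacing})"
            )
        lo, hi = self.tubule_length_um
        if not (0 < lo <= hi):
            raise ValueError("tubule length range must be positive")
        if self.n_tubules < 1 or self.n_cells < 1:
            raise ValueError("n_tubules and n_cells must be >= 1")
        if not 0.0 <= self.attach_prob <= 1.0:
            raise ValueError("attach_prob must be in [0, 1]")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical grid extent (x, y, z) in µm."""
        nz, ny, nx = self.shape
        return (
            (nx - 1) * self.spacing.dx,
            (ny - 1) * self.spacing.dy,
            (nz - 1) * self.spacing.dz,
        )


def noise_for_snr(snr: float) -> dict:
    """Noise parameters giving peak SNR ``snr`` for unit-peak tubules.

    The noise variance at peak is split evenly between the Poisson (shot)
    and Gaussian (read) components: sd_read = 1/(snr*sqrt(2)) and
    photon_scale = 2*snr**2.  Use as ``replace(spec, **noise_for_snr(5))``.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    return {"noise_sd": 1.0 / (snr * np.sqrt(2.0)), "photon_scale": 2.0 * snr**2}


@dataclass
class GroundTruth:
    """Exact phantom geometry: skeleton graph, cells, and bookkeeping.

    Graph nodes/edges carry a ``cell`` attribute giving the index of the
    owning cell; every tubule polyline lies inside its cell's ellipsoid.
    """

    graph: SkeletonGraph
    cells: list[CellGeometry]
    spec: PhantomSpec

    def total_length(self, cell: int | None = None) -> float:
        if cell is None:
            return self.graph.total_length()
        return float(
            sum(
                d["length_um"]
                for _, _, d in self.graph.g.edges(data=True)
                if d.get("cell") == cell
            )
        )

    def cell_mask(self, cell: int) -> np.ndarray:
        return self.cells[cell].mask(self.spec.shape, self.spec.spacing)

    def cell_subset(self, cell: int) -> "GroundTruth":
        """Ground truth restricted to one cell (same grid/spec)."""
        g = self.graph.copy()
        drop_edges = [
            (u, v, k)
            for u, v, k, d in g.g.edges(keys=True, data=True)
            if d.get("cell") != cell
        ]
        g.g.remove_edges_from(drop_edges)
        g.g.remove_nodes_from([n for n in list(g.g.nodes) if g.g.degree(n) == 0])
        g.refresh_kinds()
        return GroundTruth(g, self.cells, self.spec)

    def copy(self) -> "GroundTruth":
        return GroundTruth(self.graph.copy(), list(self.cells), self.spec)


# ---------------------------------------------------------------------------
# polyline arc-length helpers
# ---------------------------------------------------------------------------

def _cumlen(pts: np.ndarray) -> np.ndarray:
    steps = np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1))
    return np.concatenate([[0.0], np.cumsum(steps)])


def _point_at(pts: np.ndarray, cl: np.ndarray, s: float) -> np.ndarray:
    return np.array([np.interp(s, cl, pts[:, i]) for i in range(3)])


def _sub_polyline(pts: np.ndarray, cl: np.ndarray, s0: float, s1: float) -> np.ndarray:
    """Polyline restricted to arc-length interval [s0, s1]."""
    keep = (cl > s0) & (cl < s1)
    inner = pts[keep]
    head = _point_at(pts, cl, s0)[None]
    tail = _point_at(pts, cl, s1)[None]
    out = np.vstack([head, inner, tail])
    # drop duplicated points from exact hits
    d = np.sqrt(((out[1:] - out[:-1]) ** 2).sum(axis=1))
    return np.vstack([out[0], out[1:][d > 1e-12]])


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _place_cells(spec: PhantomSpec, rng: np.random.Generator) -> list[CellGeometry]:
    ex, ey, ez = spec.extent_um
    r = spec.cell_radius_um
    rz = min(r, ez / 2 * 0.95)
    cells: list[CellGeometry] = []
    if spec.n_cells == 1:
        cells.append(CellGeometry((ex / 2, ey / 2, ez / 2), (r, r, rz)))
    else:
        # touching chain along x, tangent ellipsoids
        total_w = 2 * r * spec.n_cells
        if total_w > ex:
            raise ValueError(
                f"{spec.n_cells} cells of radius {r} µm do not fit in {ex:.1f} µm grid"
            )
        x0 = ex / 2 - total_w / 2 + r
        for i in range(spec.n_cells):
            cells.append(CellGeometry((x0 + 2 * r * i, ey / 2, ez / 2), (r, r, rz)))
    for c in cells:
        if min(c.radii) <= 2 * spec.tubule_radius_um:
            raise ValueError("cell too small for the requested tubule radius")
    return cells


_BAND = (0.45, 0.74)  # peripheral radial band of the cell, in scaled coords
_CLAMP = 0.78  # hard containment cap; cytoplasmic margin keeps signal in-cell


def _random_walk_tubule(
    rng: np.random.Generator,
    cell: CellGeometry,
    length_um: float,
    curvature: float,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Smooth bounded-curvature random walk inside the cell's peripheral band."""
    radii = np.asarray(cell.radii)
    center = np.asarray(cell.center)
    if start is None:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        s = rng.uniform(*_BAND)
        start = center + u * s * radii
    p = np.asarray(start, dtype=float)
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    if curvature == 0:
        # straight tubule: pick a chord that stays inside the clamp surface
        # (the clamp region is convex, so checking the far end suffices)
        for _ in range(100):
            end = p + length_um * d
            if np.linalg.norm((end - center) / radii) <= _CLAMP:
                break
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
    # coarse control points (smooth at the voxel scale), spline-resampled below
    coarse = 0.6
    n_steps = max(2, int(np.ceil(length_um / coarse)))
    step = length_um / n_steps
    pts = [p.copy()]
    for _ in range(n_steps):
        if curvature > 0:
            d = d + curvature * rng.normal(size=3)
            u = (p - center) / radii
            s = np.linalg.norm(u)
            if s > _BAND[1]:
                d = d - u / max(s, 1e-9) * 2.0 * (s - _BAND[1]) / (1 - _BAND[1])
            elif s < _BAND[0] and s > 1e-6:
                d = d + u / s * 2.0 * (_BAND[0] - s) / _BAND[0]
            d /= np.linalg.norm(d)
        p = p + step * d
        u = (p - center) / radii
        s = np.linalg.norm(u)
        if s > _CLAMP:  # hard clamp guarantees containment
            p = center + u / s * _CLAMP * radii
        pts.append(p.copy())
    pts = np.array(pts)
    if len(pts) > 2:
        from scipy.interpolate import CubicSpline

        cl = _cumlen(pts)
        # drop any zero-length segments before splining
        keep = np.concatenate([[True], np.diff(cl) > 1e-9])
        cl, pts = cl[keep], pts[keep]
        if len(pts) > 2:
            cs = CubicSpline(cl, pts, axis=0)
            n_fine = max(2, int(np.ceil(cl[-1] / _WALK_STEP_UM)))
            pts = cs(np.linspace(0, cl[-1], n_fine + 1))
            u = (pts - center) / radii
            s = np.linalg.norm(u, axis=1)
            over = s > _CLAMP
            if over.any():
                pts[over] = center + u[over] / s[over, None] * _CLAMP * radii
    return pts


def generate_network(spec: PhantomSpec) -> GroundTruth:
    """Generate a seeded, reproducible ground-truth network.

    Tubules are smooth random-walk polylines placed in the peripheral band of
    each cell (mitochondria in these cells sit at the cell periphery, which
    is also what makes the multi-cell masking problem hard: adjacent cells'
    mitochondria end up closely apposed).  In filamentous/expanded modes each
    new tubule attaches with probability ``attach_prob`` to an interior point
    of an existing tubule of the same cell, forming a 3-way junction.
    """
    geom_rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed).spawn(2)[0]))
    cells = _place_cells(spec, geom_rng)
    graph = SkeletonGraph()
    attach = spec.attach_prob if spec.topology in ("filamentous", "expanded") else 0.0

    for ci in range(spec.n_cells):
        cell = cells[ci]
        for ti in range(spec.n_tubules):
            length = geom_rng.uniform(*spec.tubule_length_um)
            start = None
            attach_edge = None
            cell_edges = [
                (u, v, k, d)
                for u, v, k, d in sorted(
                    graph.g.edges(keys=True, data=True), key=lambda e: (e[0], e[1], e[2])
                )
                if d.get("cell") == ci and len(d["polyline"]) >= 4
            ]
            if ti > 0 and cell_edges and geom_rng.uniform() < attach:
                attach_edge = cell_edges[geom_rng.integers(len(cell_edges))]
            if attach_edge is not None:
                u, v, k, d = attach_edge
                pts_e = d["polyline"]
                idx = int(geom_rng.integers(1, len(pts_e) - 1))
                start = pts_e[idx]
                # split the host edge at the junction
                graph.g.remove_edge(u, v, key=k)
                j = graph.add_node(start, kind=JUNCTION, cell=ci)
                graph.add_edge(u, j, pts_e[: idx + 1], cell=ci)
                graph.add_edge(j, v, pts_e[idx:], cell=ci)
            poly = _random_walk_tubule(geom_rng, cell, length, spec.curvature, start=start)
            if attach_edge is not None:
                n_end = graph.add_node(poly[-1], cell=ci)
                graph.add_edge(j, n_end, poly, cell=ci)
            else:
                n0 = graph.add_node(poly[0], cell=ci)
                n1 = graph.add_node(poly[-1], cell=ci)
                graph.add_edge(n0, n1, poly, cell=ci)
    graph.refresh_kinds()
    truth = GroundTruth(graph, cells, spec)
    if spec.topology == "expanded":
        n_bridges = max(1, spec.n_tubules // 3)
        truth = expand_network(truth, n_bridges, seed=spec.seed + 1)
    return truth


# ---------------------------------------------------------------------------
# interventions
# ---------------------------------------------------------------------------

def fragment_network(
    truth: GroundTruth,
    n_cuts: int,
    seed: int,
    cut_length_um: float | None = None,
) -> GroundTruth:
    """Fragment the network by excising short intervals at random positions.

    Cut centres fall uniformly along the arc length of a randomly chosen
    eligible edge.  A cut whose interval reaches a junction-side edge end
    detaches the edge there (the junction loses a tubule — degree-2
    leftovers are contracted away), mirroring real fission at branch points;
    cuts that would nibble a free end are shifted inward so every cut removes
    interior length.  On acyclic networks each cut adds exactly one connected
    component.  Total length decreases by exactly the removed intervals.

    The default cut interval is twice the tubule radius, so segmentation
    blur cannot re-bridge a cut in the rendered image.
    """
    if n_cuts < 0:
        raise ValueError("n_cuts must be >= 0")
    out = truth.copy()
    if n_cuts == 0:
        return out
    h = (cut_length_um if cut_length_um is not None else 2 * truth.spec.tubule_radius_um) / 2
    stub = max(0.05, h / 4)
    rng = np.random.default_rng(seed)
    g = out.graph
    done = 0
    for _ in range(n_cuts):
        eligible = [
            (u, v, k)
            for u, v, k in g.sorted_edges()
            if g.g.edges[u, v, k]["length_um"] > 2 * h + 2 * stub
        ]
        if not eligible:
            break
        u, v, k = eligible[rng.integers(len(eligible))]
        d = g.g.edges[u, v, k]
        pts, cell = d["polyline"], d.get("cell")
        cl = _cumlen(pts)
        L = cl[-1]
        s = rng.uniform(0, L)
        s0, s1 = s - h, s + h
        detach_u = s0 <= 0 and (u != v and g.g.degree(u) >= 3)
        detach_v = s1 >= L and (u != v and g.g.degree(v) >= 3)
        if s0 <= 0 and not detach_u:
            s0, s1 = stub, stub + 2 * h  # shift inward off a free end
        elif s1 >= L and not detach_v:
            s0, s1 = L - stub - 2 * h, L - stub
        g.g.remove_edge(u, v, key=k)
        if s0 <= 0:  # detach at u
            tail = _sub_polyline(pts, cl, s1, L)
            a = g.add_node(tail[0], kind=FREE_END, cell=cell)
            g.add_edge(a, v, tail, cell=cell)
            _tidy_node(g, u)
        elif s1 >= L:  # detach at v
            head = _sub_polyline(pts, cl, 0, s0)
            b = g.add_node(head[-1], kind=FREE_END, cell=cell)
            g.add_edge(u, b, head, cell=cell)
            _tidy_node(g, v)
        else:  # interior cut
            head = _sub_polyline(pts, cl, 0, s0)
            tail = _sub_polyline(pts, cl, s1, L)
            a = g.add_node(head[-1], kind=FREE_END, cell=cell)
            b = g.add_node(tail[0], kind=FREE_END, cell=cell)
            g.add_edge(u, a, head, cell=cell)
            g.add_edge(b, v, tail, cell=cell)
            if u == v and g.g.degree(u) == 2:
                # a cut ring is just a path; the old anchor is redundant
                g.g.nodes[u]["kind"] = PASSTHROUGH
                _tidy_node(g, u)
        done += 1
    if done < n_cuts:
        logger.info("only %d of %d requested cuts were feasible", done, n_cuts)
    g.refresh_kinds()
    return out


def _tidy_node(g: SkeletonGraph, n: int) -> None:
    """After an incidence is removed: contract deg-2, drop isolated nodes."""
    deg = g.g.degree(n)
    if deg == 2 and g.g.nodes[n]["kind"] != CYCLE_ANCHOR:
        g.contract_node(n)
    elif deg == 0:
        g.g.remove_node(n)


def expand_network(truth: GroundTruth, n_bridges: int, seed: int) -> GroundTruth:
    """Add bridging tubules between existing nodes of the same cell.

    Each bridge is a straight tubule between two randomly chosen
    not-yet-adjacent nodes (ellipsoid convexity keeps it inside the cell).
    Total length and edge count increase; the node count is unchanged —
    the expansion phenotype: a longer, more interconnected network without
    new endpoints or branch points.
    """
    if n_bridges < 0:
        raise ValueError("n_bridges must be >= 0")
    out = truth.copy()
    if n_bridges == 0:
        return out
    rng = np.random.default_rng(seed)
    g = out.graph
    for _ in range(n_bridges):
        nodes = sorted(g.g.nodes)
        pairs = [
            (a, b)
            for i, a in enumerate(nodes)
            for b in nodes[i + 1 :]
            if g.g.nodes[a].get("cell") == g.g.nodes[b].get("cell")
            and g.g.nodes[a].get("cell") is not None
            and not g.g.has_edge(a, b)
        ]
        if not pairs:
            raise ValueError("no eligible node pairs for bridging")
        a, b = pairs[rng.integers(len(pairs))]
        pa, pb = g.g.nodes[a]["pos"], g.g.nodes[b]["pos"]
        n_seg = max(2, int(np.ceil(np.linalg.norm(pb - pa) / _WALK_STEP_UM)))
        t = np.linspace(0, 1, n_seg + 1)[:, None]
        poly = pa[None] * (1 - t) + pb[None] * t
        g.add_edge(a, b, poly, cell=g.g.nodes[a].get("cell"))
    g.refresh_kinds()
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _voxel_centers_um(shape, spacing: VoxelSpacing) -> np.ndarray:
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * spacing.dz,
        np.arange(shape[1]) * spacing.dy,
        np.arange(shape[2]) * spacing.dx,
        indexing="ij",
    )
    return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


def _dense_samples(graph: SkeletonGraph, step: float) -> np.ndarray:
    samples = []
    for _, _, d in graph.g.edges(data=True):
        pts = d["polyline"]
        cl = _cumlen(pts)
        n = max(2, int(np.ceil(cl[-1] / step)) + 1)
        s = np.linspace(0, cl[-1], n)
        samples.append(np.stack([np.interp(s, cl, pts[:, i]) for i in range(3)], axis=1))
    if not samples:
        return np.zeros((0, 3))
    return np.vstack(samples)


def rasterize(
    truth: GroundTruth,
    spec: PhantomSpec | None = None,
    noise: bool = True,
    blur: bool = True,
) -> tuple[ImageStack, ImageStack | None]:
    """Render the ground-truth network as a fluorescence z-stack.

    Tubules get a Gaussian cross-section (sigma = radius/2) of the exact
    distance to the polyline, the volume is blurred with the anisotropic
    PSF, peak-normalised to 1, and Poisson (photon) then additive Gaussian
    (read) noise is applied on top of the background level.  Returns the
    mitochondria channel and, if requested by the spec, a membrane channel
    rendering each cell's boundary shell.  Fully seeded and reproducible.
    """
    spec = spec or truth.spec
    noise_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(spec.seed).spawn(2)[1])
    )
    centers = _voxel_centers_um(spec.shape, spec.spacing)
    sigma_r = spec.tubule_radius_um / 2.0
    samples = _dense_samples(truth.graph, step=min(spec.spacing.xyz) / 2)
    signal = np.zeros(spec.shape, dtype=np.float64)
    if len(samples):
        dist, _ = cKDTree(samples).query(centers, workers=-1)
        signal = np.exp(-0.5 * (dist / sigma_r) ** 2).reshape(spec.shape)
    if blur:
        sig_vox = (
            spec.psf_sigma_um[1] / spec.spacing.dz,
            spec.psf_sigma_um[0] / spec.spacing.dy,
            spec.psf_sigma_um[0] / spec.spacing.dx,
        )
        signal = ndimage.gaussian_filter(signal, sig_vox)
    if signal.max() > 0:
        signal = signal / signal.max()
    mito = _apply_noise(signal, spec, noise_rng) if noise else signal
    mito_stack = ImageStack(mito.astype(np.float32), spec.spacing, "mito")

    membrane_stack = None
    if spec.membrane_channel:
        memb = np.zeros(spec.shape, dtype=np.float64)
        sigma_m = 0.3  # membrane shell thickness (µm)
        surf = np.vstack([c.surface_points(6000) for c in truth.cells])
        dist, _ = cKDTree(surf).query(centers, workers=-1)
        memb = np.exp(-0.5 * (dist / sigma_m) ** 2).reshape(spec.shape)
        if blur:
            memb = ndimage.gaussian_filter(memb, sig_vox if blur else 0)
        if memb.max() > 0:
            memb = memb / memb.max()
        memb = _apply_noise(memb, spec, noise_rng) if noise else memb
        membrane_stack = ImageStack(memb.astype(np.float32), spec.spacing, "membrane")
    return mito_stack, membrane_stack


def _apply_noise(signal: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    img = signal + spec.background
    if spec.photon_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * spec.photon_scale) / spec.photon_scale
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0, None)


def rasterize_skeleton(
    truth: GroundTruth,
    spacing: VoxelSpacing | None = None,
    shape: tuple[int, int, int] | None = None,
) -> VoxelSkeleton:
    """Draw the ground-truth polylines as a 1-voxel-wide voxel skeleton.

    Dense curve samples are snapped to voxel indices (index = round(µm /
    spacing)) with consecutive duplicates removed, yielding 26-connected
    voxel curves.  This is the direct voxel-level counterpart of the graph,
    used to validate graph extraction against voxel-adjacency oracles.

    The drawing grid defaults to *isotropic* voxels at the finest spacing
    component: snapping a smooth 3D curve onto a strongly anisotropic grid
    projects long runs into single z planes, which is no longer a thin
    curve.
    """
    if spacing is None:
        t = min(truth.spec.spacing.xyz)
        spacing = VoxelSpacing(t, t, t)
    if shape is None:
        ex, ey, ez = truth.spec.extent_um
        shape = (
            int(np.ceil(ez / spacing.dz)) + 1,
            int(np.ceil(ey / spacing.dy)) + 1,
            int(np.ceil(ex / spacing.dx)) + 1,
        )
    grid = np.zeros(shape, dtype=bool)
    step = 0.4 * min(spacing.xyz)
    for _, _, d in truth.graph.g.edges(data=True):
        pts = d["polyline"]
        cl = _cumlen(pts)
        n = max(2, int(np.ceil(cl[-1] / step)) + 1)
        s = np.linspace(0, cl[-1], n)
        dense = np.stack([np.interp(s, cl, pts[:, i]) for i in range(3)], axis=1)
        idx = np.round(dense / np.asarray(spacing.xyz)).astype(int)[:, ::-1]  # -> (z,y,x)
        idx = np.clip(idx, 0, np.asarray(shape) - 1)
        # 26-connected digital curve: drop duplicates and cut staircase
        # corners (a voxel whose predecessor and successor are themselves
        # adjacent is redundant and would read as a spurious branch)
        chain: list[np.ndarray] = [idx[0]]
        for v in idx[1:]:
            if np.array_equal(v, chain[-1]):
                continue
            if len(chain) >= 2 and np.abs(v - chain[-2]).max() <= 1:
                chain[-1] = v
            else:
                chain.append(v)
        ch = np.array(chain)
        grid[ch[:, 0], ch[:, 1], ch[:, 2]] = True
    return VoxelSkeleton(grid, spacing)
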