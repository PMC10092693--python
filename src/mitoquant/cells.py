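"""Cell segmentation, 3D morphometry and per-cell mitochondria extraction.

Cells are segmented from a membrane channel by edge-preserving smoothing
followed by seeded (marker-controlled) watershed with the membrane signal as
the ridge; labels are then smoothed with a merge-free per-label closing.
Morphometry reports volume, 3D Feret diameter (maximum caliper distance,
anisotropic spacing) and centroid per cell.

For clustered cells, :func:`extract_cell_stack` produces a single-cell
mitochondria stack: voxels inside the cell mask are copied verbatim, and
voxels outside are replaced by Gaussian noise matched to the image
background.  The noise injection matters: a hard zero fill creates a sharp
intensity step at the mask boundary that degrades downstream thresholding
and segmentation, whereas background-like noise makes the masked stack
statistically indistinguishable from a single-cell acquisition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.segmentation import watershed

from .io import ImageStack, VoxelSpacing

logger = logging.getLogger(__name__)

__all__ = [
    "CellLabels",
    "CellMorphology",
    "NoiseModel",
    "smooth_membrane",
    "segment_cells",
    "close_labels",
    "measure_cells",
    "extract_cell_stack",
    "estimate_background_noise",
]


@dataclass
class CellLabels:
    """Integer label grid: 0 = background, k >= 1 = cell k."""

    grid: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("labels must be a 3D integer grid")

    @property
    def ids(self) -> list[int]:
        return [int(v) for v in np.unique(self.grid) if v > 0]


@dataclass
class CellMorphology:
    cell_id: int
    volume_um3: float
    feret_um: float
    centroid_um: tuple[float, float, float]  # (x, y, z)


@dataclass
class NoiseModel:
    """Gaussian background model for mask-external noise injection."""

    mean: float
    sd: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


# ---------------------------------------------------------------------------
# membrane smoothing
# ---------------------------------------------------------------------------

def smooth_membrane(
    stack: ImageStack,
    sigma_radius: int = 2,
    median_radius: int = 1,
    k: float = 2.0,
) -> ImageStack:
    """Edge-preserving sigma filter followed by a median filter.

    The sigma stage replaces each voxel by the mean of the neighbours (within
    a Chebyshev radius) whose intensity lies within ``k`` times the global
    intensity standard deviation of the centre value — smoothing the
    membrane signal without displacing its edges.  The median stage removes
    residual speckle (a single hot voxel cannot survive it).
    """
    if sigma_radius < 1 or median_radius < 1:
        raise ValueError("filter radii must be >= 1 voxel")
    img = stack.voxels.astype(np.float64)
    t = k * img.std()
    r = sigma_radius
    padded = np.pad(img, r, mode="reflect")
    acc = img.copy()  # centre voxel always participates
    cnt = np.ones_like(img)
    nz, ny, nx = img.shape
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if dz == dy == dx == 0:
                    continue
                nb = padded[r + dz : r + dz + nz, r + dy : r + dy + ny, r + dx : r + dx + nx]
                within = np.abs(nb - img) <= t
                acc += np.where(within, nb, 0.0)
                cnt += within
    out = acc / cnt
    out = ndimage.median_filter(out, size=2 * median_radius + 1, mode="reflect")
    np.clip(out, 0, None, out=out)
    return ImageStack(out, stack.spacing, stack.channel_label)


# ---------------------------------------------------------------------------
# cell segmentation
# ---------------------------------------------------------------------------

def segment_cells(membrane: ImageStack, seeds: list[tuple[int, int, int]]) -> CellLabels:
    """Marker-controlled watershed on a (smoothed) membrane channel.

    One label per seed, in seed order; voxels reached first from the image
    border (outside all cells) become background 0.  A seed that lands on a
    membrane ridge is snapped to the darkest voxel within 2 voxels, with a
    warning.
    """
    if not seeds:
        raise ValueError("at least one seed is required")
    img = membrane.voxels.astype(np.float64)
    markers = np.zeros(img.shape, dtype=np.int32)
    ridge_level = img.mean() + img.std()
    for i, seed in enumerate(seeds, start=1):
        z, y, x = (int(v) for v in seed)
        if not (0 <= z < img.shape[0] and 0 <= y < img.shape[1] and 0 <= x < img.shape[2]):
            raise ValueError(f"seed {seed} outside the image")
        if img[z, y, x] > ridge_level:
            lo = np.maximum([z - 2, y - 2, x - 2], 0)
            hi = np.minimum([z + 3, y + 3, x + 3], img.shape)
            win = img[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            off = np.unravel_index(np.argmin(win), win.shape)
            z, y, x = (int(lo[d] + off[d]) for d in range(3))
            logger.warning("seed %s sits on a membrane ridge; snapped to (%d, %d, %d)", seed, z, y, x)
        markers[z, y, x] = i
    bg_label = len(seeds) + 1
    border = np.zeros(img.shape, dtype=bool)
    border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
    markers[border & (markers == 0)] = bg_label
    labels = watershed(img, markers=markers)
    labels[labels == bg_label] = 0
    return CellLabels(labels.astype(np.int32), membrane.spacing)


def close_labels(labels: CellLabels, radius: int = 2) -> CellLabels:
    """Per-label morphological closing with a spacing-aware ellipsoid.

    Fills pinholes and smooths label surfaces.  Labels never merge: a voxel
    claimed by the closing of several labels is resolved to the label whose
    original mask is nearest (physical distance).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    sp = labels.spacing
    rz = max(1, int(round(radius * sp.dx / sp.dz)))
    zz, yy, xx = np.ogrid[-rz : rz + 1, -radius : radius + 1, -radius : radius + 1]
    selem = (zz / rz) ** 2 + (yy / radius) ** 2 + (xx / radius) ** 2 <= 1.0
    ids = labels.ids
    closed = {}
    for lab in ids:
        mask = labels.grid == lab
        closed[lab] = ndimage.binary_closing(mask, structure=selem, iterations=1)
        closed[lab] |= mask  # closing never removes original voxels
    out = np.zeros_like(labels.grid)
    claim_count = np.zeros(labels.grid.shape, dtype=np.int8)
    for lab in ids:
        claim_count += closed[lab]
    contested = claim_count > 1
    for lab in ids:
        out[closed[lab] & ~contested] = lab
    if contested.any():
        dists = np.stack(
            [
                ndimage.distance_transform_edt(labels.grid != lab, sampling=sp.zyx)
                for lab in ids
            ]
        )
        nearest = np.argmin(dists, axis=0)
        for i, lab in enumerate(ids):
            out[contested & (nearest == i)] = lab
    return CellLabels(out, labels.spacing)


# ---------------------------------------------------------------------------
# morphometry
# ---------------------------------------------------------------------------

def _feret(points_um: np.ndarray) -> float:
    """Max pairwise Euclidean distance; exact via convex hull vertices."""
    if len(points_um) == 1:
        return 0.0
    if len(points_um) > 50:
        try:
            hull = ConvexHull(points_um)
            points_um = points_um[hull.vertices]
        except QhullError:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(points_um).max())


def measure_cells(labels: CellLabels, ids: list[int] | None = None) -> list[CellMorphology]:
    """Volume (µm³), 3D Feret diameter (µm) and centroid per labelled cell.

    Volume is voxel count x voxel volume; the Feret diameter is the maximum
    pairwise distance between voxel centres (anisotropic spacing), computed
    over boundary voxels — which is exact, since the maximum is attained on
    the boundary.
    """
    present = labels.ids
    if not present:
        raise ValueError("label grid contains no cells")
    if ids is None:
        ids = present
    sp = labels.spacing
    out = []
    for lab in ids:
        mask = labels.grid == lab
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"label {lab} not present")
        boundary = mask & ~ndimage.binary_erosion(mask)
        idx = np.argwhere(boundary)
        pts = idx[:, ::-1] * np.array(sp.xyz)  # (x, y, z) µm
        cidx = np.argwhere(mask).mean(axis=0)
        centroid = tuple(float(v) for v in cidx[::-1] * np.array(sp.xyz))
        out.append(
            CellMorphology(
                cell_id=int(lab),
                volume_um3=n * sp.voxel_volume,
                feret_um=_feret(pts),
                centroid_um=centroid,
            )
        )
    return out


# ---------------------------------------------------------------------------
# per-cell extraction
# ---------------------------------------------------------------------------

def estimate_background_noise(stack: ImageStack, seed: int = 0) -> NoiseModel:
    """Fit the injection noise model from the stack's own background.

    Uses the voxels between the 1st and 20th intensity percentiles as a
    background proxy (mitochondrial signal is sparse and bright, so the low
    quantiles are background).
    """
    v = stack.voxels.ravel()
    lo, hi = np.percentile(v, [1, 20])
    bg = v[(v >= lo) & (v <= hi)]
    return NoiseModel(mean=float(bg.mean()), sd=float(bg.std()), seed=seed)


def extract_cell_stack(
    mito: ImageStack,
    labels: CellLabels,
    cell_id: int,
    noise: NoiseModel,
) -> ImageStack:
    """Single-cell mitochondria stack via mask + external noise injection.

    Voxels inside the cell mask are copied verbatim; voxels outside are
    replaced by draws from Normal(mean, sd) clipped to the image's valid
    range.  Seeded and reproducible.  ``sd = 0`` (constant fill) is allowed
    but warned against: the resulting sharp step at the mask boundary is
    exactly the artefact that degrades downstream segmentation.
    """
    if mito.shape != labels.grid.shape:
        raise ValueError("mitochondria stack and labels have different shapes")
    if cell_id not in labels.ids:
        raise ValueError(f"cell id {cell_id} not present in labels")
    if noise.sd == 0:
        logger.warning(
            "noise sd is 0: constant fill leaves a sharp mask boundary and "
            "segmentation quality may degrade"
        )
    inside = labels.grid == cell_id
    rng = np.random.default_rng(noise.seed)
    out = np.array(mito.voxels, dtype=np.float64, copy=True)
    n_out = int((~inside).sum())
    draws = rng.normal(noise.mean, noise.sd, size=n_out)
    if np.issubdtype(mito.voxels.dtype, np.integer):
        info = np.iinfo(mito.voxels.dtype)
        np.clip(draws, max(0, info.min), info.max, out=draws)
    else:
        hi = max(float(mito.voxels.max()), noise.mean + 5 * noise.sd)
        np.clip(draws, 0.0, hi, out=draws)
    out[~inside] = draws
    result = ImageStack(out, mito.spacing, mito.channel_label)
    if np.issubdtype(mito.voxels.dtype, np.integer):
        result.voxels = np.round(result.voxels).astype(mito.voxels.dtype)
    return result
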