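"""Tubular enhancement and mitochondrial segmentation.

The front end of the quantitation pipeline: a multiscale Hessian-eigenvalue
tubularity (vesselness) filter highlights bright curvilinear structures and
suppresses blobs and plates, then a local adaptive threshold with a global
floor produces the binary mitochondrial mask.

Scale semantics: a :class:`ScaleSet` samples ``n_scales`` sigmas uniformly in
``[min_scale, max_scale]``, in in-plane voxel units on the isotropically
resampled grid.  The default spans tube radii of 1.0-2.5 voxels; a narrower
1.5-2.0 x 6 set helps stacks with weaker signal.  The local-threshold block
parameter is a half-width in voxels (default 10).  Both semantics are this
package's documented contracts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import sato

from .io import ImageStack, VoxelSpacing, resample_isotropic

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleSet",
    "suggest_floor",
    "BinaryMask",
    "DEFAULT_SCALES",
    "WEAK_SIGNAL_SCALES",
    "enhance_tubular",
    "segment_mitochondria",
]


@dataclass(frozen=True)
class ScaleSet:
    """Uniformly sampled Hessian scales (in-plane voxel units)."""

    min_scale: float = 1.0
    max_scale: float = 2.5
    n_scales: int = 6

    def __post_init__(self) -> None:
        if not (0 < self.min_scale <= self.max_scale):
            raise ValueError("require 0 < min_scale <= max_scale")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")

    def sigmas(self) -> np.ndarray:
        return np.linspace(self.min_scale, self.max_scale, self.n_scales)


#: Default scale span: tube radii ~1.0-2.5 in-plane voxels.
DEFAULT_SCALES = ScaleSet(1.0, 2.5, 6)
#: Narrow span that improves segmentation of weaker-signal stacks.
WEAK_SIGNAL_SCALES = ScaleSet(1.5, 2.0, 6)


@dataclass
class BinaryMask:
    """Boolean mitochondrial mask, same shape as its source stack."""

    grid: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


def enhance_tubular(
    stack: ImageStack,
    scales: ScaleSet = DEFAULT_SCALES,
    presmooth: float = 1.0,
) -> ImageStack:
    """Multiscale tubularity enhancement of a single-channel stack.

    The stack is resampled to isotropic voxels (Hessian eigen-analysis on a
    raw grid with dz ~7x dx biases orientation), denoised with a small
    Gaussian (``presmooth`` voxels — structure below the optical PSF is
    noise by definition, and unsmoothed shot noise otherwise reads as
    fine-scale tubularity), filtered with the Hessian-based tubularity
    response at each scale taking the per-voxel maximum over scales, and the
    response is rescaled to [0, 1] and mapped back to the original grid.
    A constant stack yields an identically zero response (no second-order
    structure), which is not an error.
    """
    iso = resample_isotropic(stack)
    img = iso.voxels.astype(np.float64)
    if presmooth > 0:
        img = ndimage.gaussian_filter(img, presmooth)
    if np.ptp(img) == 0:
        resp = np.zeros_like(img)
    else:
        resp = sato(img, sigmas=scales.sigmas(), black_ridges=False, mode="reflect")
        m = resp.max()
        if m > 0:
            resp = resp / m
    if iso.shape != stack.shape:
        zoom = tuple(t / s for t, s in zip(stack.shape, iso.shape))
        resp = ndimage.zoom(resp, zoom, order=1, mode="nearest")
        # zoom rounding can be off by one; pad/trim defensively
        resp = _match_shape(resp, stack.shape)
    np.clip(resp, 0.0, 1.0, out=resp)
    return ImageStack(resp, stack.spacing, stack.channel_label)


def _match_shape(arr: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    out = arr
    for ax, n in enumerate(shape):
        if out.shape[ax] > n:
            out = np.take(out, range(n), axis=ax)
        elif out.shape[ax] < n:
            pad = [(0, 0)] * 3
            pad[ax] = (0, n - out.shape[ax])
            out = np.pad(out, pad, mode="edge")
    return out


def suggest_floor(intensity: ImageStack) -> float:
    """Noise-adaptive response floor from the stack's own noise level.

    Must be computed on the *original* (unresampled) stack: isotropic
    z-interpolation correlates the noise and hides it from the estimator.
    The shot/read noise of the image is estimated robustly (wavelet-detail
    sigma) and normalised by the bright-signal level (99.9th percentile);
    the floor rises from 0.10 on clean images toward ~0.17 at peak SNR 5.
    Clean images keep dim tubule segments; noisy images must clear the
    noise-ridge tail of the tubularity response.
    """
    from skimage.restoration import estimate_sigma

    sigma = float(estimate_sigma(intensity.voxels.astype(np.float64)))
    peak = float(np.percentile(intensity.voxels, 99.9))
    sigma_norm = sigma / peak if peak > 0 else 0.0
    return float(np.clip(0.10 + 0.5 * sigma_norm, 0.10, 0.30))


def segment_mitochondria(
    enhanced: ImageStack,
    adaptive_block: int = 10,
    global_floor: float | None = None,
    offset: float = 0.01,
    min_component_voxels: int = 5,
    min_component_um3: float | None = 0.15,
    intensity: ImageStack | None = None,
    refine_halfmax: bool = False,
    halfmax_radius: int = 5,
) -> BinaryMask:
    """Threshold a tubularity response into a binary mitochondrial mask.

    A voxel is foreground when its response exceeds both the local mean over
    a block of half-width ``adaptive_block`` (plus a small ``offset``) and a
    global floor that suppresses flicker in empty regions.  When
    ``global_floor`` is None it is chosen adaptively from the image noise
    level (:func:`suggest_floor`, requires ``intensity``; falls back to
    0.15 without it).

    The tubularity response spreads roughly one scale beyond the intensity
    tube; with ``refine_halfmax`` the mask is restricted to the
    full-width-half-maximum support of ``intensity``: voxels whose
    (smoothed, background-subtracted) intensity reaches half the local tube
    peak within ``halfmax_radius`` voxels — the standard definition of
    object extent in fluorescence.  The refinement produces voxel-accurate
    masks but can drop dim segments near bright junctions, so it is off by
    default.

    Connected components (26-connectivity) smaller than the larger of
    ``min_component_voxels`` and ``min_component_um3`` (converted with the
    voxel volume) are removed: a physical floor is spacing-independent, and
    even a 0.4 µm stub of a real tubule exceeds 0.15 µm³ in mask support.
    Deterministic given identical input and parameters.
    """
    if adaptive_block < 2:
        raise ValueError(f"adaptive_block must be >= 2 voxels, got {adaptive_block}")
    e = enhanced.voxels.astype(np.float64)
    if e.min() < -1e-9 or e.max() > 1 + 1e-9:
        raise ValueError("enhanced response must lie in [0, 1]")
    if global_floor is None:
        global_floor = suggest_floor(intensity) if intensity is not None else 0.15
        logger.info("adaptive global floor: %.3f", global_floor)
    local_mean = ndimage.uniform_filter(e, size=2 * adaptive_block + 1, mode="reflect")
    mask = (e > local_mean + offset) & (e > global_floor)
    if refine_halfmax and mask.any():
        if intensity is None or intensity.shape != enhanced.shape:
            raise ValueError("half-max refinement needs a matching intensity stack")
        img = ndimage.gaussian_filter(intensity.voxels.astype(np.float64), 1.0)
        bg = np.percentile(img, 20)
        local_peak = ndimage.maximum_filter(img, size=2 * halfmax_radius + 1)
        mask &= (img - bg) >= 0.5 * (local_peak - bg)
    min_vox = min_component_voxels
    if min_component_um3 is not None:
        min_vox = max(min_vox, int(round(min_component_um3 / enhanced.spacing.voxel_volume)))
    if min_vox > 1 and mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_vox)
        mask &= ~np.isin(labels, small[small > 0])
    return BinaryMask(mask, enhanced.spacing)
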