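"""Raster data model, TIFF z-stack I/O and per-slice registration.

The universal raster currency is :class:`ImageStack`: a 3D scalar grid
indexed ``(z, y, x)`` with physical voxel spacing in micrometres.  Physical
coordinates are always ``index * spacing`` per axis, so coordinate ``(0,0,0)``
is the centre of the corner voxel.

Confocal z-stacks are almost always anisotropic (the z step is several times
the in-plane pixel size), so the spacing travels with every stack and every
downstream operation is spacing-aware.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelSpacing",
    "ImageStack",
    "DEFAULT_SPACING",
    "read_stack",
    "write_stack",
    "crop_roi",
    "register_slices",
    "apply_shifts",
    "resample_isotropic",
]


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel spacing in micrometres per voxel.

    ``dx``/``dy`` are the in-plane pixel sizes, ``dz`` the z-plane step.
    Anisotropy (``dz != dx``) is expected and permitted; all components must
    be strictly positive.
    """

    dx: float = 0.104
    dy: float = 0.104
    dz: float = 0.72

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"spacing {name} must be finite and > 0, got {v}")

    @property
    def zyx(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.dx * self.dy * self.dz

    def is_isotropic(self, rtol: float = 0.05) -> bool:
        lo, hi = min(self.zyx), max(self.zyx)
        return hi / lo <= 1.0 + rtol


#: Spinning-disc confocal defaults used throughout (µm): 0.104 in-plane,
#: 0.72 z step.
DEFAULT_SPACING = VoxelSpacing(0.104, 0.104, 0.72)


@dataclass
class ImageStack:
    """A 3D scalar intensity grid with physical voxel spacing.

    ``voxels`` is indexed ``(z, y, x)``.  Intensities must be finite and
    non-negative; at least one plane of at least 2x2 pixels is required.
    """

    voxels: np.ndarray
    spacing: VoxelSpacing = field(default_factory=VoxelSpacing)
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a (z, y, x) array, got ndim={self.voxels.ndim}")
        nz, ny, nx = self.voxels.shape
        if nz < 1 or ny < 2 or nx < 2:
            raise ValueError(f"stack too small: shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack contains non-finite values")
        if np.min(self.voxels) < 0:
            raise ValueError("stack contains negative intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy(self) -> "ImageStack":
        return ImageStack(self.voxels.copy(), self.spacing, self.channel_label)


class TiffFormatError(ValueError):
    """Raised when a file cannot be interpreted as a grayscale TIFF z-stack."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_stack(
    path: str | Path,
    spacing: VoxelSpacing | None = None,
    channel: int | None = None,
    channel_label: str = "",
) -> ImageStack:
    """Read a single- or multi-page TIFF as an :class:`ImageStack`.

    Spacing priority: the explicit ``spacing`` argument, then a sidecar
    ``<file>.json`` written by :func:`write_stack`, then
    :data:`DEFAULT_SPACING`.  TIFF resolution tags are treated as advisory
    only — acquisition metadata is unreliable across dialects.

    For 4D files (channel axis first or last) a ``channel`` index must be
    supplied.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:  # includes ragged page sizes
        raise TiffFormatError(f"cannot read {path} as a TIFF z-stack: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 4:
        if channel is None:
            raise TiffFormatError(
                f"{path} has {data.ndim} dimensions; supply a channel index"
            )
        # channel axis is whichever non-spatial axis is smallest
        ax = int(np.argmin(data.shape))
        data = np.take(data, channel, axis=ax)
    if data.ndim != 3:
        raise TiffFormatError(f"{path}: unsupported dimensionality {data.ndim}")
    if np.issubdtype(data.dtype, np.integer):
        # widen losslessly so downstream arithmetic cannot wrap
        data = data.astype(np.int64 if data.dtype.itemsize > 2 else np.int32)
    if spacing is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            spacing = VoxelSpacing(meta["dx_um"], meta["dy_um"], meta["dz_um"])
            channel_label = channel_label or meta.get("channel_label", "")
        else:
            spacing = DEFAULT_SPACING
    return ImageStack(data, spacing, channel_label)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page grayscale TIFF (one page per z-plane).

    Spacing is recorded in the TIFF x/y resolution tags and, authoritatively,
    in a ``<file>.json`` sidecar (the z step has no standard baseline TIFF
    tag).  Float data is stored as 32-bit float pages; integer data keeps an
    exact integer representation.
    """
    path = Path(path)
    data = stack.voxels
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    elif data.dtype not in (np.uint8, np.uint16, np.int16, np.int32, np.uint32):
        data = data.astype(np.int32)
    try:
        tifffile.imwrite(
            path,
            data,
            resolution=(1.0 / stack.spacing.dx, 1.0 / stack.spacing.dy),
            resolutionunit="MICROMETER",
        )
    except OSError as exc:
        raise OSError(f"cannot write TIFF to {path}: {exc}") from exc
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "dx_um": stack.spacing.dx,
                "dy_um": stack.spacing.dy,
                "dz_um": stack.spacing.dz,
                "channel_label": stack.channel_label,
            }
        )
    )


def crop_roi(
    stack: ImageStack,
    bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]],
) -> ImageStack:
    """Crop to half-open per-axis index ranges ``((z0,z1),(y0,y1),(x0,x1))``.

    Spacing is unchanged; the result is a copy.
    """
    if len(bounds) != 3:
        raise ValueError("bounds must give (z, y, x) ranges")
    sl = []
    for (lo, hi), n in zip(bounds, stack.shape):
        if not (0 <= lo < hi <= n):
            raise ValueError(f"bounds ({lo}, {hi}) invalid for axis of length {n}")
        sl.append(slice(lo, hi))
    return ImageStack(stack.voxels[tuple(sl)].copy(), stack.spacing, stack.channel_label)


def _pairwise_shift(ref_plane: np.ndarray, mov_plane: np.ndarray, upsample: int) -> np.ndarray:
    """(dy, dx) shift that maps ``mov_plane`` onto ``ref_plane``."""
    if np.ptp(ref_plane) == 0 or np.ptp(mov_plane) == 0:
        logger.warning("constant plane encountered during registration; shift set to 0")
        return np.zeros(2)
    shift, _, _ = phase_cross_correlation(
        ref_plane.astype(np.float64),
        mov_plane.astype(np.float64),
        upsample_factor=upsample,
        normalization=None,
    )
    return np.asarray(shift, dtype=float)


def register_slices(
    stack: ImageStack,
    reference: int | None = None,
    upsample: int = 20,
) -> tuple[ImageStack, np.ndarray]:
    """Correct intra-stack in-plane movement by per-plane translation.

    Sequential phase correlation between neighbouring planes is chained to the
    reference plane (default: middle plane), and each plane is translated
    (subpixel, linear interpolation) to undo its accumulated drift.  Returns
    the registered stack and the applied per-plane ``(dy, dx)`` shifts in
    voxels; the reference plane's shift is ``(0, 0)``.

    The model is translation-only: drift and jitter during acquisition are
    rigid in-plane displacements, and translation keeps lengths metric-true.
    """
    nz = stack.shape[0]
    if nz < 2:
        raise ValueError("registration needs at least 2 planes")
    if reference is None:
        reference = nz // 2
    if not (0 <= reference < nz):
        raise ValueError(f"reference plane {reference} out of range")
    planes = stack.voxels.astype(np.float64)
    shifts = np.zeros((nz, 2))
    for i in range(reference + 1, nz):
        shifts[i] = shifts[i - 1] + _pairwise_shift(planes[i - 1], planes[i], upsample)
    for i in range(reference - 1, -1, -1):
        shifts[i] = shifts[i + 1] + _pairwise_shift(planes[i + 1], planes[i], upsample)
    registered = apply_shifts(stack, shifts)
    return registered, shifts


def apply_shifts(stack: ImageStack, shifts: np.ndarray) -> ImageStack:
    """Apply per-plane (dy, dx) translations (e.g. to a second channel).

    Shifts computed on one channel of a two-colour stack are applied
    identically to the other so the channels stay aligned.
    """
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (stack.shape[0], 2):
        raise ValueError(f"expected shifts of shape ({stack.shape[0]}, 2)")
    out = np.empty_like(stack.voxels, dtype=np.float64)
    for i in range(stack.shape[0]):
        if np.all(shifts[i] == 0):
            out[i] = stack.voxels[i]
        else:
            # reflective boundary: a constant fill would create sharp dark
            # bands that bias any subsequent correlation
            out[i] = ndimage.shift(
                stack.voxels[i].astype(np.float64), shifts[i], order=1, mode="reflect"
            )
    np.clip(out, 0, None, out=out)
    return ImageStack(out, stack.spacing, stack.channel_label)


def resample_isotropic(stack: ImageStack, order: int = 1) -> ImageStack:
    """Resample to isotropic voxels at the finest spacing component.

    Hessian eigen-analysis and 3D thinning both assume isotropic voxels;
    with a z step ~7x the in-plane pixel this resampling must happen before
    either.  No-op (copy) when the stack is already near-isotropic.
    """
    if stack.spacing.is_isotropic():
        return stack.copy()
    target = min(stack.spacing.zyx)
    zoom = tuple(s / target for s in stack.spacing.zyx)
    vox = ndimage.zoom(stack.voxels.astype(np.float64), zoom, order=order, mode="nearest")
    np.clip(vox, 0, None, out=vox)
    iso = VoxelSpacing(target, target, target)
    return ImageStack(vox, iso, stack.channel_label)
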