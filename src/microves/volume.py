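"""Image-volume container, TIFF stack I/O and grid preprocessing.

Confocal z-stacks of perfused microvascular networks come with anisotropic
voxels (fine in x-y, coarse in z).  Everything downstream assumes a cubic
grid, so the two preprocessing steps offered here are z-interpolation to a
cubic voxel and optional integer decimation to trade resolution for speed.

Axis convention: arrays are indexed ``[ix, iy, iz]`` with z equal to the
TIFF page index; physical coordinates in micrometres are
``index * spacing`` (0-based, voxel-centre convention).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile
from scipy.interpolate import interp1d

__all__ = [
    "VolumeImage",
    "BinaryMask",
    "read_stack",
    "write_stack",
    "isotropize",
    "downsample",
]


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with per-axis voxel spacing in μm.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities, arbitrary units.
    spacing : tuple of float
        Voxel size ``(dx, dy, dz)`` in μm.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in μm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must have 3 axes, each of length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (μm)")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask(VolumeImage):
    """Boolean lumen volume on the same grid contract as :class:`VolumeImage`."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(bool)

    def foreground_fraction(self) -> float:
        return float(self.data.mean())


def read_stack(path: str | Path, spacing: tuple[float, float, float]) -> VolumeImage:
    """Read a multipage grayscale TIFF into a :class:`VolumeImage`.

    The page axis becomes z.  Spacing is supplied by the caller because TIFF
    metadata is unreliable across microscope exporters.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(
            f"{path}: expected grayscale pages, got array of ndim {pages.ndim} "
            "(RGB or hyperstack input is unsupported)"
        )
    # tifffile yields (z, y, x); internal order is (x, y, z)
    data = np.ascontiguousarray(pages.transpose(2, 1, 0))
    return VolumeImage(data=data, spacing=spacing)


def write_stack(img: VolumeImage, path: str | Path) -> None:
    """Write a volume as a multipage TIFF (page axis = z).

    Boolean masks are stored as 0/255 uint8 so any viewer renders them.
    """
    data = img.data
    if data.dtype == bool:
        data = data.astype(np.uint8) * 255
    tifffile.imwrite(
        Path(path), np.ascontiguousarray(data.transpose(2, 1, 0)), photometric="minisblack"
    )


def isotropize(img: VolumeImage) -> VolumeImage:
    """Resample the z-axis so voxels become cubic at the x-y pixel size.

    Linear interpolation along z; x-y planes are untouched.  The physical z
    extent is preserved to within one voxel.  Requires dx == dy.
    """
    dx, dy, dz = img.spacing
    if not np.isclose(dx, dy):
        raise ValueError(f"anisotropic x-y spacing unsupported (dx={dx}, dy={dy})")
    if dz < dx:
        raise ValueError(f"z spacing {dz} finer than x-y spacing {dx}; nothing to interpolate")
    if np.isclose(dz, dx):
        return img

    nz = img.shape[2]
    z_old = np.arange(nz) * dz
    n_new = int(round((nz - 1) * dz / dx)) + 1
    z_new = np.minimum(np.arange(n_new) * dx, z_old[-1])
    if nz == 1:
        data = img.data.copy()
    else:
        f = interp1d(z_old, img.data.astype(float), axis=2, kind="linear")
        data = f(z_new)
        if np.issubdtype(img.data.dtype, np.integer):
            data = np.rint(data).astype(img.data.dtype)
    return VolumeImage(data=data, spacing=(dx, dx, dx), origin=img.origin)


def downsample(img: VolumeImage, factor: int) -> VolumeImage:
    """Decimate the grid, keeping one out of ``factor`` voxels per axis.

    Pure index selection (no smoothing): output voxel (i, j, k) is input
    voxel (ni, nj, nk), and spacing is multiplied by ``factor``.
    """
    n = int(factor)
    if n < 1:
        raise ValueError("downsampling factor must be a positive integer")
    if min(img.shape) < n:
        raise ValueError(f"factor {n} exceeds an axis length of shape {img.shape}")
    if n == 1:
        return replace(img, data=img.data.copy())
    cls = type(img)
    return cls(
        data=img.data[::n, ::n, ::n].copy(),
        spacing=tuple(s * n for s in img.spacing),
        origin=img.origin,
    )
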