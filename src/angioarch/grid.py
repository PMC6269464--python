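"""Voxel-grid data model and multipage-TIFF stack I/O.

The whole pipeline operates on binary isotropic voxel grids: a voxel is
either vessel signal (True, stored as 255 on disk) or background.  The
coordinate convention is ``(z, y, x)`` with 0-based indices; ``z`` is the
TIFF page index, ``y`` the page row, ``x`` the page column.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile

from .errors import StackIOError

#: Edge length of the isotropic analysis voxel, in micrometres.
DEFAULT_VOXEL_SIZE_UM = 0.54


@dataclass(frozen=True)
class GridMeta:
    """Geometry of an isotropic voxel grid.

    Parameters
    ----------
    voxel_size_um:
        Edge length of the (isotropic) voxel in µm.  Must be positive.
    shape:
        Grid shape as ``(z, y, x)`` voxel counts, each at least 1.
    """

    voxel_size_um: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be three positive counts, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def voxel_area_um2(self) -> float:
        """Area of one voxel face in µm²."""
        return self.voxel_size_um ** 2

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of one voxel in µm³."""
        return self.voxel_size_um ** 3

    @property
    def n_voxels(self) -> int:
        """Total number of voxels in the grid."""
        return int(np.prod(self.shape))


@dataclass
class BinaryStack:
    """A 3D boolean grid of vessel signal plus its geometry.

    ``voxels[z, y, x]`` is True where vessel signal is present.
    """

    meta: GridMeta
    voxels: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"voxels must be 3D, got ndim={vox.ndim}")
        if vox.shape != self.meta.shape:
            raise ValueError(
                f"voxel grid shape {vox.shape} does not match meta.shape {self.meta.shape}"
            )
        self.voxels = vox.astype(bool, copy=False)

    @property
    def signal_count(self) -> int:
        """Number of signal (vessel) voxels."""
        return int(self.voxels.sum())

    def with_voxels(self, voxels: np.ndarray) -> "BinaryStack":
        """Return a new stack with the same geometry and new voxel data."""
        return BinaryStack(self.meta, voxels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryStack):
            return NotImplemented
        return self.meta == other.meta and bool(np.array_equal(self.voxels, other.voxels))


def read_stack(path: str | os.PathLike, voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM) -> BinaryStack:
    """Read a multipage TIFF z-stack as a binary stack.

    Any nonzero pixel maps to signal; the stacks this pipeline analyzes are
    already binary, so no threshold is applied.  The voxel size is supplied
    by the caller rather than parsed from TIFF tags (resolution metadata is
    unreliable across writers).

    Raises
    ------
    StackIOError
        If the file is unreadable, has zero pages, or its pages disagree
        in height/width.
    """
    try:
        with tifffile.TiffFile(os.fspath(path)) as tf:
            pages = [p.asarray() for p in tf.pages]
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise StackIOError(f"cannot read TIFF stack {path!r}: {exc}") from exc
    if len(pages) == 0:
        raise StackIOError(f"TIFF stack {path!r} contains no pages")
    first = pages[0].shape
    if any(p.ndim != 2 for p in pages):
        raise StackIOError(f"TIFF stack {path!r} has non-grayscale pages")
    if any(p.shape != first for p in pages):
        raise StackIOError(f"TIFF stack {path!r} has inconsistent page dimensions")
    vox = np.stack(pages, axis=0) != 0
    meta = GridMeta(voxel_size_um=voxel_size_um, shape=vox.shape)
    return BinaryStack(meta, vox)


def write_stack(stack: BinaryStack, path: str | os.PathLike) -> None:
    """Write a binary stack as a multipage 8-bit TIFF (signal=255)."""
    data = np.where(stack.voxels, np.uint8(255), np.uint8(0))
    try:
        tifffile.imwrite(os.fspath(path), data, photometric="minisblack")
    except OSError as exc:
        raise StackIOError(f"cannot write TIFF stack {path!r}: {exc}") from exc


def volume_fraction(stack: BinaryStack) -> float:
    """Percent vascular volume V%: 100 × signal voxels / total voxels."""
    return 100.0 * stack.signal_count / stack.meta.n_voxels
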