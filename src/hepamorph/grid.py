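"""Voxel-grid container shared by every pipeline stage.

A :class:`VoxelGrid` couples a 3D array with its physical voxel spacing in
micrometres, so that every downstream measurement (lengths, volumes,
distances) is expressed in physical units rather than voxels.  The physical
coordinate of voxel index ``i`` is ``origin + i * spacing`` (voxel-centred,
0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import nibabel as nib
import tifffile

__all__ = ["VoxelGrid", "read_volume", "write_volume"]


@dataclass
class VoxelGrid:
    """A 3D scalar or integer-label volume with physical voxel spacing.

    Parameters
    ----------
    data
        3D array.  Grayscale volumes may be any float or integer dtype;
        label volumes must hold integers.
    spacing
        Voxel spacing per axis in µm, all components > 0.
    origin
        Physical offset of voxel (0, 0, 0) in µm.
    kind
        Either ``"grayscale"`` or ``"labels"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "grayscale"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        if self.kind not in ("grayscale", "labels"):
            raise ValueError(f"kind must be 'grayscale' or 'labels', got {self.kind!r}")
        if self.kind == "labels" and not np.issubdtype(self.data.dtype, np.integer):
            if not np.issubdtype(self.data.dtype, np.bool_):
                raise ValueError("label grids must hold integers")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in µm³."""
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical extent per axis in µm (shape × spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) < 1e-9 and abs(s[1] - s[2]) < 1e-9

    def world_to_index(self, position_um) -> tuple[int, int, int]:
        """Nearest voxel index of a physical µm coordinate."""
        pos = np.asarray(position_um, dtype=float)
        idx = np.round((pos - np.asarray(self.origin)) / np.asarray(self.spacing))
        return tuple(int(i) for i in idx)

    def contains_position(self, position_um) -> bool:
        idx = self.world_to_index(position_um)
        return all(0 <= i < n for i, n in zip(idx, self.shape))

    def index_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical µm coordinate arrays per axis (1D, voxel centres)."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )

    def same_grid(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_grid(self, other: "VoxelGrid", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"grid mismatch: {what} has shape={other.shape} spacing={other.spacing}, "
                f"expected shape={self.shape} spacing={self.spacing}"
            )

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "VoxelGrid":
        """A new grid sharing this grid's geometry."""
        return replace(self, data=data, kind=kind or self.kind)


# -- I/O --------------------------------------------------------------------


def read_volume(path, spacing_override=None, kind: str = "grayscale") -> VoxelGrid:
    """Read a multi-page TIFF stack or NIfTI-1 volume.

    NIfTI spacing is taken from the header (zooms, assumed µm); TIFF files
    carry no reliable physical spacing, so ``spacing_override`` is required
    for them.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        spacing = spacing_override or tuple(float(z) for z in img.header.get_zooms()[:3])
        return VoxelGrid(data, spacing=spacing, kind=kind)
    if suffixes.endswith((".tif", ".tiff")):
        data = tifffile.imread(str(path))
        if spacing_override is None:
            raise ValueError(
                f"{path}: TIFF carries no physical spacing; pass spacing_override (µm)"
            )
        return VoxelGrid(np.asarray(data), spacing=tuple(spacing_override), kind=kind)
    raise ValueError(f"{path}: unsupported volume format (expected .tif/.tiff/.nii/.nii.gz)")


def write_volume(grid: VoxelGrid, path) -> Path:
    """Write a grid as NIfTI-1 (spacing in header) or multi-page TIFF.

    TIFF output is 16-bit for grayscale; the caller is responsible for the
    value range fitting uint16.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(grid.spacing) + [1.0])
        data = grid.data
        if grid.kind == "labels":
            data = data.astype(np.int32)
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(grid.spacing)
        nib.save(img, str(path))
        return path
    if suffixes.endswith((".tif", ".tiff")):
        data = grid.data
        if grid.kind == "labels":
            data = data.astype(np.uint16)
        else:
            data = np.clip(data, 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(str(path), data, photometric="minisblack")
        return path
    raise ValueError(f"{path}: unsupported output format")
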