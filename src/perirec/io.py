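"""NIfTI volume I/O and intensity preprocessing.

Volumes are carried as :class:`VoxelGrid` (scalar images) and
:class:`MaskVolume` (binary masks).  Both keep the full NIfTI affine so that
every millimeter distance downstream is computed in world space; voxel
indices are 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


def _default_affine() -> np.ndarray:
    return np.eye(4)


@dataclass
class VoxelGrid:
    """A 3D scalar image with world geometry.

    Parameters
    ----------
    data : ndarray
        3D array of intensities.
    affine : ndarray
        4x4 voxel-to-world (RAS mm) matrix; spacing and orientation are
        derived from it, never stored separately.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def spacing_mm(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def orientation(self) -> tuple[str, str, str]:
        """Axis direction codes, e.g. ``('R', 'A', 'S')``."""
        return nib.orientations.aff2axcodes(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def same_geometry(self, other: "VoxelGrid | MaskVolume", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)


@dataclass
class MaskVolume(VoxelGrid):
    """A binary mask sharing :class:`VoxelGrid` geometry; values in {0, 1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.data = self.data.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def indices(self) -> np.ndarray:
        """(n, 3) voxel indices of the mask support, C-order deterministic."""
        return np.argwhere(self.data > 0)


def read_volume(path, as_mask: bool = False) -> VoxelGrid:
    """Read a NIfTI-1 file into a :class:`VoxelGrid` (or :class:`MaskVolume`).

    Raises ``ValueError`` for non-3D images.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    cls = MaskVolume if as_mask else VoxelGrid
    if as_mask:
        data = (data > 0.5).astype(np.uint8)
    else:
        data = data.astype(np.float32)
    return cls(data=data, affine=np.asarray(img.affine))


def write_volume(grid: VoxelGrid, path) -> None:
    """Write a grid to NIfTI-1; float32 for images, uint8 for masks."""
    dtype = np.uint8 if isinstance(grid, MaskVolume) else np.float32
    img = nib.Nifti1Image(grid.data.astype(dtype), grid.affine)
    nib.save(img, str(path))


def require_isotropic(grid: VoxelGrid, tol: float = 0.01) -> None:
    """Raise if the grid's voxels deviate from isotropy by more than ``tol`` (relative)."""
    sp = grid.spacing_mm
    if (sp.max() - sp.min()) / sp.mean() > tol:
        raise ValueError(f"isotropic voxels required, got spacing {tuple(sp)}")


def zscore_normalize(grid: VoxelGrid, mask: MaskVolume, ddof: int = 0) -> VoxelGrid:
    """Z-score intensities within ``mask``; voxels outside are set to 0.

    Uses the population standard deviation by default (``ddof=0``).  Raises
    on an empty mask or a constant image (zero variance) within the mask.
    """
    if not grid.same_geometry(mask):
        raise ValueError("grid and mask geometry differ")
    inside = mask.data > 0
    if not inside.any():
        raise ValueError("normalization mask is empty")
    vals = grid.data[inside].astype(np.float64)
    sd = vals.std(ddof=ddof)
    if sd == 0:
        raise ValueError("constant image within mask: zero variance")
    out = np.zeros_like(grid.data, dtype=np.float32)
    out[inside] = ((grid.data[inside] - vals.mean()) / sd).astype(np.float32)
    return VoxelGrid(data=out, affine=grid.affine.copy())


def resample_isotropic(grid: VoxelGrid, target_mm: float = 1.0) -> VoxelGrid:
    """Resample to isotropic ``target_mm`` voxels.

    Trilinear interpolation for intensities, nearest-neighbour (then
    re-binarized) for masks; the world extent is preserved to within one
    voxel.  Already-at-target grids are returned unchanged.
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    sp = grid.spacing_mm
    if np.allclose(sp, target_mm):
        return grid
    is_mask = isinstance(grid, MaskVolume)
    zoom = sp / target_mm
    order = 0 if is_mask else 1
    data = ndimage.zoom(grid.data.astype(np.float32), zoom, order=order,
                        mode="nearest", grid_mode=True)
    # grid_mode=True maps voxel edges onto voxel edges: output center j sits at
    # input coordinate (j + 0.5)/zoom - 0.5, which fixes the new affine.
    new_affine = grid.affine.copy()
    new_affine[:3, :3] = grid.affine[:3, :3] / zoom[np.newaxis, :]
    new_affine[:3, 3] = grid.affine[:3, 3] + grid.affine[:3, :3] @ (0.5 / zoom - 0.5)
    if is_mask:
        return MaskVolume(data=(data > 0.5).astype(np.uint8), affine=new_affine)
    return VoxelGrid(data=data.astype(np.float32), affine=new_affine)
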