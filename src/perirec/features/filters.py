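"""Image filter bank: Laplacian of Gaussian, one-level 3D wavelets, 3D LBP.

Every filter returns a :class:`FilteredImage` on the source geometry, so the
voxelwise extractor can treat original and filtered channels uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from ..io import VoxelGrid


@dataclass
class FilteredImage:
    source_modality: str
    filter_id: str
    grid: VoxelGrid


def log_filter(grid: VoxelGrid, sigma_mm: float,
               source_modality: str = "image") -> FilteredImage:
    """Laplacian-of-Gaussian response; ``sigma_mm`` is a world-space scale."""
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    sigma_vox = sigma_mm / grid.spacing_mm
    if np.any(sigma_vox < 0.5):
        warnings.warn(f"LoG sigma {sigma_mm} mm is below half a voxel; "
                      "response will be noise-dominated", stacklevel=2)
    def _laplace_world(img: np.ndarray) -> np.ndarray:
        # second derivatives are per voxel^2; divide by spacing^2 per axis so
        # the response is in world (mm^-2) units
        out = np.zeros_like(img)
        for ax in range(3):
            order = [0, 0, 0]
            order[ax] = 2
            out += (ndimage.gaussian_filter(img, sigma=sigma_vox, order=order)
                    / grid.spacing_mm[ax] ** 2)
        return out

    data = _laplace_world(grid.data.astype(np.float64))
    # The truncated discrete kernel does not sum exactly to zero; subtract the
    # DC gain so a constant image maps to an exactly zero response.
    m = [2 * int(np.ceil(4 * s)) + 3 for s in sigma_vox]
    dc = _laplace_world(np.ones(m))[tuple(n // 2 for n in m)]
    data = data - dc * grid.data.astype(np.float64)
    return FilteredImage(source_modality, f"log@{sigma_mm:g}mm",
                         VoxelGrid(data.astype(np.float32), grid.affine.copy()))


_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def wavelet_decompose(grid: VoxelGrid, wavelet: str = "haar",
                      source_modality: str = "image") -> list[FilteredImage]:
    """One-level separable 3D wavelet decomposition into 8 sub-band images.

    Each sub-band is reconstructed back to source resolution (all other bands
    zeroed), so the outputs are orthogonal projections of the input for an
    orthonormal wavelet and their energies sum to the input energy.
    """
    if min(grid.shape) < 2:
        raise ValueError("each axis must have length >= 2")
    data = grid.data.astype(np.float64)
    coeffs = pywt.dwtn(data, wavelet)
    out = []
    for band in _SUBBANDS:
        key = band.lower().replace("l", "a").replace("h", "d")
        only = {k: (v if k == key else np.zeros_like(v)) for k, v in coeffs.items()}
        rec = pywt.idwtn(only, wavelet)
        rec = rec[tuple(slice(0, n) for n in grid.shape)]  # crop odd-size padding
        out.append(FilteredImage(source_modality, f"wavelet@{band}",
                                 VoxelGrid(rec.astype(np.float32), grid.affine.copy())))
    return out


def lbp3d(grid: VoxelGrid, source_modality: str = "image") -> FilteredImage:
    """3D local binary pattern: count of 6 face-neighbours >= center (ties count).

    The count code (0..6) is rotation-invariant by construction under 90-degree
    rotations about any axis.  Edges use replicate padding, so a constant image
    maps to the maximal code 6 everywhere.
    """
    data = grid.data.astype(np.float64)
    padded = np.pad(data, 1, mode="edge")
    code = np.zeros(grid.shape, dtype=np.float32)
    c = (slice(1, -1),) * 3
    for axis in range(3):
        for step in (-1, 1):
            sl = [slice(1, -1)] * 3
            sl[axis] = slice(1 + step, padded.shape[axis] - 1 + step)
            code += (padded[tuple(sl)] >= padded[c])
    return FilteredImage(source_modality, "lbp3d",
                         VoxelGrid(code, grid.affine.copy()))


def filter_bank(grid: VoxelGrid, source_modality: str,
                filters: tuple[str, ...] = ("original",),
                log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0),
                wavelet: str = "haar") -> list[FilteredImage]:
    """Expand one modality into its configured filtered channels."""
    out: list[FilteredImage] = []
    for f in filters:
        if f == "original":
            out.append(FilteredImage(source_modality, "original", grid))
        elif f == "log":
            out.extend(log_filter(grid, s, source_modality) for s in log_sigmas_mm)
        elif f == "wavelet":
            out.extend(wavelet_decompose(grid, wavelet, source_modality))
        elif f == "lbp3d":
            out.append(lbp3d(grid, source_modality))
        else:
            raise ValueError(f"unknown filter {f!r}")
    return out
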