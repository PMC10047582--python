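"""Ground-truth recurrence labels on the peritumoral support.

A peritumoral voxel that reappears inside the follow-up enhancing-tumor
segmentation is labeled recurrence (1); the remaining peritumoral voxels are
nonrecurrence (0).  Voxels outside the peritumor carry no label and are coded
``OUTSIDE`` (255) in the stored volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .io import MaskVolume

OUTSIDE = 255
RECURRENCE = 1
NONRECURRENCE = 0


@dataclass
class LabelVolume:
    """Per-voxel class over the peritumor: 1 recurrence, 0 nonrecurrence, 255 outside."""

    data: np.ndarray
    affine: np.ndarray

    @property
    def counts(self) -> dict[int, int]:
        return {
            RECURRENCE: int((self.data == RECURRENCE).sum()),
            NONRECURRENCE: int((self.data == NONRECURRENCE).sum()),
        }

    @property
    def support(self) -> np.ndarray:
        return self.data != OUTSIDE

    def labels_at(self, indices: np.ndarray) -> np.ndarray:
        """Class values at (n, 3) voxel indices (must lie on the support)."""
        vals = self.data[tuple(indices.T)]
        if np.any(vals == OUTSIDE):
            raise ValueError("requested labels outside the peritumoral support")
        return vals.astype(np.int8)


def derive_labels(peritumor: MaskVolume, followup_enhancing: MaskVolume) -> LabelVolume:
    """Label peritumoral voxels by overlap with the follow-up enhancing tumor.

    Follow-up voxels outside the peritumor (e.g. regrowth bulging into the
    resection cavity) are ignored; the labeled support is exactly the
    peritumor, so counts always satisfy ``|1| + |0| = |peritumor|``.
    """
    if not peritumor.same_geometry(followup_enhancing):
        raise ValueError("peritumor and follow-up masks differ in geometry")
    peri = peritumor.data > 0
    if not peri.any():
        raise ValueError("empty peritumoral mask")
    out = np.full(peritumor.shape, OUTSIDE, dtype=np.uint8)
    out[peri] = NONRECURRENCE
    out[peri & (followup_enhancing.data > 0)] = RECURRENCE
    return LabelVolume(data=out, affine=peritumor.affine.copy())


def write_labels(labels: LabelVolume, path) -> None:
    nib.save(nib.Nifti1Image(labels.data.astype(np.uint8), labels.affine), str(path))


def read_labels(path) -> LabelVolume:
    img = nib.load(str(path))
    return LabelVolume(data=np.asanyarray(img.dataobj).astype(np.uint8),
                       affine=np.asarray(img.affine))
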