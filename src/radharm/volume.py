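"""The unit of feature extraction: a 3D intensity grid, a binary ROI, spacing."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeWithMask", "load_nifti_pair", "save_nifti_pair"]


@dataclass
class VolumeWithMask:
    """A 3D scalar image with an aligned binary region of interest.

    image
        3D float array of intensities (CT-like values in HU).
    mask
        3D boolean array, same shape; True marks ROI voxels.
    spacing
        physical voxel size in mm per axis, ordered like the array axes.
    """

    image: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.image.ndim != 3 or self.mask.shape != self.image.shape:
            raise ValueError("image and mask must be 3D arrays of identical shape")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def roi_values(self) -> np.ndarray:
        """Masked intensities as a flat array."""
        return self.image[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def save_nifti_pair(vol: VolumeWithMask, image_path: str | Path, mask_path: str | Path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.image.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), affine), str(mask_path))


def load_nifti_pair(image_path: str | Path, mask_path: str | Path,
                    subject_id: str = "") -> VolumeWithMask:
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeWithMask(
        image=np.asanyarray(img.dataobj, dtype=np.float32),
        mask=np.asanyarray(msk.dataobj) > 0,
        spacing=spacing,
        subject_id=subject_id or Path(image_path).stem.replace(".nii", ""),
    )
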