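"""3D labelled volumes: the unit of radiomic feature extraction.

A :class:`LabeledVolume` bundles an intensity grid (HU-like scalars), a
binary region-of-interest mask of the same shape and the physical voxel
spacing in mm.  NIfTI round-tripping goes through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class LabeledVolume:
    intensities: np.ndarray  # 3D float
    mask: np.ndarray  # 3D bool, same shape
    spacing: tuple[float, float, float]  # mm

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D grid")
        if self.mask.shape != self.intensities.shape:
            raise ValueError("mask and intensities shapes differ")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def masked_values(self) -> np.ndarray:
        return self.intensities[self.mask]

    # ------------------------------------------------------------- IO

    def to_nifti(self, image_path: str | Path, mask_path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        nib.save(nib.Nifti1Image(self.intensities.astype(np.float32), affine),
                 str(image_path))
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), affine),
                 str(mask_path))

    @classmethod
    def from_nifti(cls, image_path: str | Path, mask_path: str | Path) -> "LabeledVolume":
        img = nib.load(str(image_path))
        msk = nib.load(str(mask_path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(
            intensities=np.asanyarray(img.dataobj, dtype=float),
            mask=np.asanyarray(msk.dataobj) > 0.5,
            spacing=spacing,
        )

    # ------------------------------------------------------- resampling

    def resample_isotropic(self, target_mm: float = 1.0) -> "LabeledVolume":
        """Resample to isotropic voxels (trilinear intensities,
        nearest-neighbour mask)."""
        if target_mm <= 0:
            raise ValueError("target spacing must be positive")
        factors = [s / target_mm for s in self.spacing]
        if np.allclose(factors, 1.0):
            return self
        img = ndimage.zoom(self.intensities, factors, order=1)
        msk = ndimage.zoom(self.mask.astype(np.uint8), factors, order=0) > 0
        if not msk.any():
            # tiny masks can vanish under coarse resampling; keep the
            # nearest original voxel alive instead of failing
            centre = tuple(
                int(round(c * f)) for c, f in
                zip(np.argwhere(self.mask).mean(axis=0), factors)
            )
            centre = tuple(min(max(c, 0), s - 1) for c, s in zip(centre, msk.shape))
            msk[centre] = True
        return LabeledVolume(img, msk, (target_mm,) * 3)
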