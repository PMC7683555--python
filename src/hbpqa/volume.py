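"""Containers for masked 3D volumes and NIfTI / CSV round-tripping.

A :class:`MaskedVolume` carries a scalar intensity grid together with an
aligned binary organ mask; everything downstream (bias correction, mixture
fitting, Euler curves, texture) operates only on in-mask voxels.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "MaskedVolume",
    "StandardizedVolume",
    "save_nifti_pair",
    "load_nifti_pair",
]


@dataclass
class MaskedVolume:
    """A 3D intensity grid with an aligned binary mask.

    Parameters
    ----------
    intensity : ndarray, shape (nx, ny, nz)
        Scalar intensities ``I(x, y, z)``.
    mask : ndarray of bool, same shape
        True inside the organ.
    voxel_size : tuple of float
        Physical voxel edge lengths (mm); informational only.
    id : str
        Subject / series identifier.
    """

    intensity: np.ndarray
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    id: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensity.ndim != 3:
            raise ValueError(f"intensity must be 3D, got ndim={self.intensity.ndim}")
        if self.intensity.shape != self.mask.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != mask shape {self.mask.shape}"
            )
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    def in_mask(self) -> np.ndarray:
        """Return the 1D array of in-mask intensities."""
        return self.intensity[self.mask]

    def replace(self, **kw) -> "MaskedVolume":
        return dataclasses.replace(self, **kw)


@dataclass
class StandardizedVolume:
    """Output of the preprocessing chain: in-mask mean 0, sd 1.

    Out-of-mask voxels hold NaN so they can never leak into downstream
    statistics; the (eroded) mask is authoritative.
    """

    intensity: np.ndarray
    mask: np.ndarray
    id: str = ""
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensity.shape != self.mask.shape:
            raise ValueError("intensity / mask shape mismatch")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_liver_voxels(self) -> int:
        return int(self.mask.sum())

    def in_mask(self) -> np.ndarray:
        return self.intensity[self.mask]


def save_nifti_pair(v: MaskedVolume, directory: str) -> tuple[str, str]:
    """Write ``<id>_img.nii.gz`` and ``<id>_mask.nii.gz`` under *directory*."""
    os.makedirs(directory, exist_ok=True)
    affine = np.diag(list(v.voxel_size) + [1.0])
    img_path = os.path.join(directory, f"{v.id}_img.nii.gz")
    mask_path = os.path.join(directory, f"{v.id}_mask.nii.gz")
    nib.save(nib.Nifti1Image(v.intensity.astype(np.float32), affine), img_path)
    nib.save(nib.Nifti1Image(v.mask.astype(np.uint8), affine), mask_path)
    return img_path, mask_path


def load_nifti_pair(img_path: str, mask_path: str, id: str = "") -> MaskedVolume:
    img = nib.load(img_path)
    mask = nib.load(mask_path)
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MaskedVolume(
        intensity=np.asanyarray(img.dataobj, dtype=float),
        mask=np.asanyarray(mask.dataobj) > 0,
        voxel_size=vox,
        id=id or os.path.basename(img_path).replace("_img.nii.gz", ""),
    )


def save_labels(ids: list[str], labels: list[str], path: str) -> None:
    pd.DataFrame({"id": ids, "label": labels}).to_csv(path, index=False)


def load_labels(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"id": str, "label": str})
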