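"""Lesion volumetrics from binary masks.

Volume is voxel count times voxel volume, expressed in cubic millimeters.
Masks are expected in a 1 mm isotropic standard space but any strictly
positive voxel dimensions are supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np


@dataclass
class LesionMask:
    """A 3-D binary lesion mask with physical voxel dimensions (mm)."""

    grid: np.ndarray
    voxel_dims: tuple[float, float, float]
    space_label: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        values = np.unique(self.grid)
        if not np.all(np.isin(values, (0, 1))):
            raise ValueError(
                "mask is not binary; pass threshold=0.5 when loading "
                "interpolated masks"
            )
        self.grid = self.grid.astype(np.uint8)
        self.voxel_dims = tuple(float(d) for d in self.voxel_dims)
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel dimensions must be three positive numbers")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_dims))


@dataclass(frozen=True)
class LesionVolume:
    volume_mm3: float
    voxel_count: int


def compute_lesion_volume(mask: LesionMask) -> LesionVolume:
    """Count foreground voxels and multiply by the voxel volume."""
    count = int(mask.grid.sum())
    return LesionVolume(volume_mm3=count * mask.voxel_volume, voxel_count=count)


def save_lesion_mask(mask: LesionMask, path) -> None:
    affine = np.diag((*mask.voxel_dims, 1.0))
    nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), affine), str(path))


def load_lesion_mask(
    path,
    threshold: float | None = None,
    expected_voxel_dims: tuple[float, float, float] | None = None,
    space_label: str = "",
) -> LesionMask:
    """Read a NIfTI mask; voxel dimensions come from the image header.

    ``threshold`` binarizes masks carrying interpolation residue in [0, 1]
    (values >= threshold become foreground); without it, non-binary data is
    an error.  If ``expected_voxel_dims`` is given, a header mismatch is an
    error rather than a warning.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    if expected_voxel_dims is not None and not np.allclose(
        dims, expected_voxel_dims, rtol=1e-5
    ):
        raise ValueError(
            f"header voxel dimensions {dims} do not match expected "
            f"{tuple(expected_voxel_dims)}"
        )
    if threshold is not None:
        data = (data >= threshold).astype(np.uint8)
    return LesionMask(grid=data, voxel_dims=dims, space_label=space_label)
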