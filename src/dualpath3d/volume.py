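"""Volumetric containers for CT intensity grids and aligned label maps.

A :class:`Volume3D` is a scalar intensity grid (HU-like units) with voxel
spacing and physical origin in millimetres; a :class:`LabelVolume` is an
integer class grid aligned to it, with the convention

    0 = background, 1 = liver, 2 = tumor.

NIfTI round-tripping goes through nibabel and preserves the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np

BACKGROUND, LIVER, TUMOR = 0, 1, 2


class AlignmentError(ValueError):
    """Raised when an image and a label grid do not share a geometry."""


@dataclass
class Volume3D:
    """Scalar 3D intensity grid with physical voxel geometry.

    Parameters
    ----------
    data
        3D array of intensities. Stored as float32.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        Per-axis physical offset in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """A copy of this volume's geometry carrying new voxel data."""
        return replace(self, data=np.asarray(data, dtype=np.float32))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), path)

    @classmethod
    def from_nifti(cls, path: str) -> "Volume3D":
        img = nib.load(path)
        data = np.asanyarray(img.dataobj).astype(np.float32)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(x) for x in img.affine[:3, 3])
        return cls(data=data, spacing=tuple(float(z) for z in zooms), origin=origin)


@dataclass
class LabelVolume:
    """Integer class grid aligned to a :class:`Volume3D`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(rounded, self.data):
                raise ValueError("label data must be integer-valued")
            self.data = rounded
        self.data = self.data.astype(np.int16)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D label grid, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "LabelVolume":
        return replace(self, data=np.asarray(data))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), self.affine), path)

    @classmethod
    def from_nifti(cls, path: str) -> "LabelVolume":
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(x) for x in img.affine[:3, 3])
        return cls(data=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def check_aligned(vol: Volume3D | LabelVolume, labels: Volume3D | LabelVolume) -> None:
    """Raise :class:`AlignmentError` unless the two grids share a shape."""
    if vol.shape != labels.shape:
        raise AlignmentError(f"shape mismatch: {vol.shape} vs {labels.shape}")
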