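"""Volumetric containers: scalar images and label maps on a regular grid.

Conventions
-----------
* Voxel indices are 0-based; world mm coordinate of voxel ``(i,j,k)`` is
  ``origin + index * spacing`` (axis-aligned grids only — the phantom world
  has no oblique acquisitions).
* All masks, fields and statistics live on the fixed template grid unless
  stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class Image3D:
    """A 3D scalar volume with voxel spacing and world origin.

    Parameters
    ----------
    data : ndarray
        3D scalar grid, arbitrary units.
    spacing : tuple of float
        Per-axis voxel size in mm, all > 0.
    origin : tuple of float
        World coordinate (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Image3D requires a 3D array, got ndim={self.data.ndim}")
        if any(s < 8 for s in self.data.shape):
            raise ValueError(f"all dims must be >= 8, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "Image3D | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self) -> "Image3D":
        return Image3D(self.data.copy(), self.spacing, self.origin)

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "Image3D":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(x) for x in np.abs(np.diag(affine)[:3]))
        origin = tuple(float(x) for x in affine[:3, 3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


# anatomical label codes shared across the pipeline
BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
LEFT_HIPPO, RIGHT_HIPPO, AMYGDALA, ATROPHY_NUCLEUS = 4, 5, 6, 7

ANATOMY_LEGEND = {
    BACKGROUND: "background",
    CSF: "CSF",
    GM: "GM",
    WM: "WM",
    LEFT_HIPPO: "left-hippocampus",
    RIGHT_HIPPO: "right-hippocampus",
    AMYGDALA: "amygdala-region",
    ATROPHY_NUCLEUS: "atrophy-nucleus",
}

PARCEL_OFFSET = 100  # parcel r has legend code PARCEL_OFFSET + r


@dataclass
class LabelMap:
    """Integer label grid aligned to an :class:`Image3D`.

    ``labels`` holds anatomical labels (tissue classes plus hippocampus /
    amygdala / atrophy-nucleus structures); ``parcels`` holds the tissue
    parcellation used for regional features (0 outside tissue, 1..R inside).
    Both share the legend: parcel r appears as ``parcel_r``.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    legend: dict[int, str] = field(default_factory=lambda: dict(ANATOMY_LEGEND))
    parcels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        self.spacing = tuple(float(s) for s in self.spacing)
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} not in legend")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def mask(self, *codes: int) -> np.ndarray:
        return np.isin(self.labels, codes)

    @property
    def hippocampus_mask(self) -> np.ndarray:
        return self.mask(LEFT_HIPPO, RIGHT_HIPPO)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND

    @property
    def n_parcels(self) -> int:
        if self.parcels is None:
            return 0
        return int(self.parcels.max())

    def copy(self) -> "LabelMap":
        return LabelMap(
            self.labels.copy(),
            self.spacing,
            self.origin,
            dict(self.legend),
            None if self.parcels is None else self.parcels.copy(),
        )

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))
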