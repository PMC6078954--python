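"""Core in-memory containers for 3D volumes, lesion masks and atlas label maps.

All volumes are plain numpy arrays with an isotropic-or-not voxel spacing in mm
and a 4x4 voxel-to-world affine.  NIfTI round-tripping goes through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "RawVolume",
    "NormalizedVolume",
    "ZScoreVolume",
    "VOIMask",
    "AtlasLabelMap",
    "affine_from_spacing",
    "load_volume",
    "save_volume",
]


def affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    """Diagonal voxel-to-world affine for a given spacing (mm), origin at 0."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class Volume:
    """A 3D scalar volume with voxel spacing (mm) and voxel-to-world affine."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = affine_from_spacing(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


@dataclass
class RawVolume(Volume):
    """An acquired channel in native scanner units (finite values required)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.all(np.isfinite(self.data)):
            raise ValueError("raw volume contains non-finite values")


@dataclass
class NormalizedVolume(Volume):
    """An 8-bit gray-scaled channel: integer levels 0..255.

    ``provenance`` records which rescaling rule produced it (``t2_fullrange``
    keeps 100% of the intensity range; ``clip999`` winsorizes the top 0.1%).
    """

    provenance: str = "t2_fullrange"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.size and (self.data.min() < 0 or self.data.max() > 255):
            raise ValueError("normalized volume values must lie in 0..255")


@dataclass
class ZScoreVolume(Volume):
    """Voxel-wise z-scored contrast-enhancement map (Gd minus T1, z units)."""

    reference_mean: float = 0.0
    reference_sd: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.reference_sd < 0:
            raise ValueError("reference SD must be >= 0")


@dataclass
class VOIMask(Volume):
    """Binary lesion mask (volume of interest), in native or atlas space."""

    space: str = "native"

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.asarray(self.data).astype(bool)
        if self.space not in ("native", "atlas"):
            raise ValueError(f"unknown space {self.space!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class AtlasLabelMap(Volume):
    """Integer label volume plus a label -> region-name table.

    Label 0 is the white matter / background compartment by convention.
    """

    labels: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.asarray(self.data).astype(np.int32)

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def label_values(self) -> list[int]:
        return sorted(self.labels)


def save_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume to NIfTI.  Boolean masks are stored as uint8."""
    path = Path(path)
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path, cls: type = Volume, **kwargs) -> Volume:
    """Load a NIfTI file into the requested container class."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return cls(data=data, spacing=spacing, affine=np.asarray(img.affine), **kwargs)
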