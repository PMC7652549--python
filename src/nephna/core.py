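"""Core containers, error types and NIfTI I/O.

The whole pipeline works on plain 3-D magnitude grids with an explicit
voxel spacing in millimetres.  :class:`ImageVolume` is the raw-signal
currency; a concentration map is the same container with modality
``"concentration"`` and values in mmol/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "RegionSummary",
    "ConfigError",
    "DataError",
    "GeometryError",
    "CalibrationError",
    "LayerError",
    "read_nifti",
    "write_nifti",
    "write_labels",
]


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or inconsistent data (CLI exit code 3)."""


class GeometryError(ConfigError):
    """Synthetic geometry does not fit the requested grid."""


class CalibrationError(DataError):
    """Implausible or degenerate phantom calibration."""


class LayerError(DataError):
    """Concentric-layer segmentation failed (e.g. an empty layer)."""


@dataclass
class ImageVolume:
    """A 3-D scalar magnitude grid with voxel spacing in mm.

    Parameters
    ----------
    data :
        3-D array of voxel values (float).
    spacing :
        Voxel size along each axis, mm.
    modality :
        Free-text tag, e.g. ``"na_signal"`` or ``"concentration"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = "na_signal"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DataError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def fov_mm(self) -> tuple[float, ...]:
        """Field of view along each axis, mm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def like(self, data: np.ndarray, modality: str | None = None) -> "ImageVolume":
        """A new volume on the same grid."""
        return ImageVolume(data, self.spacing, modality or self.modality)


@dataclass
class RegionSummary:
    """Mean/SD of a concentration map over one region of interest."""

    region: str
    mean: float
    sd: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise DataError(f"region {self.region!r}: empty mask")
        if self.sd < 0:
            raise DataError(f"region {self.region!r}: negative sd")


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def write_nifti(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with spacing in the header (mm)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def write_labels(labels: np.ndarray, spacing: tuple[float, float, float],
                 path: str | Path) -> Path:
    """Write an integer label volume (0 background) as NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), _affine(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path, modality: str = "na_signal") -> ImageVolume:
    """Read a 3-D NIfTI volume, taking voxel spacing from the header."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise DataError(f"{path}: expected 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(data, spacing, modality)
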