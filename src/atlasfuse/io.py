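"""NIfTI-1 volume I/O and grid-consistency checks.

All volumes handled by the pipeline — the target image, the registered
atlas intensities and labels, probability maps and output segmentations —
live on a common voxel grid. This module reads and writes them through
nibabel, carries the affine geometry untouched, and validates that
multi-volume inputs actually share a grid before any voxelwise operation
runs.

Conventions: voxel indexing is 0-based ``(i, j, k)``; all physical
distances downstream use the voxel spacing in mm taken from the header.
Labels are stored on disk as unsigned 8-bit, intensities and probability
maps as float32. No reorientation is ever performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GridMismatchError, Non3DImageError, NonBinaryLabelError

__all__ = [
    "Volume",
    "LabelVolume",
    "AtlasPair",
    "read_volume",
    "read_label",
    "write_volume",
    "write_label",
    "check_common_grid",
]

#: spacing agreement tolerance for grid checks, in mm
SPACING_TOL = 1e-4


@dataclass
class Volume:
    """A 3D scalar intensity grid with its affine geometry.

    Parameters
    ----------
    data
        3D array of intensities (any scalar units).
    affine
        4x4 voxel-to-world matrix (NIfTI convention).
    name
        Optional identifier used in error messages.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise Non3DImageError(
                f"expected a 3D volume, got shape {self.data.shape}"
                + (f" ({self.name})" if self.name else "")
            )
        if not np.all(np.asarray(self.spacing) > 0):
            raise ValueError(f"non-positive voxel spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))


@dataclass
class LabelVolume(Volume):
    """A binary (0/1) mask on the same grid as its paired :class:`Volume`."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        bad = np.setdiff1d(np.unique(self.data), [0, 1])
        if bad.size:
            raise NonBinaryLabelError(
                f"non-binary label values {bad.tolist()}"
                + (f" in {self.name}" if self.name else "")
            )
        self.data = self.data.astype(np.uint8)
        super().__post_init__()


@dataclass
class AtlasPair:
    """A registered atlas: intensity image plus its expert label."""

    intensity: Volume
    label: LabelVolume
    id: str = ""

    def __post_init__(self) -> None:
        check_common_grid(
            [self.intensity, self.label],
            ids=[f"{self.id}:intensity", f"{self.id}:label"],
        )


def _load_3d(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        affine = img.affine
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises a zoo of header errors
        raise OSError(f"unreadable NIfTI image {path}: {exc}") from exc
    if data.ndim != 3:
        raise Non3DImageError(f"non-3D image {path}: shape {data.shape}")
    return data, affine


def read_volume(path: str | Path, nan: str = "error") -> Volume:
    """Read a 3D NIfTI intensity volume.

    Parameters
    ----------
    path
        ``.nii`` / ``.nii.gz`` file.
    nan
        ``"error"`` rejects volumes containing NaN; ``"zero"`` imputes 0.
    """
    data, affine = _load_3d(path)
    data = data.astype(np.float32)
    if np.isnan(data).any():
        if nan == "zero":
            data = np.nan_to_num(data, nan=0.0)
        else:
            raise ValueError(f"volume {path} contains NaN values")
    return Volume(data, affine, name=str(path))


def read_label(path: str | Path, tol: float = 1e-3) -> LabelVolume:
    """Read a binary label volume, binarizing float-stored 0/1 values.

    Values must lie within ``tol`` of 0 or 1; anything else raises
    :class:`NonBinaryLabelError` naming the offending values.
    """
    data, affine = _load_3d(path)
    data = data.astype(np.float64)
    rounded = np.rint(data)
    off = (np.abs(data - rounded) > tol) | ~np.isin(rounded, (0.0, 1.0))
    if off.any():
        values = np.unique(data[off])[:10]
        raise NonBinaryLabelError(
            f"non-binary label {path}: offending values {values.tolist()}"
        )
    return LabelVolume(rounded.astype(np.uint8), affine, name=str(path))


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write an intensity or probability volume as NIfTI float32."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))


def write_label(label: LabelVolume, path: str | Path) -> None:
    """Write a binary label volume as NIfTI uint8."""
    img = nib.Nifti1Image(label.data.astype(np.uint8), label.affine)
    nib.save(img, str(path))


def check_common_grid(volumes: list[Volume], ids: list[str] | None = None) -> None:
    """Verify that all volumes share shape and spacing (within 1e-4 mm).

    Raises :class:`GridMismatchError` naming the first offending pair.
    """
    if not volumes:
        raise ValueError("check_common_grid: empty volume list")
    if ids is None:
        ids = [v.name or f"volume[{i}]" for i, v in enumerate(volumes)]
    ref = volumes[0]
    for vol, vid in zip(volumes[1:], ids[1:]):
        if vol.shape != ref.shape:
            raise GridMismatchError(
                f"shape mismatch: {ids[0]} {ref.shape} vs {vid} {vol.shape}"
            )
        if np.max(np.abs(np.subtract(vol.spacing, ref.spacing))) > SPACING_TOL:
            raise GridMismatchError(
                f"spacing mismatch: {ids[0]} {ref.spacing} vs {vid} {vol.spacing}"
            )
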