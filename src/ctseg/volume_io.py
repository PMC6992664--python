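"""Volume containers, NIfTI I/O, grid resampling and mid-sagittal mirror indexing.

Volumes are held in a canonical axis order — left-right, posterior-anterior,
inferior-superior — with 0-based voxel indexing. All symmetry operations assume
the input has been rigidly aligned so that the mid-sagittal plane is a fixed
column along the first (left-right) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "BinaryMask",
    "GridSpec",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_to_grid",
    "mirror_pair",
]

#: Index of the left-right axis in the canonical axis order.
LR_AXIS = 0
#: Index of the inferior-superior (axial slice) axis.
AXIAL_AXIS = 2


@dataclass(frozen=True)
class GridSpec:
    """Target lattice: voxels per axis and millimetres per voxel."""

    shape: tuple[int, int, int] | None
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.shape is not None and any(s < 1 for s in self.shape):
            raise ValueError("GridSpec shape entries must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("GridSpec spacing entries must be positive")


@dataclass(frozen=True)
class CTVolume:
    """A 3-D scalar grid in Hounsfield units on a known lattice.

    Parameters
    ----------
    data:
        3-D float array of intensities (HU).
    spacing:
        Voxel size in mm along each canonical axis.
    midsagittal_index:
        Column index of the mid-sagittal plane along the left-right axis.
        Defaults to the central column.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    midsagittal_index: int = field(default=-1)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {data.ndim}-D")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite voxels")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive on every axis")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        ms = self.midsagittal_index
        if ms == -1:
            ms = data.shape[LR_AXIS] // 2
        if not 0 <= ms < data.shape[LR_AXIS]:
            raise ValueError("midsagittal_index outside the left-right axis extent")
        object.__setattr__(self, "midsagittal_index", int(ms))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "CTVolume":
        """Same lattice, new voxel values."""
        return replace(self, data=data)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean grid on the same lattice as the volume it was derived from."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected 3-D mask, got {data.ndim}-D")
        object.__setattr__(self, "data", data.astype(bool))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def volume_ml(self) -> float:
        """Occupied volume in millilitres (1 ml = 1000 mm^3)."""
        return self.count() * float(np.prod(self.spacing)) / 1000.0

    def same_lattice(self, other) -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def _check_lattice(a, b, what: str = "operand") -> None:
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing):
        raise ValueError(f"{what}: lattice mismatch {a.shape}/{a.spacing} vs {b.shape}/{b.spacing}")


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path: str | Path, midsagittal_index: int = -1) -> CTVolume:
    """Read a single-volume NIfTI file as a :class:`CTVolume`.

    The image is reoriented to the closest RAS axis permutation so the first
    axis is left-right, and spacing is taken from the header zooms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected 3-D volume, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume contains non-finite voxels: {path}")
    if any(n < 2 for n in data.shape):
        raise ValueError(f"degenerate grid {data.shape}: need >= 2 voxels per axis")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(data, spacing, midsagittal_index)


def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def write_volume(vol: CTVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float64), _affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D mask, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return BinaryMask(data > 0, spacing)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling


def _bin_indices(n_src: int, sp_src: float, sp_tgt: float) -> tuple[np.ndarray, int]:
    """Map source voxel centres to target bins along one axis."""
    centres = (np.arange(n_src) + 0.5) * sp_src
    idx = np.floor(centres / sp_tgt).astype(np.intp)
    n_tgt = int(np.ceil(n_src * sp_src / sp_tgt))
    idx = np.clip(idx, 0, n_tgt - 1)
    return idx, n_tgt


def _bin_average(data: np.ndarray, spacing, target_spacing):
    """Average source voxels into target bins (intensity-conserving)."""
    idx, shapes = [], []
    for ax in range(3):
        i, n = _bin_indices(data.shape[ax], spacing[ax], target_spacing[ax])
        idx.append(i)
        shapes.append(n)
    flat = (
        idx[0][:, None, None] * (shapes[1] * shapes[2])
        + idx[1][None, :, None] * shapes[2]
        + idx[2][None, None, :]
    ).ravel()
    ntot = shapes[0] * shapes[1] * shapes[2]
    sums = np.bincount(flat, weights=data.ravel(), minlength=ntot)
    counts = np.bincount(flat, minlength=ntot)
    counts = np.maximum(counts, 1)
    return (sums / counts).reshape(shapes), tuple(shapes)


def resample_to_grid(vol: CTVolume | BinaryMask, target: GridSpec):
    """Resample to a coarser lattice.

    Scalar volumes are resampled by local averaging over the voxels whose
    centres fall in each target cell; binary masks by fractional occupancy
    followed by a 0.5 threshold (ties count as set, conservative toward
    lesion retention).
    """
    if any(t < s - 1e-9 for t, s in zip(target.spacing, vol.spacing)):
        raise ValueError("target spacing must be >= source spacing on every axis")
    if isinstance(vol, BinaryMask):
        occ, _ = _bin_average(vol.data.astype(np.float64), vol.spacing, target.spacing)
        return BinaryMask(occ >= 0.5 - 1e-12, target.spacing)
    avg, _ = _bin_average(vol.data, vol.spacing, target.spacing)
    ms = min(avg.shape[LR_AXIS] // 2, avg.shape[LR_AXIS] - 1)
    return CTVolume(avg, target.spacing, midsagittal_index=ms)


# ---------------------------------------------------------------------------
# Mirror pairing


def mirror_pair(idx: tuple[int, int, int], vol: CTVolume) -> tuple[int, int, int] | None:
    """Reflect a voxel index about the mid-sagittal plane along the LR axis.

    Returns ``None`` when the reflection falls outside the grid. An index on
    the plane maps to itself.
    """
    i, j, k = idx
    if not (0 <= i < vol.shape[0] and 0 <= j < vol.shape[1] and 0 <= k < vol.shape[2]):
        raise IndexError(f"index {idx} outside grid {vol.shape}")
    ri = 2 * vol.midsagittal_index - i
    if not 0 <= ri < vol.shape[LR_AXIS]:
        return None
    return (ri, j, k)


def mirror_lr(data: np.ndarray, midsagittal_index: int) -> np.ndarray:
    """Array-level mirror about the mid-sagittal column.

    Voxels whose reflection falls outside the grid receive the fill value 0
    (False for boolean arrays).
    """
    n = data.shape[LR_AXIS]
    src = 2 * midsagittal_index - np.arange(n)
    inside = (src >= 0) & (src < n)
    out = np.zeros_like(data)
    out[inside] = data[src[inside]]
    return out
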