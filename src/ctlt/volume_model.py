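"""Core volumetric containers and mask algebra for CT lung densitometry.

Every quantity in this package is computed from two primitives defined here:
a scalar lattice of Hounsfield units (:class:`CTVolume`) and an aligned
boolean selection (:class:`VoxelMask`).  All lattices are ``(z, y, x)`` with
axial slices along ``z`` and 0-based indexing; voxel spacing is in mm and
region volumes are reported in millilitres (mm**3 / 1000).

The statistics functions implement exact volume-weighted accounting: the mean
HU of a union of disjoint regions equals the "mean x volume" sums pooled and
divided by the pooled volume, so splitting a region and recombining it is
lossless up to floating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EmptyRegionError",
    "MaskAlignmentError",
    "CTVolume",
    "VoxelMask",
    "LungMeasurement",
    "RoiSpec",
    "mask_statistics",
    "combine_statistics",
    "roi_mean_hu",
    "hu_window_mask",
]


class EmptyRegionError(ValueError):
    """A statistic was requested over a region containing no voxels."""


class MaskAlignmentError(ValueError):
    """A mask does not share the lattice shape of its volume or peer mask."""


@dataclass(frozen=True)
class CTVolume:
    """A 3D scalar field of CT numbers (HU) with physical voxel spacing.

    Parameters
    ----------
    values
        3D array of Hounsfield units, axis order ``(z, y, x)``.
    spacing
        Per-axis voxel edge length in mm, ordered ``(z, y, x)``; all > 0.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"CTVolume requires a 3D array, got ndim={values.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths (mm), got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class VoxelMask:
    """A boolean selection aligned to a :class:`CTVolume` lattice."""

    selected: np.ndarray

    def __post_init__(self) -> None:
        selected = np.asarray(self.selected)
        if selected.dtype != bool:
            selected = selected.astype(bool)
        if selected.ndim != 3:
            raise ValueError(f"VoxelMask requires a 3D array, got ndim={selected.ndim}")
        object.__setattr__(self, "selected", selected)

    @classmethod
    def empty(cls, shape: Sequence[int]) -> "VoxelMask":
        return cls(np.zeros(tuple(shape), dtype=bool))

    @classmethod
    def full(cls, shape: Sequence[int]) -> "VoxelMask":
        return cls(np.ones(tuple(shape), dtype=bool))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.selected.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        """Number of selected voxels."""
        return int(self.selected.sum())

    def _require_aligned(self, shape: Sequence[int], what: str = "mask") -> None:
        if tuple(self.shape) != tuple(shape):
            raise MaskAlignmentError(
                f"{what} shape {tuple(shape)} does not match mask shape {self.shape}"
            )

    def union(self, other: "VoxelMask") -> "VoxelMask":
        self._require_aligned(other.shape, "peer mask")
        return VoxelMask(self.selected | other.selected)

    def intersection(self, other: "VoxelMask") -> "VoxelMask":
        self._require_aligned(other.shape, "peer mask")
        return VoxelMask(self.selected & other.selected)

    def difference(self, other: "VoxelMask") -> "VoxelMask":
        self._require_aligned(other.shape, "peer mask")
        return VoxelMask(self.selected & ~other.selected)

    __or__ = union
    __and__ = intersection
    __sub__ = difference


@dataclass(frozen=True)
class LungMeasurement:
    """The (total volume, mean CT number) pair the mixing model consumes.

    ``volume_ml`` is the measured region volume in ml; ``mean_hu`` its
    arithmetic mean CT number.  After the final extraction window the mean
    lies in [-1000, +100] HU, but intermediate measurements are unrestricted.
    """

    volume_ml: float
    mean_hu: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.volume_ml) or self.volume_ml < 0:
            raise ValueError(f"volume_ml must be finite and >= 0, got {self.volume_ml}")
        if not np.isfinite(self.mean_hu):
            raise ValueError(f"mean_hu must be finite, got {self.mean_hu}")


@dataclass(frozen=True)
class RoiSpec:
    """A circular in-plane region of interest on one axial slice.

    ``center_mm`` is the (y, x) disc centre in mm; voxel in-plane centres sit
    at ``index * spacing``.  The default diameter band 10-25 mm reflects the
    clinical convention of 1-2.5 cm discs for trachea/atelectasis sampling.
    """

    slice_index: int
    center_mm: tuple[float, float]
    diameter_mm: float
    diameter_band: tuple[float, float] = field(default=(10.0, 25.0))

    def __post_init__(self) -> None:
        lo, hi = self.diameter_band
        if not (lo <= self.diameter_mm <= hi):
            raise ValueError(
                f"ROI diameter {self.diameter_mm} mm outside allowed band [{lo}, {hi}] mm"
            )


def mask_statistics(volume: CTVolume, mask: VoxelMask) -> LungMeasurement:
    """Volume (ml) and mean HU of the voxels selected by ``mask``.

    Raises
    ------
    EmptyRegionError
        If the mask selects no voxels (never returns NaN silently).
    """
    mask._require_aligned(volume.shape, "volume")
    n = mask.count
    if n == 0:
        raise EmptyRegionError("cannot compute statistics over an empty region")
    mean = float(volume.values[mask.selected].mean())
    return LungMeasurement(volume_ml=n * volume.voxel_volume_ml, mean_hu=mean)


def combine_statistics(parts: Iterable[LungMeasurement]) -> LungMeasurement:
    """Pool disjoint region measurements by exact volume weighting.

    The pooled mean is sum(mean_i * vol_i) / sum(vol_i) — the "mean CT number
    x volume" bookkeeping that lets a region be measured piecewise.  Parts
    must describe disjoint regions (caller contract).
    """
    parts = list(parts)
    total = sum(p.volume_ml for p in parts)
    if not parts or total <= 0:
        raise EmptyRegionError("combined region has zero volume")
    weighted = sum(p.mean_hu * p.volume_ml for p in parts)
    return LungMeasurement(volume_ml=total, mean_hu=weighted / total)


def roi_mean_hu(volume: CTVolume, roi: RoiSpec) -> float:
    """Mean HU over a circular ROI on one axial slice.

    A voxel belongs to the disc when its in-plane centre (at index * spacing)
    lies within the disc; the disc must fit entirely inside the slice.
    """
    nz, ny, nx = volume.shape
    if not (0 <= roi.slice_index < nz):
        raise ValueError(f"slice_index {roi.slice_index} outside volume (nz={nz})")
    sy, sx = volume.spacing[1], volume.spacing[2]
    cy, cx = roi.center_mm
    r = roi.diameter_mm / 2.0
    if cy - r < 0 or cx - r < 0 or cy + r > (ny - 1) * sy or cx + r > (nx - 1) * sx:
        raise ValueError("ROI disc is not fully inside the slice")
    yy = np.arange(ny)[:, None] * sy
    xx = np.arange(nx)[None, :] * sx
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    if not disc.any():
        raise EmptyRegionError("ROI disc selects no voxel centres")
    return float(volume.values[roi.slice_index][disc].mean())


def hu_window_mask(volume: CTVolume, base: VoxelMask, lo: float, hi: float) -> VoxelMask:
    """Subset of ``base`` whose HU lies in the inclusive window [lo, hi]."""
    if lo > hi:
        raise ValueError(f"window lower bound {lo} exceeds upper bound {hi}")
    base._require_aligned(volume.shape, "volume")
    return VoxelMask(base.selected & (volume.values >= lo) & (volume.values <= hi))
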