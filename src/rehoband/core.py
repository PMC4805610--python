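"""Shared containers for masked BOLD volumes and derived maps."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


def as_voxel_size(value) -> np.ndarray:
    """Coerce a scalar or length-3 sequence into a (3,) array of voxel edges [mm]."""
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.shape != (3,) or np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError(f"voxel size must be a positive scalar or 3-vector, got {value!r}")
    return arr


@dataclass
class BoldSeries:
    """A masked 4D BOLD time series.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal values in arbitrary units.
    tr_s : float
        Repetition time in seconds; the sampling interval of the time axis.
    voxel_size_mm : float or (3,) array
        Voxel edge lengths in millimetres.
    mask : ndarray of bool, shape (x, y, z), optional
        Analysis mask. ``None`` means every voxel is inside.
    """

    data: np.ndarray
    tr_s: float
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.ones(3) * 3.0)
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x, y, z, t), got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("a BOLD series needs at least 2 time points")
        if not (np.isfinite(self.tr_s) and self.tr_s > 0):
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        self.voxel_size_mm = as_voxel_size(self.voxel_size_mm)
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match spatial shape {self.data.shape[:3]}"
            )
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("non-finite values inside the mask")

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        """Return a new series with the same metadata and different data."""
        return BoldSeries(data, self.tr_s, self.voxel_size_mm.copy(), self.mask.copy())


@dataclass
class ReHoMap:
    """A 3D per-voxel Kendall's-W map, raw (W in [0, 1]) or z-standardized."""

    values: np.ndarray
    mask: np.ndarray
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.ones(3) * 3.0)
    standardized: bool = False
    band: Optional[object] = None  # BandSpec, kept loose to avoid an import cycle
    subject_id: Optional[str] = None
    state: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3 or self.values.shape != self.mask.shape:
            raise ValueError("ReHoMap values and mask must be matching 3D grids")
        self.voxel_size_mm = as_voxel_size(self.voxel_size_mm)
        if not self.standardized:
            inside = self.values[self.mask]
            if inside.size and (inside.min() < -1e-9 or inside.max() > 1 + 1e-9):
                raise ValueError("raw Kendall's W values must lie in [0, 1] within the mask")

    def with_values(self, values: np.ndarray, standardized: Optional[bool] = None) -> "ReHoMap":
        return ReHoMap(
            values,
            self.mask.copy(),
            self.voxel_size_mm.copy(),
            self.standardized if standardized is None else standardized,
            self.band,
            self.subject_id,
            self.state,
        )
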