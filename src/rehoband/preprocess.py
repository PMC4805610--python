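"""Temporal preprocessing of BOLD series.

Order of operations in the pipeline: volume trimming -> nuisance regression ->
linear detrend + ideal band-pass filtering. Spatial steps (realignment,
normalization, slice timing) are out of scope; phantoms are aligned by
construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import detrend as _linear_detrend

from .bands import band_bin_keep, get_band
from .core import BoldSeries

logger = logging.getLogger(__name__)

#: head radius (mm) used to convert rotations (radians) into displacements when
#: summarising motion as mean framewise displacement.
FD_ROTATION_RADIUS_MM = 50.0


# ---------------------------------------------------------------------------
# volume trimming
# ---------------------------------------------------------------------------

def trim_volumes(series: BoldSeries, n_discard: int) -> BoldSeries:
    """Drop the first ``n_discard`` volumes (scanner equilibration period).

    Resting runs of 200 volumes trimmed by 46 and task runs of 163 volumes
    trimmed by 9 both leave 154 volumes, equalising the two states.
    """
    n_discard = int(n_discard)
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= series.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_volumes} volumes"
        )
    if n_discard == 0:
        return series.with_data(series.data.copy())
    return series.with_data(series.data[..., n_discard:])


# ---------------------------------------------------------------------------
# motion quality control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionQC:
    """Outcome of head-motion screening for one scan."""

    passed: bool
    max_translation_mm: float
    mean_fd_mm: float
    threshold_mm: float


def mean_framewise_displacement(params: np.ndarray, radius_mm: float = FD_ROTATION_RADIUS_MM) -> float:
    """Mean framewise displacement from t x 6 rigid-body parameters.

    Columns 0-2 are translations in mm, columns 3-5 rotations in radians;
    rotations are converted to arc lengths on a sphere of ``radius_mm``.
    FD at each frame is the sum of absolute backward differences.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(f"motion parameters must be t x 6, got shape {params.shape}")
    scaled = params.copy()
    scaled[:, 3:] *= radius_mm
    fd = np.abs(np.diff(scaled, axis=0)).sum(axis=1)
    return float(fd.mean()) if fd.size else 0.0


def motion_qc(motion_params, threshold_mm: float = 3.0) -> MotionQC:
    """Screen a scan for excessive head motion.

    A scan fails when any translation's absolute excursion reaches
    ``threshold_mm`` (the inclusion rule is strict: motion must stay *below*
    the threshold). Also returns mean framewise displacement, the scalar
    motion summary used as a covariate downstream.
    """
    if isinstance(motion_params, pd.DataFrame):
        motion_params = motion_params.to_numpy()
    params = np.asarray(motion_params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6 or not np.all(np.isfinite(params)):
        raise ValueError("motion table must be a finite t x 6 array "
                         "(3 translations in mm, 3 rotations in radians)")
    max_translation = float(np.abs(params[:, :3]).max()) if len(params) else 0.0
    passed = max_translation < threshold_mm
    return MotionQC(
        passed=passed,
        max_translation_mm=max_translation,
        mean_fd_mm=mean_framewise_displacement(params),
        threshold_mm=float(threshold_mm),
    )


# ---------------------------------------------------------------------------
# nuisance regression
# ---------------------------------------------------------------------------

def _drop_collinear(design: np.ndarray, labels: list) -> tuple:
    """Greedily keep a maximal linearly independent subset of columns."""
    keep = [0]  # intercept always stays
    for j in range(1, design.shape[1]):
        cand = design[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            warnings.warn(
                f"dropping collinear nuisance regressor {labels[j]!r}",
                RuntimeWarning,
                stacklevel=3,
            )
            logger.warning("dropping collinear nuisance regressor %r", labels[j])
    return design[:, keep], [labels[j] for j in keep]


def regress_nuisance(series: BoldSeries, nuisance) -> BoldSeries:
    """Remove nuisance signals by voxel-wise least squares.

    ``nuisance`` is a t x q table (DataFrame or array) of regressors, e.g. six
    rigid-body motion parameters plus global / white-matter / CSF mean
    signals. An intercept is added; each in-mask voxel is replaced by its
    residual, which is orthogonal to every retained regressor. Out-of-mask
    voxels are zeroed.
    """
    if isinstance(nuisance, pd.DataFrame):
        labels = [str(c) for c in nuisance.columns]
        reg = nuisance.to_numpy(dtype=float)
    else:
        reg = np.asarray(nuisance, dtype=float)
        if reg.ndim == 1:
            reg = reg[:, None]
        labels = [f"reg{j}" for j in range(reg.shape[1])]
    if reg.ndim != 2 or reg.shape[0] != series.n_volumes:
        raise ValueError(
            f"nuisance table has {reg.shape[0] if reg.ndim == 2 else 'bad'} rows, "
            f"series has {series.n_volumes} volumes"
        )
    if not np.all(np.isfinite(reg)):
        raise ValueError("nuisance regressors contain non-finite values")

    design = np.column_stack([np.ones(series.n_volumes), reg])
    design, _ = _drop_collinear(design, ["intercept"] + labels)

    y = series.data[series.mask].T  # (t, V)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta

    out = np.zeros_like(series.data)
    out[series.mask] = resid.T
    return series.with_data(out)


# ---------------------------------------------------------------------------
# ideal band-pass filtering
# ---------------------------------------------------------------------------

def ideal_bandpass_array(
    x: np.ndarray, tr_s: float, band, detrend: bool = True
) -> np.ndarray:
    """Ideal rectangular band-pass along the last axis.

    Linear detrend (optional), forward real FFT, zero every bin outside the
    band (kept iff ``f_low < f <= f_high``), inverse transform. The
    bin-selection convention makes the named bands tile (0, Nyquist] exactly,
    so variance is partitioned across disjoint bands (Parseval).
    """
    band = get_band(band)
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if detrend:
        x = _linear_detrend(x, axis=-1, type="linear")
    spec = np.fft.rfft(x, axis=-1)
    keep = band_bin_keep(n, tr_s, band)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def bandpass(series: BoldSeries, band, detrend: bool = True) -> BoldSeries:
    """Band-limit every voxel's series to ``band`` with the ideal DFT filter."""
    band = get_band(band)
    if band.f_high > series.nyquist_hz + 1e-9:
        raise ValueError(
            f"band {band.name} upper edge {band.f_high} Hz exceeds the Nyquist "
            f"frequency {series.nyquist_hz} Hz at TR = {series.tr_s} s"
        )
    filtered = ideal_bandpass_array(series.data, series.tr_s, band, detrend=detrend)
    filtered[~series.mask] = 0.0
    return series.with_data(filtered)
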