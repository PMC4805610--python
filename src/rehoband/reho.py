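"""Regional homogeneity: voxel-wise Kendall's coefficient of concordance (KCC).

ReHo quantifies local temporal synchrony as Kendall's W between a voxel's
BOLD time series and those of its nearest neighbours (26 by default, i.e.
faces + edges + corners of the 3x3x3 cube). With k series of length n, average
ranks for ties, rank sums R_t per time point and S = sum_t (R_t - mean R)^2:

    W = 12 S / (k^2 (n^3 - n) - k * sum(T))

where T = sum(t^3 - t) over tie groups of size t within each series. W lies in
[0, 1]; under independence E[W] = 1/k and k(n-1)W approximately follows a
chi-square with n-1 degrees of freedom (the Friedman statistic).

ReHo is computed on *unsmoothed* band-filtered data; the map is then
z-standardized within the brain mask and only afterwards spatially smoothed.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .core import BoldSeries, ReHoMap

logger = logging.getLogger(__name__)

#: FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

_SCHEMES = (6, 18, 26)


def neighbourhood_offsets(connectivity: int = 26) -> np.ndarray:
    """Offsets (m, 3) of the neighbourhood scheme, excluding the centre.

    6 = faces only, 18 = faces + edges, 26 = faces + edges + corners.
    """
    if connectivity not in _SCHEMES:
        raise ValueError(f"connectivity must be one of {_SCHEMES}, got {connectivity}")
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    struct = ndimage.generate_binary_structure(3, order)
    offs = np.argwhere(struct) - 1
    return offs[np.any(offs != 0, axis=1)]


def neighborhood(voxel, mask: np.ndarray, connectivity: int = 26) -> list:
    """In-mask neighbours of ``voxel`` under the scheme, excluding the centre.

    At mask borders the available subset is returned (so k varies there).
    """
    mask = np.asarray(mask, dtype=bool)
    voxel = tuple(int(v) for v in voxel)
    if len(voxel) != 3:
        raise ValueError("voxel must be a 3D grid coordinate")
    if not all(0 <= voxel[i] < mask.shape[i] for i in range(3)):
        raise ValueError(f"voxel {voxel} outside the grid {mask.shape}")
    if not mask[voxel]:
        raise ValueError(f"voxel {voxel} is outside the mask")
    out = []
    for off in neighbourhood_offsets(connectivity):
        nb = tuple(voxel[i] + int(off[i]) for i in range(3))
        if all(0 <= nb[i] < mask.shape[i] for i in range(3)) and mask[nb]:
            out.append(nb)
    return out


# ---------------------------------------------------------------------------
# Kendall's W
# ---------------------------------------------------------------------------

def _tie_correction_1d(x: np.ndarray) -> float:
    _, counts = np.unique(x, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kendalls_w(series_set) -> float:
    """Kendall's coefficient of concordance for k time series of length n.

    Ranks are averaged over ties and the denominator is tie-corrected. If the
    denominator vanishes (every series constant) the statistic is undefined
    and 0 is returned with a log message.
    """
    x = np.asarray(series_set, dtype=float)
    if x.ndim != 2:
        raise ValueError("series_set must be a (k, n) array")
    k, n = x.shape
    if k < 2 or n < 2:
        raise ValueError(f"need k >= 2 series of n >= 2 points, got k={k}, n={n}")
    ranks = rankdata(x, axis=1)
    if np.any(np.ptp(x, axis=1) == 0):
        logger.warning("kendalls_w: constant series present; tie correction applied")
    rank_sums = ranks.sum(axis=0)
    s = float(np.sum((rank_sums - k * (n + 1) / 2.0) ** 2))
    tie = sum(_tie_correction_1d(row) for row in x)
    denom = k * k * (n**3 - n) - k * tie
    if denom <= 0:
        logger.warning("kendalls_w: degenerate denominator (all series constant); returning 0")
        return 0.0
    return float(np.clip(12.0 * s / denom, 0.0, 1.0))


def _ranks_and_ties(data: np.ndarray) -> tuple:
    """Vectorised average ranks along the last axis plus tie corrections.

    Fast path assumes no ties (true for continuous BOLD data); rows with ties
    are re-ranked individually with average ranks.
    """
    n = data.shape[-1]
    order = np.argsort(data, axis=-1, kind="stable")
    ranks = np.empty(data.shape, dtype=np.float64)
    np.put_along_axis(
        ranks, order, np.broadcast_to(np.arange(1.0, n + 1.0), data.shape), axis=-1
    )
    srt = np.take_along_axis(data, order, axis=-1)
    has_tie = np.any(srt[..., 1:] == srt[..., :-1], axis=-1)
    ties = np.zeros(data.shape[:-1], dtype=np.float64)
    if np.any(has_tie):
        for idx in map(tuple, np.argwhere(has_tie)):
            ranks[idx] = rankdata(data[idx])
            ties[idx] = _tie_correction_1d(data[idx])
    return ranks, ties


def _shifted_slices(shape, off):
    dst, src = [], []
    for size, d in zip(shape, off):
        d = int(d)
        if d >= 0:
            dst.append(slice(0, size - d))
            src.append(slice(d, size))
        else:
            dst.append(slice(-d, size))
            src.append(slice(0, size + d))
    return tuple(dst), tuple(src)


def reho_map(series: BoldSeries, connectivity: int = 26) -> ReHoMap:
    """Voxel-wise Kendall's W over each voxel plus its in-mask neighbours.

    k = 1 + |in-mask neighbours| varies at mask borders (minimum 2; isolated
    voxels get W = 0). Expects unsmoothed, band-filtered data.
    """
    mask = series.mask
    if not mask.any():
        raise ValueError("empty mask")
    data = series.data
    n = series.n_volumes

    ranks, ties = _ranks_and_ties(data)
    maskf = mask.astype(np.float64)
    ranks *= maskf[..., None]
    ties *= maskf

    spatial = series.spatial_shape
    rank_sum = np.zeros(data.shape, dtype=np.float64)
    k_map = np.zeros(spatial, dtype=np.float64)
    tie_sum = np.zeros(spatial, dtype=np.float64)
    offsets = np.vstack([[0, 0, 0], neighbourhood_offsets(connectivity)])
    for off in offsets:
        dst, src = _shifted_slices(spatial, off)
        rank_sum[dst] += ranks[src]
        k_map[dst] += maskf[src]
        tie_sum[dst] += ties[src]

    mean_rank = k_map[..., None] * (n + 1) / 2.0
    s = ((rank_sum - mean_rank) ** 2).sum(axis=-1)
    denom = k_map**2 * (n**3 - n) - k_map * tie_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 12.0 * s / denom
    w[~np.isfinite(w)] = 0.0
    w[denom <= 0] = 0.0
    isolated = mask & (k_map < 2)
    if isolated.any():
        logger.warning("reho_map: %d isolated voxels set to W = 0", int(isolated.sum()))
        w[isolated] = 0.0
    w[~mask] = 0.0
    np.clip(w, 0.0, 1.0, out=w)
    return ReHoMap(w, mask.copy(), series.voxel_size_mm.copy(), standardized=False)


# ---------------------------------------------------------------------------
# standardization and smoothing
# ---------------------------------------------------------------------------

def standardize(rmap: ReHoMap) -> ReHoMap:
    """Subject-wise z-standardization within the mask (sample SD, ddof=1).

    z = (W - mean_mask) / SD_mask; out-of-mask voxels are zero. Improves
    across-subject comparability of ReHo maps.
    """
    if rmap.standardized:
        raise ValueError("map is already standardized")
    inside = rmap.values[rmap.mask]
    if inside.size < 2:
        raise ValueError("standardization needs at least two in-mask voxels")
    sd = inside.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant map (zero SD)")
    z = np.zeros_like(rmap.values)
    z[rmap.mask] = (inside - inside.mean()) / sd
    return rmap.with_values(z, standardized=True)


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    voxel = np.atleast_1d(np.asarray(voxel_size_mm, dtype=float))
    if voxel.size == 1:
        voxel = np.repeat(voxel, 3)
    return fwhm_mm / (voxel * FWHM_PER_SIGMA)


def smooth(rmap: ReHoMap, fwhm_mm: float) -> ReHoMap:
    """3D Gaussian smoothing of a (standardized) map; mask re-applied after.

    ``fwhm_mm = 0`` is the identity. Smoothing is applied to the standardized
    map, never to the time series entering the KCC.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return rmap.with_values(rmap.values.copy())
    sigma = fwhm_to_sigma_voxels(fwhm_mm, rmap.voxel_size_mm)
    out = ndimage.gaussian_filter(rmap.values, sigma=sigma, mode="constant", cval=0.0)
    out[~rmap.mask] = 0.0
    return rmap.with_values(out)
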