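"""Voxel-wise group x state interaction mapping with cluster-extent correction.

The 2 (group) x 2 (state) repeated-measures interaction with subject-constant
covariates is fitted on *difference scores*: for each subject the task-minus-
rest map d_i is regressed on [intercept | group indicator | covariates]; the
squared t of the group coefficient is the interaction F with df (1, N - q).
For a balanced 2x2 design with state-invariant covariates this is algebraically
identical to the mixed-model interaction test (the within-subject state factor
is eliminated by differencing, which also absorbs any state main effect).

Multiple comparisons are handled by an AlphaSim-style Monte-Carlo: smooth
Gaussian noise fields are thresholded at the voxel p-level and the null
distribution of the maximum cluster extent yields the minimum cluster size k*
controlling the family-wise rate at alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .reho import fwhm_to_sigma_voxels

DEFAULT_COVARIATES = ("age", "sex", "education", "motion")


def connectivity_structure(connectivity: int) -> np.ndarray:
    """scipy.ndimage binary structure for 6/18/26 cluster connectivity."""
    try:
        order = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}") from None
    return ndimage.generate_binary_structure(3, order)


# ---------------------------------------------------------------------------
# difference scores and the interaction map
# ---------------------------------------------------------------------------

def state_difference(task_map: np.ndarray, rest_map: np.ndarray) -> np.ndarray:
    """Voxel-wise state-related change: task minus rest."""
    task_map = np.asarray(task_map, dtype=float)
    rest_map = np.asarray(rest_map, dtype=float)
    if task_map.shape != rest_map.shape:
        raise ValueError(
            f"shape mismatch: task {task_map.shape} vs rest {rest_map.shape}"
        )
    return task_map - rest_map


@dataclass
class InteractionResult:
    """Uncorrected voxel-wise interaction F/p maps plus threshold bookkeeping."""

    f_map: np.ndarray
    p_map: np.ndarray
    df: tuple
    group_beta: np.ndarray
    design_columns: list
    voxel_p_threshold: Optional[float] = None
    cluster_extent_threshold: Optional[int] = None
    clusters: Optional[pd.DataFrame] = None


def _build_design(design: pd.DataFrame, covariates, group_col: str, groups) -> tuple:
    if group_col not in design.columns:
        raise ValueError(f"design table lacks the {group_col!r} column")
    labels = design[group_col].to_numpy()
    present = pd.unique(labels)
    if groups is None:
        groups = tuple(present)
    if len(groups) != 2 or not set(present) <= set(groups):
        raise ValueError(f"need exactly two groups {groups}, design has {list(present)}")
    for g in groups:
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")
    indicator = (labels == groups[1]).astype(float)
    cols = [np.ones(len(design)), indicator]
    names = ["intercept", f"group[{groups[1]}]"]
    for cov in covariates or ():
        vals = design[cov].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"covariate {cov!r} contains non-finite values")
        cols.append(vals)
        names.append(cov)
    x = np.column_stack(cols)
    keep = [0, 1]
    for j in range(2, x.shape[1]):
        if np.linalg.matrix_rank(x[:, keep + [j]]) > len(keep):
            keep.append(j)
        else:
            warnings.warn(
                f"dropping collinear covariate {names[j]!r}", RuntimeWarning, stacklevel=3
            )
    if np.linalg.matrix_rank(x[:, keep]) < len(keep):
        raise ValueError("group indicator is collinear with the intercept/covariates")
    return x[:, keep], [names[j] for j in keep], groups


def interaction_map(
    diffs: np.ndarray,
    design: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    mask: Optional[np.ndarray] = None,
    group_col: str = "group",
    groups: Optional[tuple] = None,
) -> InteractionResult:
    """Group x state interaction F/p at every voxel from difference scores.

    Parameters
    ----------
    diffs : ndarray, shape (N, x, y, z)
        Per-subject task-minus-rest maps, rows aligned with ``design``.
    design : DataFrame
        One row per subject with ``group`` and covariate columns.
    covariates : sequence of str
        Subject-constant covariate columns (collinear ones are dropped with a
        warning). Pass ``()`` for none.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 4:
        raise ValueError("diffs must be (N, x, y, z)")
    n = diffs.shape[0]
    if n != len(design):
        raise ValueError("diffs rows and design rows do not match")
    spatial = diffs.shape[1:]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)

    x, names, groups = _build_design(design, covariates, group_col, groups)
    q = x.shape[1]
    dof = n - q
    if dof < 1:
        raise ValueError(f"not enough subjects ({n}) for {q} design columns")

    d = diffs[:, mask]  # (N, V)
    pinv = np.linalg.pinv(x)
    beta = pinv @ d
    resid = d - x @ beta
    rss = np.einsum("nv,nv->v", resid, resid)
    sigma2 = rss / dof
    c_gg = np.linalg.inv(x.T @ x)[1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = beta[1] ** 2 / (sigma2 * c_gg)
    zero_var = sigma2 <= 0
    f[zero_var & (beta[1] == 0)] = 0.0
    f[zero_var & (beta[1] != 0)] = np.inf
    p = stats.f.sf(f, 1, dof)
    p[zero_var & (beta[1] == 0)] = 1.0

    f_map = np.zeros(spatial)
    p_map = np.ones(spatial)
    b_map = np.zeros(spatial)
    f_map[mask] = f
    p_map[mask] = p
    b_map[mask] = beta[1]
    return InteractionResult(f_map, p_map, (1, dof), b_map, names)


# ---------------------------------------------------------------------------
# Monte-Carlo cluster-extent threshold (AlphaSim-style)
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloResult:
    """Null distribution of the maximum suprathreshold cluster extent."""

    k_star: int
    alpha: float
    p_voxel: float
    fwhm_mm: np.ndarray  # scalar or per-axis FWHM as given
    connectivity: int
    n_iter: int
    max_cluster_sizes: np.ndarray = field(repr=False)
    mean_suprathreshold: float = 0.0


def monte_carlo_cluster_threshold(
    mask: np.ndarray,
    fwhm_mm: float,
    p_voxel: float,
    alpha: float,
    n_iter: int = 1000,
    connectivity: int = 18,
    voxel_size_mm=3.0,
    seed=None,
    rng: Optional[np.random.Generator] = None,
) -> MonteCarloResult:
    """Minimum cluster extent k* controlling the family-wise rate at ``alpha``.

    Each iteration fills the mask with white Gaussian noise, smooths it to
    ``fwhm_mm``, re-standardizes within the mask, thresholds at the upper
    z-quantile of ``p_voxel``, labels clusters and records the maximum
    extent. k* is the smallest k with P(max extent >= k) <= alpha.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    if not (0 < p_voxel < 1):
        raise ValueError("p_voxel must lie in (0, 1)")
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if rng is None:
        rng = np.random.default_rng(seed)
    structure = connectivity_structure(connectivity)
    fwhm_arr = np.atleast_1d(np.asarray(fwhm_mm, dtype=float))
    sigma = fwhm_to_sigma_voxels(fwhm_arr, voxel_size_mm) if np.any(fwhm_arr > 0) else None
    z_thresh = stats.norm.isf(p_voxel)

    max_sizes = np.zeros(n_iter, dtype=int)
    total_supra = 0
    for i in range(n_iter):
        field_ = rng.standard_normal(mask.shape)
        if sigma is not None:
            field_ = ndimage.gaussian_filter(field_, sigma=sigma, mode="constant")
        inside = field_[mask]
        inside = (inside - inside.mean()) / inside.std(ddof=1)
        binary = np.zeros(mask.shape, dtype=bool)
        binary[mask] = inside > z_thresh
        total_supra += int(binary.sum())
        labels, n_lab = ndimage.label(binary, structure=structure)
        if n_lab:
            max_sizes[i] = np.bincount(labels.ravel())[1:].max()

    k = 1
    while (max_sizes >= k).mean() > alpha:
        k += 1
    return MonteCarloResult(
        k_star=int(k),
        alpha=float(alpha),
        p_voxel=float(p_voxel),
        fwhm_mm=fwhm_arr if fwhm_arr.size > 1 else float(fwhm_arr[0]),
        connectivity=connectivity,
        n_iter=n_iter,
        max_cluster_sizes=max_sizes,
        mean_suprathreshold=total_supra / n_iter,
    )


def estimate_map_fwhm(maps: np.ndarray, mask: np.ndarray, voxel_size_mm=3.0) -> np.ndarray:
    """Per-axis smoothness (FWHM, mm) of residual maps from gradient variance.

    Classic Gaussian-field estimate: for unit-variance fields,
    ``fwhm = voxel * sqrt(-2 ln 2 / ln(1 - var(diff) / (2 var)))`` along each
    axis. Useful when the maps entering the cluster correction are smoother
    than the applied kernel (ReHo maps carry intrinsic smoothness because
    neighbouring voxels share most of their neighbourhood series); pass the
    result to :func:`monte_carlo_cluster_threshold` instead of the nominal
    FWHM for a better-calibrated extent threshold.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 3:
        maps = maps[None]
    mask = np.asarray(mask, dtype=bool)
    voxel = np.atleast_1d(np.asarray(voxel_size_mm, float))
    if voxel.size == 1:
        voxel = np.repeat(voxel, 3)
    fwhm = np.zeros(3)
    for axis in range(3):
        pair = mask & np.roll(mask, -1, axis=axis)
        pair[tuple(slice(None) if a != axis else slice(-1, None) for a in range(3))] = False
        ratios = []
        for m in maps:
            inside = m[mask]
            var = inside.var()
            d = (np.roll(m, -1, axis=axis) - m)[pair]
            if var > 0 and d.size:
                ratios.append(d.var() / (2.0 * var))
        ratio = float(np.mean(ratios)) if ratios else 1.0
        if ratio >= 1.0 or ratio <= 0.0:
            fwhm[axis] = 0.0  # rougher than voxel scale; no resolvable smoothness
        else:
            fwhm[axis] = voxel[axis] * np.sqrt(-2.0 * np.log(2.0) / np.log(1.0 - ratio))
    return fwhm


# ---------------------------------------------------------------------------
# cluster extraction and post-hoc tests
# ---------------------------------------------------------------------------

def extract_clusters(
    stat_map: np.ndarray,
    p_map: np.ndarray,
    p_voxel: float,
    extent_threshold: int,
    connectivity: int = 18,
    mask: Optional[np.ndarray] = None,
    positive_only: bool = False,
) -> tuple:
    """Label suprathreshold clusters and keep those of size >= k*.

    Returns ``(table, labels)`` where ``table`` has one row per retained
    cluster (label, size, peak statistic, peak grid coordinate; peak ties
    broken by the first voxel in lexicographic grid order) and ``labels`` is
    the relabelled cluster volume (0 = background).
    """
    stat_map = np.asarray(stat_map, dtype=float)
    p_map = np.asarray(p_map, dtype=float)
    binary = p_map < p_voxel
    if positive_only:
        binary &= stat_map > 0
    if mask is not None:
        binary &= np.asarray(mask, dtype=bool)
    labels, n_lab = ndimage.label(binary, structure=connectivity_structure(connectivity))
    rows = []
    out_labels = np.zeros_like(labels)
    next_id = 0
    sizes = np.bincount(labels.ravel()) if n_lab else np.array([0])
    order = np.argsort(sizes[1:])[::-1] + 1 if n_lab else []
    for lab in order:
        size = int(sizes[lab])
        if size < extent_threshold:
            continue
        next_id += 1
        coords = np.argwhere(labels == lab)  # lexicographic order
        vals = stat_map[tuple(coords.T)]
        peak = coords[int(np.argmax(vals))]
        out_labels[labels == lab] = next_id
        rows.append(
            {
                "label": next_id,
                "size": size,
                "peak_stat": float(vals.max()),
                "peak_x": int(peak[0]),
                "peak_y": int(peak[1]),
                "peak_z": int(peak[2]),
            }
        )
    table = pd.DataFrame(
        rows, columns=["label", "size", "peak_stat", "peak_x", "peak_y", "peak_z"]
    )
    return table, out_labels


def cluster_cell_means(
    rest_maps: np.ndarray, task_maps: np.ndarray, cluster_voxels: np.ndarray, design: pd.DataFrame
) -> pd.DataFrame:
    """Per-subject mean map value over a cluster, per state.

    ``cluster_voxels`` is an (m, 3) array of grid coordinates. Returns a table
    with columns subject_id, group, rest, task, change (task - rest).
    """
    cluster_voxels = np.asarray(cluster_voxels, dtype=int)
    if cluster_voxels.size == 0:
        raise ValueError("empty cluster")
    idx = tuple(cluster_voxels.T)
    rest = np.asarray(rest_maps)[:, idx[0], idx[1], idx[2]].mean(axis=1)
    task = np.asarray(task_maps)[:, idx[0], idx[1], idx[2]].mean(axis=1)
    return pd.DataFrame(
        {
            "subject_id": design["subject_id"].to_numpy(),
            "group": design["group"].to_numpy(),
            "rest": rest,
            "task": task,
            "change": task - rest,
        }
    )


def posthoc_t(cell_means: pd.DataFrame, groups: tuple = ("NC", "MCI")) -> pd.DataFrame:
    """Post-hoc t-tests on cluster-mean values for a significant cluster.

    Per state: two-sample t between groups (pooled variance). Per group:
    paired t between states, with the direction of the task-vs-rest change.
    Together these characterise the interaction pattern (which cells rise or
    fall).
    """
    for g in groups:
        if (cell_means["group"] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    rows = []
    a = cell_means[cell_means["group"] == groups[0]]
    b = cell_means[cell_means["group"] == groups[1]]
    for state in ("rest", "task"):
        t, p = stats.ttest_ind(a[state], b[state], equal_var=True)
        rows.append(
            {
                "comparison": f"{groups[0]} vs {groups[1]}",
                "state": state,
                "group": "",
                "t": float(t),
                "p": float(p),
                "direction": "",
            }
        )
    for g, sub in ((groups[0], a), (groups[1], b)):
        t, p = stats.ttest_rel(sub["task"], sub["rest"])
        delta = float(sub["task"].mean() - sub["rest"].mean())
        rows.append(
            {
                "comparison": "task vs rest",
                "state": "",
                "group": g,
                "t": float(t),
                "p": float(p),
                "direction": "increase" if delta > 0 else "decrease",
            }
        )
    return pd.DataFrame(rows)
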