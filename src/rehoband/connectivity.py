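"""Seed-based functional connectivity with Fisher z transformation.

For each subject and state, the seed time course is the unweighted mean BOLD
series over the seed cluster's voxels; the FC map holds the Pearson
correlation of every in-mask voxel with that time course, and its Fisher
z = atanh(r) counterpart (variance-stabilized for group-level t-tests).
Group contrasts are voxel-wise two-sample t-tests between groups within a
state; state contrasts are paired t-tests between states within a group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import BoldSeries
from .groupstats import extract_clusters

#: |r| is clipped here before atanh so that self-correlations stay finite.
R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class SeedDefinition:
    """A seed region: cluster voxels (m, 3), its frequency band and a label."""

    label: str
    voxels: np.ndarray
    band: Optional[object] = None

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels, dtype=int)
        if voxels.ndim != 2 or voxels.shape[1] != 3 or len(voxels) == 0:
            raise ValueError("seed voxels must be a non-empty (m, 3) coordinate array")
        object.__setattr__(self, "voxels", voxels)

    def validate_mask(self, mask: np.ndarray) -> None:
        mask = np.asarray(mask, dtype=bool)
        idx = tuple(self.voxels.T)
        if not np.all(mask[idx]):
            raise ValueError(f"seed {self.label!r} has voxels outside the mask")


@dataclass
class FCMap:
    """Per-subject seed connectivity: Pearson r map and its Fisher z map."""

    r_map: np.ndarray
    z_map: np.ndarray
    seed_label: str
    subject_id: Optional[str] = None
    state: Optional[str] = None
    n_flagged: int = 0  # zero-variance voxels set to r = 0


def seed_timecourse(series: BoldSeries, seed: SeedDefinition) -> np.ndarray:
    """Unweighted mean BOLD time course over the seed voxels."""
    seed.validate_mask(series.mask)
    idx = tuple(seed.voxels.T)
    return series.data[idx].mean(axis=0)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| clipped at 1 - 1e-7 so the transform stays finite."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def fc_map(series: BoldSeries, seed_tc: np.ndarray, seed_label: str = "seed",
           subject_id: Optional[str] = None, state: Optional[str] = None) -> FCMap:
    """Correlate every in-mask voxel's series with the seed time course."""
    seed_tc = np.asarray(seed_tc, dtype=float)
    if seed_tc.shape != (series.n_volumes,):
        raise ValueError("seed time course length does not match the series")
    sc = seed_tc - seed_tc.mean()
    s_norm = np.sqrt((sc**2).sum())
    if s_norm == 0:
        raise ValueError("seed time course has zero variance")
    data = series.data[series.mask]  # (V, t)
    dc = data - data.mean(axis=1, keepdims=True)
    v_norm = np.sqrt((dc**2).sum(axis=1))
    flagged = v_norm == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (dc @ sc) / (v_norm * s_norm)
    r[flagged] = 0.0
    r = np.clip(r, -1.0, 1.0)
    r_map = np.zeros(series.spatial_shape)
    r_map[series.mask] = r
    z_map = np.zeros(series.spatial_shape)
    z_map[series.mask] = fisher_z(r)
    return FCMap(r_map, z_map, seed_label, subject_id, state, int(flagged.sum()))


# ---------------------------------------------------------------------------
# group-level contrasts on Fisher z maps
# ---------------------------------------------------------------------------

@dataclass
class FCContrast:
    """A voxel-wise t contrast on Fisher z maps."""

    t_map: np.ndarray
    p_map: np.ndarray  # two-tailed
    df: int
    contrast: str
    detail: str
    thresholded: Optional[np.ndarray] = None
    clusters: Optional[pd.DataFrame] = field(default=None, repr=False)


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple:
    """Pooled-variance two-sample t over the leading axis, vectorised."""
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    dof = n1 + n2 - 2
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t[~np.isfinite(t)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return t, p, dof


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple:
    n = a.shape[0]
    if n < 2 or b.shape[0] != n:
        raise ValueError("paired t needs matched samples of >= 2 subjects")
    d = a - b
    dof = n - 1
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d.mean(axis=0) / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return t, p, dof


def group_fc_contrast(
    z_maps: dict,
    design: pd.DataFrame,
    contrast: str,
    state: Optional[str] = None,
    group: Optional[str] = None,
    groups: tuple = ("NC", "MCI"),
) -> FCContrast:
    """Voxel-wise contrast of Fisher z maps.

    ``z_maps`` maps (subject_id, state) to a 3D z map. ``contrast`` is
    ``"group"`` (two-sample t between groups within ``state``, first group
    minus second) or ``"state"`` (paired t, task minus rest, within
    ``group``).
    """
    sids = design["subject_id"].to_numpy()
    glabels = design["group"].to_numpy()
    if contrast == "group":
        if state is None:
            raise ValueError("group contrast requires a state")
        a = np.stack([z_maps[(s, state)] for s in sids[glabels == groups[0]]])
        b = np.stack([z_maps[(s, state)] for s in sids[glabels == groups[1]]])
        t, p, dof = _two_sample_t(a, b)
        detail = f"{groups[0]} - {groups[1]} ({state})"
    elif contrast == "state":
        if group is None:
            raise ValueError("state contrast requires a group")
        sel = sids[glabels == group]
        task = np.stack([z_maps[(s, "task")] for s in sel])
        rest = np.stack([z_maps[(s, "rest")] for s in sel])
        t, p, dof = _paired_t(task, rest)
        detail = f"task - rest ({group})"
    else:
        raise ValueError("contrast must be 'group' or 'state'")
    return FCContrast(t, p, dof, contrast, detail)


def threshold_contrast(
    result: FCContrast,
    p_voxel: float,
    extent_threshold: int,
    connectivity: int = 18,
    mask: Optional[np.ndarray] = None,
    positive_only: bool = True,
) -> FCContrast:
    """Apply a voxel p-threshold and cluster-extent filter to a contrast.

    Positive connectivity differences only by default (negative values remain
    available in the raw t map).
    """
    table, labels = extract_clusters(
        result.t_map,
        result.p_map,
        p_voxel,
        extent_threshold,
        connectivity=connectivity,
        mask=mask,
        positive_only=positive_only,
    )
    result.thresholded = labels > 0
    result.clusters = table
    return result
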