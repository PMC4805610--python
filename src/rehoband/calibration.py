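"""Calibration and recovery studies on synthetic phantoms.

These routines quantify how the pipeline behaves under known conditions:
the independence expectation of Kendall's W, the voxel-wise false-positive
rate of the interaction map, the Monte-Carlo extent threshold's null
behaviour, detection of a planted group x state interaction cluster, and
recovery of a planted brain-behaviour coupling. They are what the test suite
and the reproduction script run; see docs/methods.md for the problem sizes
and what each study does and does not establish.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .bands import NAMED_BANDS, get_band
from .behavior import correlate_with_bootstrap
from .core import BoldSeries
from .groupstats import monte_carlo_cluster_threshold
from .phantom import (
    GROUP_PROFILES,
    PhantomConfig,
    PlantedEffect,
    block_cluster,
    coupling_for_target_r,
    generate_behavior,
    generate_bold,
    generate_cohort,
)
from .pipeline import analyze_band
from .preprocess import bandpass, ideal_bandpass_array
from .reho import reho_map


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Kendall's W under independence
# ---------------------------------------------------------------------------

def null_reho_calibration(
    grid: Tuple[int, int, int] = (12, 12, 8),
    n_volumes: int = 154,
    n_scans: int = 4,
    seed: int = 0,
) -> Dict[str, float]:
    """Mean W over full-neighbourhood voxels of pure-noise phantoms.

    Under independence E[W] = 1/k with k = 27 for a complete neighbourhood;
    border voxels have larger expectations (smaller k) and are excluded.
    """
    rng = np.random.default_rng(seed)
    means = []
    for _ in range(n_scans):
        series = generate_bold(grid, n_volumes, 2.0, [], ("NC", "rest"),
                               rng=rng, global_weight=0.0)
        rmap = reho_map(series, 26)
        means.append(rmap.values[1:-1, 1:-1, 1:-1].mean())
    n_interior = int(np.prod(np.asarray(grid) - 2))
    return {
        "mean_interior_w": float(np.mean(means)),
        "expectation": 1.0 / 27.0,
        "n_voxels": n_interior * n_scans,
    }


# ---------------------------------------------------------------------------
# voxel-wise type-I rate of the interaction map
# ---------------------------------------------------------------------------

def null_type_i_study(
    seed: int = 0,
    grid: Tuple[int, int, int] = (12, 12, 8),
    band: str = "slow-5",
    p_voxel: float = 0.01,
) -> Dict[str, float]:
    """Voxel-wise interaction false-positive rate on a null cohort.

    The cohort has no planted effects; maps are left unsmoothed so voxels stay
    as close to independent as the ReHo neighbourhood overlap allows, and the
    observed rate can be compared with the nominal ``p_voxel``.
    """
    cfg = PhantomConfig(
        grid_shape=grid, planted_clusters=[], include_response_logs=False,
        rng_seed=seed,
    )
    cohort = generate_cohort(cfg)
    res = analyze_band(
        cohort, band, fwhm_mm=0.0, k_star=10**9, do_fc=False, seed=seed
    )
    rate = float((res.interaction.p_map < p_voxel)[cohort.mask].mean())
    n_vox = int(cohort.mask.sum())
    half_width = 1.96 * np.sqrt(p_voxel * (1 - p_voxel) / n_vox)
    return {
        "type_i_rate": rate,
        "nominal": p_voxel,
        "n_voxels": n_vox,
        "binomial_band": (p_voxel - half_width, p_voxel + half_width),
    }


# ---------------------------------------------------------------------------
# Monte-Carlo extent threshold null behaviour
# ---------------------------------------------------------------------------

def mc_threshold_study(
    seed: int = 0,
    mask_shape: Tuple[int, int, int] = (25, 25, 16),
    n_iter: int = 1000,
) -> Dict[str, float]:
    """Null facts about the extent threshold on a 10^4-voxel mask.

    Without smoothing the thresholded field is iid Bernoulli(p), so the mean
    suprathreshold count is p times the mask size; smoothing to 8 mm inflates
    null cluster extents and therefore k*.
    """
    mask = np.ones(mask_shape, dtype=bool)
    seeds = _child_seeds(seed, 2)
    rough = monte_carlo_cluster_threshold(
        mask, 0.0, 0.01, 0.05, n_iter=n_iter, connectivity=26, seed=seeds[0]
    )
    smoothed = monte_carlo_cluster_threshold(
        mask, 8.0, 0.01, 0.05, n_iter=n_iter, connectivity=26, seed=seeds[1]
    )
    return {
        "mean_suprathreshold_fwhm0": rough.mean_suprathreshold,
        "expected_suprathreshold": 0.01 * mask.sum(),
        "k_star_fwhm0": rough.k_star,
        "k_star_fwhm8": smoothed.k_star,
        "n_iter": n_iter,
    }


# ---------------------------------------------------------------------------
# planted interaction recovery
# ---------------------------------------------------------------------------

def _replicate_phantom_config(seed: int, grid: Tuple[int, int, int]) -> PhantomConfig:
    """Replicate-study conditions: default cohort and effect sizes, a planted
    cluster at the default ~144-voxel extent, on a compact grid."""
    planted = [
        PlantedEffect(
            cluster_voxels=block_cluster(grid, (6, 6, 4)),
            band=get_band("slow-5"),
            coupling_by_cell={
                ("NC", "rest"): 0.35,
                ("NC", "task"): 0.05,
                ("MCI", "rest"): 0.05,
                ("MCI", "task"): 0.35,
            },
        )
    ]
    return PhantomConfig(
        grid_shape=grid,
        planted_clusters=planted,
        include_response_logs=False,
        rng_seed=seed,
    )


def recovery_study(
    n_replicates: int = 50,
    seed: int = 0,
    grid: Tuple[int, int, int] = (18, 18, 12),
    band: str = "slow-5",
    fwhm_mm: float = 4.0,
    p_voxel: float = 0.01,
    alpha: float = 0.05,
    connectivity: int = 18,
    mc_iter: int = 1000,
    min_overlap: int = 10,
) -> Dict[str, float]:
    """Detection rate of the planted interaction cluster after correction.

    The first replicate estimates the extent threshold k* from its own
    residual smoothness (1000-iteration Monte-Carlo); later replicates reuse
    it, since mask and smoothness are condition-stable. A replicate counts
    as a detection when a retained cluster overlaps the planted cluster by at
    least ``min_overlap`` voxels; for detected clusters the post-hoc paired
    t-tests must reproduce the planted pattern (synchrony falls from rest to
    task in NC, rises in MCI) to count as a correct sign pattern.
    """
    seeds = _child_seeds(seed, n_replicates + 1)
    planted_idx = None
    k_star = None
    detected = 0
    signs_ok = 0
    off_target = 0
    for rep in range(n_replicates):
        cfg = _replicate_phantom_config(int(seeds[rep]), grid)
        cohort = generate_cohort(cfg)
        if planted_idx is None:
            planted = np.zeros(grid, dtype=bool)
            planted[tuple(cfg.planted_clusters[0].cluster_voxels.T)] = True
            planted_idx = planted
        res = analyze_band(
            cohort, band, fwhm_mm=fwhm_mm, p_voxel=p_voxel, alpha=alpha,
            connectivity=connectivity, k_star=k_star, mc_iter=mc_iter,
            do_fc=False, seed=int(seeds[-1]), n_boot=200,
        )
        k_star = res.k_star
        hit_label = None
        for rec in res.clusters.itertuples(index=False):
            overlap = int((planted_idx & (res.cluster_labels == rec.label)).sum())
            if overlap >= min_overlap and hit_label is None:
                hit_label = rec.label
            elif overlap < min_overlap:
                off_target += 1
        if hit_label is None:
            continue
        detected += 1
        ph = res.posthoc[hit_label]
        paired = ph[ph["comparison"] == "task vs rest"].set_index("group")
        if paired.loc["NC", "t"] < 0 and paired.loc["MCI", "t"] > 0:
            signs_ok += 1
    return {
        "recovery_rate": detected / n_replicates,
        "sign_pattern_rate": signs_ok / n_replicates,
        "off_target_cluster_rate": off_target / n_replicates,
        "k_star": int(k_star),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# behaviour coupling recovery
# ---------------------------------------------------------------------------

def behavior_recovery_study(
    n_replicates: int = 200,
    seed: int = 0,
    n_subjects: int = 17,
    target_r: float = -0.63,
    n_boot: int = 1000,
) -> Dict[str, float]:
    """Recovery of a planted state-change/performance correlation.

    State changes are standard normal; the coupling slope is set so the
    population correlation with the performance index equals ``target_r``
    (patient-group baseline and RT profile). Reports the mean recovered
    Pearson r and the fraction of bootstrap percentile CIs covering the
    population value.
    """
    profile = GROUP_PROFILES["MCI"]
    noise_sd = 6e-5
    coupling = coupling_for_target_r(target_r, sd_change=1.0, noise_sd=noise_sd)
    seeds = _child_seeds(seed, n_replicates)
    rs = np.empty(n_replicates)
    covered = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(int(seeds[rep]))
        change = rng.standard_normal(n_subjects)
        beh = generate_behavior(
            change, coupling, noise_sd, rng=rng,
            baseline=profile["performance_baseline"],
            rt_mean_ms=profile["rt_ms"][0], rt_sd_ms=profile["rt_ms"][1],
        )
        rep_report = correlate_with_bootstrap(
            change, beh["performance"].to_numpy(), n_boot=n_boot, rng=rng
        )
        rs[rep] = rep_report.r
        if rep_report.ci_low <= target_r <= rep_report.ci_high:
            covered += 1
    return {
        "mean_r": float(rs.mean()),
        "target_r": target_r,
        "ci_coverage": covered / n_replicates,
        "n_replicates": n_replicates,
        "n_boot": n_boot,
    }


# ---------------------------------------------------------------------------
# filter properties
# ---------------------------------------------------------------------------

def filter_property_study(seed: int = 0) -> Dict[str, float]:
    """Parseval partition across the named bands plus sinusoid checks."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((3, 3, 2, 154))
    series = BoldSeries(x, 2.0)
    from scipy.signal import detrend

    total = detrend(x, axis=-1).var(axis=-1)
    acc = np.zeros_like(total)
    for name in NAMED_BANDS:
        acc += bandpass(series, name).data.var(axis=-1)
    parseval_err = float(np.max(np.abs(acc - total) / total))

    t = np.arange(154) * 2.0
    sine = np.sin(2 * np.pi * 0.05 * t)
    kept = ideal_bandpass_array(sine, 2.0, get_band("slow-4"))
    rejected = ideal_bandpass_array(sine, 2.0, get_band("slow-5"))
    return {
        "parseval_max_rel_error": parseval_err,
        "passband_correlation": float(np.corrcoef(kept, sine)[0, 1]),
        "stopband_variance_ratio": float(rejected.var() / sine.var()),
    }
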