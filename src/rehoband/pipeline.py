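"""End-to-end orchestration: phantom -> preprocess -> ReHo -> stats -> FC -> behaviour.

A single :class:`RunConfig` drives every stage per frequency band; all outputs
are standard formats (NIfTI volumes, TSV tables, JSON config/manifest) under
one output directory, and one global seed fans out deterministically to every
stochastic stage, so repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io
from .bands import DEFAULT_ANALYSIS_BANDS, BandSpec, get_band
from .behavior import correlate_with_bootstrap, score_dmst
from .connectivity import SeedDefinition, fc_map, group_fc_contrast, seed_timecourse, threshold_contrast
from .core import BoldSeries, ReHoMap
from .groupstats import (
    DEFAULT_COVARIATES,
    InteractionResult,
    MonteCarloResult,
    cluster_cell_means,
    estimate_map_fwhm,
    extract_clusters,
    interaction_map,
    monte_carlo_cluster_threshold,
    posthoc_t,
)
from .phantom import STATES, Cohort, PhantomConfig, PlantedEffect, generate_cohort
from .preprocess import bandpass, motion_qc, regress_nuisance, trim_volumes
from .reho import reho_map, smooth, standardize

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a full run needs; see docs/methods.md for parameter roles."""

    out_dir: str = "rehoband_out"
    input_dir: Optional[str] = None  # existing phantom directory; None = simulate
    bands: Tuple[str, ...] = DEFAULT_ANALYSIS_BANDS
    p_voxel: float = 0.01
    alpha: float = 0.05
    connectivity: int = 18
    fwhm_mm: float = 4.0
    scheme: int = 26
    mc_iter: int = 1000
    qc_threshold_mm: float = 3.0
    n_boot: int = 1000
    fc_p_voxel: float = 0.05
    smoothness: str = "estimated"  # noise FWHM for the Monte-Carlo: estimated | applied
    n_discard: Dict[str, int] = field(default_factory=lambda: {"rest": 0, "task": 0})
    covariates: Tuple[str, ...] = DEFAULT_COVARIATES
    write_subject_fc: bool = False
    seed: int = 0
    phantom: Dict = field(default_factory=dict)  # PhantomConfig overrides

    def __post_init__(self) -> None:
        self.bands = tuple(self.bands)
        for name in self.bands:
            get_band(name)  # raises on unknown names
        if not (0 < self.p_voxel < 1) or not (0 < self.alpha <= 1):
            raise ValueError("p_voxel must be in (0, 1) and alpha in (0, 1]")
        if self.connectivity not in (6, 18, 26) or self.scheme not in (6, 18, 26):
            raise ValueError("connectivity/scheme must be 6, 18 or 26")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be non-negative")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls(**data)

    def validate_bands(self, tr_s: float) -> None:
        nyquist = 1.0 / (2.0 * tr_s)
        for name in self.bands:
            band = get_band(name)
            if band.f_high > nyquist + 1e-9:
                raise ValueError(
                    f"band {band.name} upper edge {band.f_high} Hz exceeds the "
                    f"Nyquist frequency {nyquist} Hz at TR = {tr_s} s"
                )


# ---------------------------------------------------------------------------
# per-scan and per-band computation
# ---------------------------------------------------------------------------

def preprocess_scan(
    series: BoldSeries, nuisance: pd.DataFrame, band, n_discard: int = 0
) -> BoldSeries:
    """Trim -> nuisance regression -> detrend + ideal band-pass for one scan."""
    if n_discard:
        series = trim_volumes(series, n_discard)
        nuisance = nuisance.iloc[n_discard:].reset_index(drop=True)
    series = regress_nuisance(series, nuisance)
    return bandpass(series, band)


def zreho(series: BoldSeries, scheme: int = 26, fwhm_mm: float = 4.0) -> ReHoMap:
    """Raw ReHo -> subject-wise z-standardization -> Gaussian smoothing."""
    return smooth(standardize(reho_map(series, scheme)), fwhm_mm)


@dataclass
class BandResult:
    """All analysis products for one frequency band."""

    band: BandSpec
    z_maps: Dict[Tuple[str, str], np.ndarray]
    rest_stack: np.ndarray
    task_stack: np.ndarray
    diffs: np.ndarray
    interaction: InteractionResult
    mc: Optional[MonteCarloResult]
    k_star: int
    cluster_labels: np.ndarray
    clusters: pd.DataFrame
    cell_means: Dict[int, pd.DataFrame]
    posthoc: Dict[int, pd.DataFrame]
    correlations: pd.DataFrame
    fc: Dict[int, Dict[str, object]] = field(default_factory=dict)


def analyze_band(
    cohort: Cohort,
    band,
    *,
    scheme: int = 26,
    fwhm_mm: float = 4.0,
    p_voxel: float = 0.01,
    alpha: float = 0.05,
    connectivity: int = 18,
    mc_iter: int = 1000,
    k_star: Optional[int] = None,
    smoothness: str = "estimated",
    seed: int = 0,
    n_boot: int = 1000,
    fc_p_voxel: float = 0.05,
    do_fc: bool = True,
    covariates: Tuple[str, ...] = DEFAULT_COVARIATES,
    performance: Optional[np.ndarray] = None,
) -> BandResult:
    """Run the full analysis for one band on an in-memory cohort.

    ``k_star`` can be supplied to reuse a Monte-Carlo extent threshold
    computed once for the shared mask/smoothness (it depends only on those);
    otherwise it is estimated here with ``mc_iter`` iterations. The noise
    smoothness fed to the Monte-Carlo is, by default, estimated from the
    group-demeaned difference maps (``smoothness="estimated"``): ReHo maps
    are intrinsically smoother than the applied kernel because neighbouring
    voxels share most of their neighbourhood series, and using the nominal
    FWHM (``smoothness="applied"``) makes the extent threshold markedly
    anti-conservative.
    """
    band = get_band(band)
    subjects = cohort.subjects
    groups = cohort.config.groups
    sids = list(subjects["subject_id"])

    filtered: Dict[Tuple[str, str], BoldSeries] = {}
    z_maps: Dict[Tuple[str, str], np.ndarray] = {}
    for key, series in cohort.bold.items():
        pre = preprocess_scan(series, cohort.nuisance[key], band)
        if do_fc:
            filtered[key] = pre
        z_maps[key] = zreho(pre, scheme, fwhm_mm).values

    rest_stack = np.stack([z_maps[(s, "rest")] for s in sids])
    task_stack = np.stack([z_maps[(s, "task")] for s in sids])
    diffs = task_stack - rest_stack

    interaction = interaction_map(diffs, subjects, covariates, mask=cohort.mask)
    mc = None
    if k_star is None:
        if smoothness == "estimated":
            resid = diffs.copy()
            for g in groups:  # remove group means: what the F-test models
                in_g = (subjects["group"] == g).to_numpy()
                resid[in_g] -= resid[in_g].mean(axis=0)
            mc_fwhm = estimate_map_fwhm(resid, cohort.mask, cohort.config.voxel_size_mm)
        elif smoothness == "applied":
            mc_fwhm = fwhm_mm
        else:
            raise ValueError("smoothness must be 'estimated' or 'applied'")
        mc = monte_carlo_cluster_threshold(
            cohort.mask,
            mc_fwhm,
            p_voxel,
            alpha,
            n_iter=mc_iter,
            connectivity=connectivity,
            voxel_size_mm=cohort.config.voxel_size_mm,
            seed=np.random.SeedSequence((seed, 0xA15A)).generate_state(1)[0] & 0x7FFFFFFF,
        )
        k_star = mc.k_star
    clusters, labels = extract_clusters(
        interaction.f_map, interaction.p_map, p_voxel, k_star, connectivity, cohort.mask
    )
    interaction.voxel_p_threshold = p_voxel
    interaction.cluster_extent_threshold = int(k_star)
    interaction.clusters = clusters

    perf = (
        np.asarray(performance, dtype=float)
        if performance is not None
        else subjects["performance"].to_numpy(dtype=float)
    )

    cell_means: Dict[int, pd.DataFrame] = {}
    posthoc: Dict[int, pd.DataFrame] = {}
    corr_rows: List[dict] = []
    fc_out: Dict[int, Dict[str, object]] = {}
    for rec in clusters.itertuples(index=False):
        voxels = np.argwhere(labels == rec.label)
        cm = cluster_cell_means(rest_stack, task_stack, voxels, subjects)
        cell_means[rec.label] = cm
        posthoc[rec.label] = posthoc_t(cm, groups=groups)
        # brain-behaviour coupling, always within a single group
        for gi, group in enumerate(groups):
            in_group = (subjects["group"] == group).to_numpy()
            x = cm.loc[in_group, "change"].to_numpy()
            y = perf[in_group]
            try:
                rep = correlate_with_bootstrap(
                    x, y, n_boot=n_boot, seed=np.random.SeedSequence((seed, rec.label, gi)).generate_state(1)[0]
                )
            except ValueError as exc:
                logger.warning("cluster %d group %s: correlation skipped (%s)", rec.label, group, exc)
                continue
            corr_rows.append(
                {
                    "band": band.name,
                    "cluster": rec.label,
                    "group": group,
                    "n": rep.n,
                    "r": rep.r,
                    "p": rep.p,
                    "ci_low": rep.ci_low,
                    "ci_high": rep.ci_high,
                    "n_boot": rep.n_boot,
                }
            )
        if do_fc:
            fc_out[rec.label] = _cluster_fc(
                filtered, subjects, groups, voxels, band, rec.label,
                fc_p_voxel, k_star, connectivity, cohort.mask,
            )

    correlations = pd.DataFrame(
        corr_rows,
        columns=["band", "cluster", "group", "n", "r", "p", "ci_low", "ci_high", "n_boot"],
    )
    return BandResult(
        band=band,
        z_maps=z_maps,
        rest_stack=rest_stack,
        task_stack=task_stack,
        diffs=diffs,
        interaction=interaction,
        mc=mc,
        k_star=int(k_star),
        cluster_labels=labels,
        clusters=clusters,
        cell_means=cell_means,
        posthoc=posthoc,
        correlations=correlations,
        fc=fc_out,
    )


def _cluster_fc(filtered, subjects, groups, voxels, band, label,
                fc_p_voxel, extent, connectivity, mask) -> Dict[str, object]:
    """Seed FC on the same band-filtered series the seed was found in."""
    seed_def = SeedDefinition(f"cluster{label}", voxels, band)
    z_fc = {
        key: fc_map(series, seed_timecourse(series, seed_def), seed_def.label, *key).z_map
        for key, series in filtered.items()
    }
    contrasts: Dict[str, object] = {"z_maps": z_fc}
    for state in STATES:
        c = group_fc_contrast(z_fc, subjects, "group", state=state, groups=groups)
        contrasts[f"group_{state}"] = threshold_contrast(
            c, fc_p_voxel, extent, connectivity, mask
        )
    for group in groups:
        c = group_fc_contrast(z_fc, subjects, "state", group=group, groups=groups)
        contrasts[f"state_{group}"] = threshold_contrast(
            c, fc_p_voxel, extent, connectivity, mask
        )
    return contrasts


# ---------------------------------------------------------------------------
# cohort persistence
# ---------------------------------------------------------------------------

def _effect_to_dict(eff: PlantedEffect) -> dict:
    return {
        "cluster_voxels": eff.cluster_voxels.tolist(),
        "band": {"name": eff.band.name, "f_low": eff.band.f_low, "f_high": eff.band.f_high},
        "coupling_by_cell": {f"{g}|{s}": w for (g, s), w in eff.coupling_by_cell.items()},
        "connectivity": eff.connectivity,
    }


def _effect_from_dict(d: dict) -> PlantedEffect:
    return PlantedEffect(
        cluster_voxels=np.asarray(d["cluster_voxels"], dtype=int),
        band=BandSpec(**d["band"]),
        coupling_by_cell={
            tuple(k.split("|")): w for k, w in d["coupling_by_cell"].items()
        },
        connectivity=d.get("connectivity", 26),
    )


def phantom_config_to_dict(config: PhantomConfig) -> dict:
    d = dataclasses.asdict(config)
    d["planted_clusters"] = [_effect_to_dict(e) for e in config.planted_clusters]
    return d


def phantom_config_from_dict(d: dict) -> PhantomConfig:
    d = dict(d)
    if d.get("planted_clusters") is not None:
        d["planted_clusters"] = [_effect_from_dict(e) for e in d["planted_clusters"]]
    for key in ("n_per_group", "groups", "grid_shape"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return PhantomConfig(**d)


def save_cohort(cohort: Cohort, out_dir) -> List[Path]:
    """Write a cohort to disk (NIfTI volumes, TSV tables, JSON config)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: List[Path] = []
    paths.append(io.write_json(phantom_config_to_dict(cohort.config), out / "config.json"))
    paths.append(io.write_volume(cohort.mask.astype(float), out / "mask.nii.gz",
                                 voxel_size_mm=cohort.config.voxel_size_mm))
    paths.append(io.write_table(cohort.subjects, out / "subjects.tsv"))
    for (sid, state), series in cohort.bold.items():
        stem = f"sub-{sid}_state-{state}"
        paths.append(io.write_volume(series, out / f"{stem}_bold.nii.gz"))
        paths.append(io.write_table(cohort.nuisance[(sid, state)], out / f"{stem}_nuisance.tsv"))
        paths.append(io.write_table(cohort.motion[(sid, state)], out / f"{stem}_motion.tsv"))
    for sid, sched in cohort.schedules.items():
        paths.append(io.write_table(sched, out / f"sub-{sid}_schedule.tsv"))
        paths.append(io.write_table(cohort.responses[sid], out / f"sub-{sid}_responses.tsv"))
    return paths


def load_cohort(in_dir) -> Cohort:
    """Read a cohort previously written by :func:`save_cohort`."""
    src = Path(in_dir)
    config = phantom_config_from_dict(json.loads((src / "config.json").read_text()))
    mask_data, _ = io.read_map(src / "mask.nii.gz")
    mask = mask_data > 0.5
    subjects = io.read_table(src / "subjects.tsv")
    bold, nuisance, motion, schedules, responses = {}, {}, {}, {}, {}
    for sid in subjects["subject_id"]:
        for state in STATES:
            stem = f"sub-{sid}_state-{state}"
            bold[(sid, state)] = io.read_series(src / f"{stem}_bold.nii.gz", mask=mask,
                                                tr_s=config.tr_s)
            nuisance[(sid, state)] = io.read_table(src / f"{stem}_nuisance.tsv")
            motion[(sid, state)] = io.read_table(src / f"{stem}_motion.tsv")
        sched_path = src / f"sub-{sid}_schedule.tsv"
        if sched_path.exists():  # absent when logs were not generated
            schedules[sid] = io.read_table(sched_path)
            responses[sid] = io.read_table(src / f"sub-{sid}_responses.tsv")
    return Cohort(config, subjects, mask, bold, nuisance, motion, schedules, responses)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _qc_table(cohort: Cohort, threshold_mm: float) -> pd.DataFrame:
    rows = []
    for (sid, state), mot in cohort.motion.items():
        qc = motion_qc(mot, threshold_mm)
        rows.append(
            {
                "subject_id": sid,
                "state": state,
                "passed": qc.passed,
                "max_translation_mm": qc.max_translation_mm,
                "mean_fd_mm": qc.mean_fd_mm,
                "threshold_mm": qc.threshold_mm,
            }
        )
    return pd.DataFrame(rows).sort_values(["subject_id", "state"]).reset_index(drop=True)


def score_cohort_behavior(cohort: Cohort) -> pd.DataFrame:
    """Score every subject's response log against their schedule."""
    rows = []
    for sid in cohort.subjects["subject_id"]:
        score = score_dmst(cohort.responses[sid], cohort.schedules[sid])
        rows.append(
            {
                "subject_id": sid,
                "hit_rate": score.hit_rate,
                "false_alarm_rate": score.false_alarm_rate,
                "accuracy": score.accuracy,
                "rt_ms": score.rt_ms,
                "performance": score.performance,
                "n_misses": score.n_misses,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage per band; returns the manifest (also written out).

    The manifest maps each written file (relative path) to its stage and
    SHA-256 checksum; identical configs and seeds reproduce it byte for byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    if config.input_dir is not None:
        cohort = load_cohort(config.input_dir)
    else:
        overrides = dict(config.phantom)
        overrides.setdefault("rng_seed", config.seed)
        cohort = generate_cohort(phantom_config_from_dict(overrides))
    config.validate_bands(cohort.config.tr_s)  # before any heavy compute

    files: Dict[str, str] = {}

    def record(path: Path, stage: str) -> None:
        files[str(Path(path).relative_to(out))] = stage

    io.write_json(dataclasses.asdict(config), out / "run_config.json")
    record(out / "run_config.json", "config")

    for p in save_cohort(cohort, out / "phantom"):
        record(p, "phantom")

    qc = _qc_table(cohort, config.qc_threshold_mm)
    record(io.write_table(qc, out / "qc.tsv"), "qc")
    if not qc["passed"].all():
        failed = qc.loc[~qc["passed"], ["subject_id", "state"]]
        logger.warning("motion QC failures:\n%s", failed.to_string(index=False))

    if cohort.responses:
        scored = score_cohort_behavior(cohort)
        record(io.write_table(scored, out / "behavior_scores.tsv"), "behavior")
        perf = scored.set_index("subject_id").loc[
            cohort.subjects["subject_id"], "performance"
        ].to_numpy()
    else:  # cohorts generated without response logs carry generative scores
        perf = cohort.subjects["performance"].to_numpy()

    k_star_by_band: Dict[str, int] = {}
    for band_name in config.bands:
        res = analyze_band(
            cohort,
            band_name,
            scheme=config.scheme,
            fwhm_mm=config.fwhm_mm,
            p_voxel=config.p_voxel,
            alpha=config.alpha,
            connectivity=config.connectivity,
            mc_iter=config.mc_iter,
            smoothness=config.smoothness,
            seed=config.seed,
            n_boot=config.n_boot,
            fc_p_voxel=config.fc_p_voxel,
            covariates=config.covariates,
            performance=perf,
        )
        k_star_by_band[band_name] = res.k_star
        bdir = out / "bands" / band_name
        voxel = cohort.config.voxel_size_mm
        for (sid, state), zmap in res.z_maps.items():
            p = io.write_volume(zmap, bdir / "zreho" / f"sub-{sid}_state-{state}_zreho.nii.gz",
                                voxel_size_mm=voxel)
            record(p, "reho")
        record(io.write_volume(res.interaction.f_map, bdir / "interaction_F.nii.gz",
                               voxel_size_mm=voxel), "stats")
        record(io.write_volume(res.interaction.p_map, bdir / "interaction_p.nii.gz",
                               voxel_size_mm=voxel), "stats")
        record(io.write_volume(res.cluster_labels.astype(float),
                               bdir / "cluster_labels.nii.gz", voxel_size_mm=voxel), "stats")
        record(io.write_table(res.clusters, bdir / "clusters.tsv"), "stats")
        if res.posthoc:
            record(io.write_table(
                pd.concat([t.assign(cluster=lab) for lab, t in res.posthoc.items()]),
                bdir / "posthoc.tsv"), "stats")
        record(io.write_table(res.correlations, bdir / "behavior_correlations.tsv"), "behavior")
        for lab, contrasts in res.fc.items():
            fdir = bdir / "fc" / f"cluster-{lab:02d}"
            for name, c in contrasts.items():
                if name == "z_maps":
                    if config.write_subject_fc:
                        for (sid, state), zm in c.items():
                            record(io.write_volume(
                                zm, fdir / f"sub-{sid}_state-{state}_zfc.nii.gz",
                                voxel_size_mm=voxel), "fc")
                    continue
                record(io.write_volume(c.t_map, fdir / f"{name}_t.nii.gz",
                                       voxel_size_mm=voxel), "fc")
                record(io.write_volume(c.thresholded.astype(float),
                                       fdir / f"{name}_thresholded.nii.gz",
                                       voxel_size_mm=voxel), "fc")
                record(io.write_table(c.clusters, fdir / f"{name}_clusters.tsv"), "fc")
        logger.info("band %s: k*=%d, %d significant cluster(s)",
                    band_name, res.k_star, len(res.clusters))

    logger.info("pipeline finished in %.1f s", time.time() - t0)
    manifest = {
        "seed": config.seed,
        "k_star": k_star_by_band,
        "files": {
            rel: {"stage": stage, "sha256": io.sha256_file(out / rel)}
            for rel, stage in sorted(files.items())
        },
    }
    # checksums cover every declared artifact; the manifest itself is excluded
    io.write_json(manifest, out / "manifest.json")

    # verify completeness: every declared artifact exists and is non-empty
    for rel in files:
        p = out / rel
        if not p.exists() or p.stat().st_size == 0:
            raise RuntimeError(f"pipeline declared {rel} but it is missing or empty")
    return manifest
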