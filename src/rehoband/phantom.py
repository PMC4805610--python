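"""Synthetic two-group x two-state BOLD phantoms with planted ReHo effects.

The generator emulates the study conditions every downstream stage expects:
two groups (16 normal-control and 17 mildly impaired subjects), two states
per subject (resting, working-memory task) with 154 volumes each at TR = 2 s,
nuisance structure (motion random walks, a shared global signal, white-matter
and CSF series), a blocked delayed-match-to-sample trial schedule, and a
behavioural performance variable coupled to the planted state change.

Local synchrony is planted by mixing, inside a cluster, a shared band-limited
latent signal into otherwise independent voxel noise:

    voxel series = sqrt(w) * latent + sqrt(1 - w) * noise,   w in [0, 1],

with w chosen per (group, state) cell. w = 0 everywhere yields the
independence null (mean Kendall's W ~ 1/k); w = 1 makes cluster voxels
identical. The latent is synthesized by passing white noise through the same
ideal band-pass used in preprocessing, so its spectrum lies exactly in the
planted band. The default planted pattern is the qualitative interaction of
interest: synchrony falls from rest to task in controls but rises in
patients, in a slow-5-band cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d

from .bands import BandSpec, get_band
from .core import BoldSeries
from .preprocess import ideal_bandpass_array, mean_framewise_displacement

STATES = ("rest", "task")
DEFAULT_GROUPS = ("NC", "MCI")

#: per-group sampling profiles for covariates and behaviour (age in years,
#: education in years, RT in ms, performance baseline in 1/ms). Means and SDs
#: follow the cohort summary the phantoms emulate.
GROUP_PROFILES = {
    "NC": {
        "age": (68.56, 5.76),
        "education": (11.75, 3.17),
        "male_p": 8 / 16,
        "rt_ms": (609.76, 56.09),
        "performance_baseline": 1.51e-3,
        "gm_intensity": (1.00, 0.05),
    },
    "MCI": {
        "age": (70.53, 4.54),
        "education": (9.82, 4.63),
        "male_p": 9 / 17,
        "rt_ms": (692.86, 86.36),
        "performance_baseline": 1.16e-3,
        "gm_intensity": (0.95, 0.05),
    },
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEffect:
    """A connected cluster with a per-(group, state) local-synchrony weight."""

    cluster_voxels: np.ndarray  # (m, 3) grid coordinates
    band: BandSpec
    coupling_by_cell: Dict[Tuple[str, str], float]
    connectivity: int = 26

    def __post_init__(self) -> None:
        voxels = np.asarray(self.cluster_voxels, dtype=int)
        if voxels.ndim != 2 or voxels.shape[1] != 3 or len(voxels) == 0:
            raise ValueError("cluster_voxels must be a non-empty (m, 3) array")
        object.__setattr__(self, "cluster_voxels", voxels)
        object.__setattr__(self, "band", get_band(self.band))
        for cell, w in self.coupling_by_cell.items():
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"synchrony weight for cell {cell} must be in [0, 1], got {w}")

    def weight(self, cell: Tuple[str, str]) -> float:
        try:
            return self.coupling_by_cell[cell]
        except KeyError:
            raise ValueError(f"planted effect has no weight for cell {cell}") from None

    def validate_grid(self, grid_shape) -> None:
        v = self.cluster_voxels
        if np.any(v < 0) or np.any(v >= np.asarray(grid_shape)):
            raise ValueError("planted cluster extends outside the grid")
        # connectedness under the configured scheme
        vol = np.zeros(grid_shape, dtype=bool)
        vol[tuple(v.T)] = True
        order = {6: 1, 18: 2, 26: 3}[self.connectivity]
        _, n_lab = ndimage.label(vol, ndimage.generate_binary_structure(3, order))
        if n_lab != 1:
            raise ValueError(f"planted cluster is not connected ({n_lab} components)")


def block_cluster(grid_shape, block_shape, center: bool = True) -> np.ndarray:
    """Grid coordinates of an axis-aligned block, centred by default."""
    grid = np.asarray(grid_shape, int)
    blk = np.asarray(block_shape, int)
    if np.any(blk <= 0) or np.any(blk > grid):
        raise ValueError(f"block {tuple(blk)} does not fit grid {tuple(grid)}")
    start = (grid - blk) // 2 if center else np.zeros(3, int)
    ranges = [np.arange(start[i], start[i] + blk[i]) for i in range(3)]
    return np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)


def default_planted_effects(grid_shape) -> List[PlantedEffect]:
    """One centred slow-5 cluster with the canonical interaction pattern.

    Synchrony drops from rest to task in NC (0.35 -> 0.05) and rises in MCI
    (0.05 -> 0.35); the block spans roughly a quarter of each axis (>= 3
    voxels), giving >= 96 voxels on the default grid.
    """
    grid = np.asarray(grid_shape, int)
    blk = np.clip(grid // 4, 3, 6)
    return [
        PlantedEffect(
            cluster_voxels=block_cluster(grid, blk),
            band=get_band("slow-5"),
            coupling_by_cell={
                ("NC", "rest"): 0.35,
                ("NC", "task"): 0.05,
                ("MCI", "rest"): 0.05,
                ("MCI", "task"): 0.35,
            },
        )
    ]


@dataclass
class PhantomConfig:
    """Generating conditions for a synthetic cohort.

    ``behavior_coupling`` links each subject's planted state change (the
    jittered w difference, task minus rest) to the performance index; the
    default is calibrated so that the within-patient-group correlation between
    change and performance is approximately -0.63 in the population.
    """

    n_per_group: Tuple[int, int] = (16, 17)  # (NC, MCI)
    groups: Tuple[str, str] = DEFAULT_GROUPS
    grid_shape: Tuple[int, int, int] = (24, 24, 16)
    voxel_size_mm: float = 3.0
    n_volumes: int = 154
    tr_s: float = 2.0
    planted_clusters: Optional[List[PlantedEffect]] = None
    noise_sd: float = 1.0
    baseline: float = 1000.0
    global_weight: float = 0.2
    w_jitter_sd: float = 0.04
    behavior_coupling: Optional[float] = None
    #: residual SD of the performance index (1/ms); calibrated so the implied
    #: accuracy spread matches a healthy elderly cohort (~0.05) and clipping of
    #: accuracy at 1 stays rare
    behavior_noise_sd: float = 6e-5
    behavior_target_r: float = -0.63
    include_response_logs: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_clusters is None:
            self.planted_clusters = default_planted_effects(self.grid_shape)
        if self.behavior_coupling is None:
            self.behavior_coupling = coupling_for_target_r(
                self.behavior_target_r,
                sd_change=np.sqrt(2.0) * self.w_jitter_sd,
                noise_sd=self.behavior_noise_sd,
            )
        self.validate()

    def validate(self) -> None:
        if len(self.n_per_group) != 2 or any(int(n) <= 0 for n in self.n_per_group):
            raise ValueError(f"n_per_group must be two positive counts, got {self.n_per_group}")
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive counts, got {self.grid_shape}")
        if self.n_volumes < 8:
            raise ValueError("n_volumes must be at least 8")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        nyq = 1.0 / (2.0 * self.tr_s)
        for eff in self.planted_clusters:
            eff.validate_grid(self.grid_shape)
            if eff.band.f_high > nyq + 1e-9:
                raise ValueError(f"planted band {eff.band.name} exceeds Nyquist {nyq} Hz")


# ---------------------------------------------------------------------------
# BOLD generation
# ---------------------------------------------------------------------------

def band_limited_latent(n_volumes: int, tr_s: float, band, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance latent series band-limited by the ideal filter."""
    raw = rng.standard_normal(n_volumes)
    latent = ideal_bandpass_array(raw, tr_s, get_band(band), detrend=True)
    sd = latent.std()
    if sd == 0:  # band holds no DFT bin at this length; keep a flat latent
        return np.zeros(n_volumes)
    return latent / sd


def generate_bold(
    shape,
    n_volumes: int,
    tr_s: float,
    planted: List[PlantedEffect],
    cell: Tuple[str, str],
    noise_sd: float = 1.0,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    baseline: float = 1000.0,
    global_weight: float = 0.2,
    mask: Optional[np.ndarray] = None,
) -> BoldSeries:
    """One 4D BOLD series for a (group, state) cell.

    Inside each planted cluster, ``sqrt(w) * latent + sqrt(1 - w) * noise``
    with the cluster's cell weight w; pure independent noise elsewhere. A
    weak shared global fluctuation and a constant baseline are added on top.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape) or n_volumes < 2:
        raise ValueError("shape must be 3 positive ints and n_volumes >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    if mask is None:
        mask = np.ones(shape, dtype=bool)

    signal = rng.standard_normal(shape + (n_volumes,))
    for eff in planted:
        w = eff.weight(cell)
        latent = band_limited_latent(n_volumes, tr_s, eff.band, rng)
        idx = tuple(eff.cluster_voxels.T)
        signal[idx] = np.sqrt(w) * latent + np.sqrt(1.0 - w) * signal[idx]

    global_sig = gaussian_filter1d(rng.standard_normal(n_volumes), sigma=2.0)
    global_sig /= global_sig.std()
    data = baseline + noise_sd * (signal + global_weight * global_sig)
    data[~mask] = 0.0
    return BoldSeries(data, tr_s, voxel_size_mm=3.0, mask=mask)


def simulate_motion(n_volumes: int, rng: np.random.Generator, step_mm: float = 0.02) -> pd.DataFrame:
    """A gentle rigid-body random walk (3 translations mm, 3 rotations rad)."""
    steps = rng.normal(0.0, step_mm, size=(n_volumes, 6))
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0)
    return pd.DataFrame(walk, columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"])


def _smooth_unit_noise(n: int, rng: np.random.Generator, sigma: float = 3.0) -> np.ndarray:
    x = gaussian_filter1d(rng.standard_normal(n), sigma=sigma)
    return x / x.std()


def nuisance_table(series: BoldSeries, motion: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Nuisance regressors for one scan: motion, global, WM and CSF means."""
    table = motion.copy()
    table["global"] = series.data[series.mask].mean(axis=0)
    table["white_matter"] = _smooth_unit_noise(series.n_volumes, rng)
    table["csf"] = _smooth_unit_noise(series.n_volumes, rng)
    return table


# ---------------------------------------------------------------------------
# DMST schedule and responses
# ---------------------------------------------------------------------------

def _compose_counts(total: int, lo: int, hi: int, rng: np.random.Generator) -> List[int]:
    """Random composition of ``total`` into parts within [lo, hi]."""
    parts: List[int] = []
    rem = total
    while rem > 0:
        feasible = [c for c in range(lo, min(hi, rem) + 1) if rem - c == 0 or rem - c >= lo]
        if not feasible:
            raise ValueError(f"cannot compose {total} into parts within [{lo}, {hi}]")
        c = int(rng.choice(feasible))
        parts.append(c)
        rem -= c
    return parts


def generate_dmst_schedule(
    n_blocks: int = 4,
    trials_per_block: int = 8,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    n_targets: int = 2,
    repeats: Tuple[int, int] = (2, 4),
    n_test_range: Tuple[int, int] = (12, 13),
) -> pd.DataFrame:
    """A blocked DMST trial schedule (default: 4 blocks x 8 trials = 32).

    Each trial presents ``n_targets`` target objects followed by 12-13 test
    objects; every target and distractor appears 2-4 times, pseudo-randomized.
    Returns one row per test stimulus with columns block, trial, position,
    object_id, is_target.
    """
    if n_blocks <= 0 or trials_per_block <= 0 or n_targets <= 0:
        raise ValueError("counts must be positive")
    lo, hi = repeats
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid repetition range {repeats}")
    if n_targets * lo + lo > max(n_test_range):
        raise ValueError(
            f"{n_targets} targets repeating >= {lo} times plus one distractor "
            f"cannot fit in {max(n_test_range)} test objects"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    rows = []
    trial = 0
    for block in range(1, n_blocks + 1):
        for _ in range(trials_per_block):
            trial += 1
            total = int(rng.integers(n_test_range[0], n_test_range[1] + 1))
            while True:  # target repetition counts that leave a composable remainder
                t_counts = rng.integers(lo, hi + 1, size=n_targets)
                rem = total - int(t_counts.sum())
                if rem >= lo:
                    try:
                        d_counts = _compose_counts(rem, lo, hi, rng)
                        break
                    except ValueError:
                        continue
            seq = []
            for j, c in enumerate(t_counts):
                seq += [(f"T{j + 1}", True)] * int(c)
            for j, c in enumerate(d_counts):
                seq += [(f"D{j + 1}", False)] * int(c)
            order = rng.permutation(len(seq))
            for pos, k in enumerate(order, start=1):
                obj, is_target = seq[k]
                rows.append(
                    {
                        "block": block,
                        "trial": trial,
                        "position": pos,
                        "object_id": obj,
                        "is_target": is_target,
                    }
                )
    return pd.DataFrame(rows)


def simulate_responses(
    schedule: pd.DataFrame,
    hit_rate: float,
    fa_rate: float,
    rt_mean_ms: float,
    rt_sd_ms: float,
    rng: Optional[np.random.Generator] = None,
    seed=None,
    miss_rate: float = 0.0,
) -> pd.DataFrame:
    """A response log consistent with the given hit/false-alarm rates."""
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for rec in schedule.itertuples(index=False):
        if rng.random() < miss_rate:
            rows.append({"trial": rec.trial, "position": rec.position,
                         "response": "none", "rt_ms": np.nan})
            continue
        p_match = hit_rate if rec.is_target else fa_rate
        response = "match" if rng.random() < p_match else "nonmatch"
        rt = max(150.0, rng.normal(rt_mean_ms, rt_sd_ms))
        rows.append({"trial": rec.trial, "position": rec.position,
                     "response": response, "rt_ms": rt})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def coupling_for_target_r(target_r: float, sd_change: float, noise_sd: float) -> float:
    """Slope giving population correlation ``target_r`` between change and
    performance when performance = baseline + slope * change + N(0, noise_sd)."""
    if not (-1.0 < target_r < 1.0):
        raise ValueError("target_r must lie strictly inside (-1, 1)")
    if sd_change <= 0 or noise_sd <= 0:
        raise ValueError("sd_change and noise_sd must be positive")
    return target_r / np.sqrt(1.0 - target_r**2) * noise_sd / sd_change


def generate_behavior(
    state_change,
    coupling: float,
    noise_sd: float,
    rng: Optional[np.random.Generator] = None,
    seed=None,
    baseline=1.5e-3,
    rt_mean_ms=610.0,
    rt_sd_ms=60.0,
) -> pd.DataFrame:
    """Per-subject (accuracy, RT, performance) coupled to a state change.

    performance = baseline + coupling * change + Gaussian noise; RT is drawn
    from a truncated normal and accuracy = performance * RT (clipped to
    [0, 1]), so performance = accuracy / RT holds exactly wherever clipping
    is inactive. ``baseline``/``rt_mean_ms``/``rt_sd_ms`` may be scalars or
    per-subject arrays.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    change = np.asarray(state_change, dtype=float)
    n = change.size
    if rng is None:
        rng = np.random.default_rng(seed)
    perf = np.broadcast_to(np.asarray(baseline, float), (n,)).copy()
    perf += coupling * change
    if noise_sd > 0:
        perf += rng.normal(0.0, noise_sd, size=n)
    rt = rng.normal(
        np.broadcast_to(np.asarray(rt_mean_ms, float), (n,)),
        np.broadcast_to(np.asarray(rt_sd_ms, float), (n,)),
    )
    rt = np.maximum(rt, 150.0)
    accuracy = np.clip(perf * rt, 0.0, 1.0)
    return pd.DataFrame(
        {
            "state_change": change,
            "accuracy": accuracy,
            "rt_ms": rt,
            "performance": accuracy / rt,
        }
    )


# ---------------------------------------------------------------------------
# full cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A generated cohort: tables plus in-memory BOLD pairs per subject."""

    config: PhantomConfig
    subjects: pd.DataFrame
    mask: np.ndarray
    bold: Dict[Tuple[str, str], BoldSeries]
    nuisance: Dict[Tuple[str, str], pd.DataFrame]
    motion: Dict[Tuple[str, str], pd.DataFrame]
    schedules: Dict[str, pd.DataFrame]
    responses: Dict[str, pd.DataFrame]

    @property
    def subject_ids(self) -> np.ndarray:
        return self.subjects["subject_id"].to_numpy()


def generate_cohort(config: PhantomConfig) -> Cohort:
    """Generate a full synthetic cohort under ``config`` (seeded, deterministic).

    Per subject: covariates from the group profile, per-state synchrony
    weights jittered around the planted cell values, a BOLD pair, motion and
    nuisance tables, a DMST schedule and a simulated response log whose
    scoring approximates the subject's generative accuracy.
    """
    config.validate()
    mask = np.ones(config.grid_shape, dtype=bool)
    n_total = int(sum(config.n_per_group))
    children = np.random.SeedSequence(config.rng_seed).spawn(n_total + 1)

    rows: List[dict] = []
    subject_rngs: List[np.random.Generator] = []
    bold: Dict[Tuple[str, str], BoldSeries] = {}
    nuisance: Dict[Tuple[str, str], pd.DataFrame] = {}
    motion: Dict[Tuple[str, str], pd.DataFrame] = {}

    idx = 0
    for group, n in zip(config.groups, config.n_per_group):
        profile = GROUP_PROFILES[group]
        for i in range(int(n)):
            rng = np.random.default_rng(children[idx])
            subject_rngs.append(rng)
            sid = f"{group.lower()}{i + 1:02d}"
            age = rng.normal(*profile["age"])
            sex = int(rng.random() < profile["male_p"])
            education = rng.normal(*profile["education"])
            gm = rng.normal(*profile["gm_intensity"])

            # jittered per-state weights; the first planted effect defines the
            # subject's planted state change fed into the behaviour model
            effects_by_state: Dict[str, List[PlantedEffect]] = {}
            w_by_state: Dict[str, float] = {}
            for state in STATES:
                effs = []
                for j, eff in enumerate(config.planted_clusters):
                    w = float(
                        np.clip(
                            eff.weight((group, state)) + rng.normal(0.0, config.w_jitter_sd),
                            0.0,
                            1.0,
                        )
                    )
                    if j == 0:
                        w_by_state[state] = w
                    effs.append(replace(eff, coupling_by_cell={(group, state): w}))
                effects_by_state[state] = effs
            if not config.planted_clusters:
                w_by_state = {s: 0.0 for s in STATES}

            fds = []
            for state in STATES:
                series = generate_bold(
                    config.grid_shape,
                    config.n_volumes,
                    config.tr_s,
                    effects_by_state[state],
                    (group, state),
                    noise_sd=config.noise_sd,
                    rng=rng,
                    baseline=config.baseline,
                    global_weight=config.global_weight,
                    mask=mask,
                )
                series.voxel_size_mm[:] = config.voxel_size_mm
                mot = simulate_motion(config.n_volumes, rng)
                bold[(sid, state)] = series
                motion[(sid, state)] = mot
                nuisance[(sid, state)] = nuisance_table(series, mot, rng)
                fds.append(mean_framewise_displacement(mot.to_numpy()))

            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "age": age,
                    "sex": sex,
                    "education": education,
                    "motion": float(np.mean(fds)),
                    "gm_intensity": gm,
                    "planted_change": w_by_state["task"] - w_by_state["rest"],
                }
            )
            idx += 1

    subjects = pd.DataFrame(rows)

    # behaviour coupled to the planted state change, per group baselines
    beh_rng = np.random.default_rng(children[-1])
    baselines = subjects["group"].map(
        {g: GROUP_PROFILES[g]["performance_baseline"] for g in config.groups}
    ).to_numpy()
    rt_means = subjects["group"].map(
        {g: GROUP_PROFILES[g]["rt_ms"][0] for g in config.groups}
    ).to_numpy()
    rt_sds = subjects["group"].map(
        {g: GROUP_PROFILES[g]["rt_ms"][1] for g in config.groups}
    ).to_numpy()
    beh = generate_behavior(
        subjects["planted_change"].to_numpy(),
        config.behavior_coupling,
        config.behavior_noise_sd,
        rng=beh_rng,
        baseline=baselines,
        rt_mean_ms=rt_means,
        rt_sd_ms=rt_sds,
    )
    subjects = pd.concat([subjects, beh[["accuracy", "rt_ms", "performance"]]], axis=1)

    # DMST schedules and response logs consistent with each subject's scores
    schedules: Dict[str, pd.DataFrame] = {}
    responses: Dict[str, pd.DataFrame] = {}
    if config.include_response_logs:
        for rng, rec in zip(subject_rngs, subjects.itertuples(index=False)):
            sched = generate_dmst_schedule(rng=rng)
            hit = float(np.clip(rec.accuracy + 0.05, 0.0, 1.0))
            fa = float(np.clip(hit - rec.accuracy, 0.0, 1.0))
            responses[rec.subject_id] = simulate_responses(
                sched, hit, fa, rec.rt_ms, 80.0, rng=rng, miss_rate=0.02
            )
            schedules[rec.subject_id] = sched

    return Cohort(
        config=config,
        subjects=subjects,
        mask=mask,
        bold=bold,
        nuisance=nuisance,
        motion=motion,
        schedules=schedules,
        responses=responses,
    )
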