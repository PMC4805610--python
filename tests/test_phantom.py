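"""Synthetic cohort generator: bookkeeping, determinism, planted effects."""

import numpy as np
import pandas as pd
import pytest

from rehoband.bands import get_band
from rehoband.behavior import score_dmst
from rehoband.core import BoldSeries
from rehoband.phantom import (
    PhantomConfig,
    PlantedEffect,
    block_cluster,
    band_limited_latent,
    coupling_for_target_r,
    generate_behavior,
    generate_bold,
    generate_cohort,
    generate_dmst_schedule,
    simulate_responses,
)
from rehoband.reho import reho_map


def test_cohort_default_group_sizes():
    """Default cohort composition: 16 controls and 17 patients."""
    cfg = PhantomConfig(grid_shape=(10, 10, 6), rng_seed=3, include_response_logs=False)
    cohort = generate_cohort(cfg)
    counts = cohort.subjects["group"].value_counts()
    assert counts["NC"] == 16 and counts["MCI"] == 17
    assert len(cohort.bold) == 33 * 2


def test_cohort_bookkeeping_tiny(tiny_cohort):
    cohort = tiny_cohort
    assert len(cohort.subjects) == 6
    for sid in cohort.subject_ids:
        for state in ("rest", "task"):
            series = cohort.bold[(sid, state)]
            assert isinstance(series, BoldSeries)
            assert series.data.shape == (12, 12, 8, 154)
            assert series.tr_s == 2.0
            nuis = cohort.nuisance[(sid, state)]
            assert len(nuis) == 154
            assert list(nuis.columns) == [
                "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
                "global", "white_matter", "csf",
            ]
    assert {"age", "sex", "education", "motion", "performance"} <= set(
        cohort.subjects.columns
    )


def test_cohort_seeded_determinism():
    cfg = dict(n_per_group=(2, 2), grid_shape=(8, 8, 6), rng_seed=21)
    a = generate_cohort(PhantomConfig(**cfg))
    b = generate_cohort(PhantomConfig(**cfg))
    pd.testing.assert_frame_equal(a.subjects, b.subjects)
    for key in a.bold:
        assert np.array_equal(a.bold[key].data, b.bold[key].data)
        pd.testing.assert_frame_equal(a.nuisance[key], b.nuisance[key])
    for sid in a.schedules:
        pd.testing.assert_frame_equal(a.schedules[sid], b.schedules[sid])
        pd.testing.assert_frame_equal(a.responses[sid], b.responses[sid])


def test_config_validation_errors():
    with pytest.raises(ValueError):
        PhantomConfig(n_volumes=4)
    with pytest.raises(ValueError):
        PhantomConfig(tr_s=-1.0)
    with pytest.raises(ValueError):
        PhantomConfig(n_per_group=(0, 5))
    outside = PlantedEffect(
        cluster_voxels=np.array([[50, 0, 0]]),
        band="slow-5",
        coupling_by_cell={("NC", "rest"): 0.5},
    )
    with pytest.raises(ValueError, match="outside the grid"):
        PhantomConfig(grid_shape=(8, 8, 8), planted_clusters=[outside])
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        PlantedEffect(np.array([[0, 0, 0]]), "slow-5", {("NC", "rest"): 1.2})


def test_planted_cluster_must_be_connected():
    apart = np.array([[0, 0, 0], [5, 5, 5]])
    eff = PlantedEffect(apart, "slow-5", {("NC", "rest"): 0.5})
    with pytest.raises(ValueError, match="not connected"):
        eff.validate_grid((8, 8, 8))


def test_shared_signal_limit_pairwise_correlation(rng):
    grid = (8, 8, 6)
    eff = PlantedEffect(
        block_cluster(grid, (3, 3, 3)), "slow-5", {("NC", "rest"): 1.0}
    )
    series = generate_bold(grid, 154, 2.0, [eff], ("NC", "rest"), rng=rng,
                           global_weight=0.0)
    v = eff.cluster_voxels
    a = series.data[tuple(v[0])]
    b = series.data[tuple(v[-1])]
    assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0, abs=1e-10)


def test_in_cluster_reho_monotone_in_synchrony(rng):
    """Achieved in-cluster mean W is non-decreasing in the planted weight."""
    grid = (10, 10, 6)
    voxels = block_cluster(grid, (4, 4, 3))
    means = []
    for w in (0.0, 0.3, 0.6, 0.9):
        eff = PlantedEffect(voxels, "slow-5", {("NC", "rest"): w})
        series = generate_bold(grid, 154, 2.0, [eff], ("NC", "rest"),
                               rng=np.random.default_rng(77), global_weight=0.0)
        rmap = reho_map(series, 26)
        means.append(rmap.values[tuple(voxels.T)].mean())
    assert all(b > a - 0.01 for a, b in zip(means, means[1:]))
    assert means[-1] > means[0] + 0.2


def test_latent_band_purity():
    """>= 90% of the latent's periodogram mass lies inside its band (the
    ideal filter actually makes it essentially all of it)."""
    for name in ("slow-5", "slow-3"):
        band = get_band(name)
        latent = band_limited_latent(154, 2.0, band, np.random.default_rng(5))
        power = np.abs(np.fft.rfft(latent)) ** 2
        freqs = np.fft.rfftfreq(154, d=2.0)
        inside = (freqs > band.f_low) & (freqs <= band.f_high)
        assert power[inside].sum() / power.sum() >= 0.9


# ---------------------------------------------------------------------------
# DMST schedules and response logs
# ---------------------------------------------------------------------------

def test_dmst_schedule_satisfies_design():
    sched = generate_dmst_schedule(4, 8, seed=9)
    assert sched["trial"].nunique() == 32
    for _, trial in sched.groupby("trial"):
        assert len(trial) in (12, 13)  # test objects per trial
        targets = trial[trial["is_target"]]["object_id"].unique()
        assert len(targets) == 2
        reps = trial["object_id"].value_counts()
        assert reps.between(2, 4).all()
    assert sched.groupby("trial")["block"].nunique().eq(1).all()


def test_dmst_schedule_infeasible_configuration():
    with pytest.raises(ValueError):
        generate_dmst_schedule(n_targets=7, seed=0)  # 7 targets x >=2 cannot fit


def test_response_simulation_scores_back(rng):
    sched = generate_dmst_schedule(4, 8, rng=rng)
    resp = simulate_responses(sched, hit_rate=1.0, fa_rate=0.0,
                              rt_mean_ms=600.0, rt_sd_ms=50.0, rng=rng)
    score = score_dmst(resp, sched)
    assert score.accuracy == 1.0
    assert 400 < score.rt_ms < 800


# ---------------------------------------------------------------------------
# behaviour generator
# ---------------------------------------------------------------------------

def test_behavior_noiseless_negative_coupling_is_a_line(rng):
    change = rng.standard_normal(12) * 0.05
    # baseline low enough that accuracy never clips at 1, so the noiseless
    # relation stays an exact line
    out = generate_behavior(change, coupling=-2e-3, noise_sd=0.0, seed=4,
                            baseline=1.1e-3)
    r = np.corrcoef(change, out["performance"])[0, 1]
    assert r == pytest.approx(-1.0, abs=1e-12)
    assert (out["accuracy"] <= 1).all() and (out["accuracy"] >= 0).all()
    assert (out["rt_ms"] > 0).all()


def test_behavior_null_coupling_centres_on_zero():
    rs = []
    rng = np.random.default_rng(10)
    for _ in range(300):
        change = rng.standard_normal(17) * 0.05
        out = generate_behavior(change, coupling=0.0, noise_sd=6e-5, rng=rng)
        rs.append(np.corrcoef(change, out["performance"])[0, 1])
    assert abs(np.mean(rs)) < 2.5 / np.sqrt(17 * 300)  # ~2 SE of the mean


def test_coupling_inversion_closed_form():
    c = coupling_for_target_r(-0.63, sd_change=1.0, noise_sd=1.0)
    implied = c / np.sqrt(c**2 + 1.0)
    assert implied == pytest.approx(-0.63, abs=1e-12)
    with pytest.raises(ValueError):
        coupling_for_target_r(1.0, 1.0, 1.0)


def test_cohort_behaviour_consistency(tiny_cohort):
    subjects = tiny_cohort.subjects
    # performance = accuracy / RT by construction
    assert np.allclose(
        subjects["performance"], subjects["accuracy"] / subjects["rt_ms"]
    )
    assert subjects["rt_ms"].gt(0).all()
    assert subjects["accuracy"].between(0, 1).all()
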