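"""Interaction mapping, Monte-Carlo extent threshold, clusters, post-hoc tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rehoband.groupstats import (
    cluster_cell_means,
    estimate_map_fwhm,
    extract_clusters,
    interaction_map,
    monte_carlo_cluster_threshold,
    posthoc_t,
    state_difference,
)


def _design(n1=8, n2=9, rng=None, covariates=True):
    n = n1 + n2
    rows = {
        "subject_id": [f"s{i:02d}" for i in range(n)],
        "group": ["NC"] * n1 + ["MCI"] * n2,
    }
    if covariates:
        rng = rng or np.random.default_rng(0)
        rows.update(
            age=rng.normal(70, 5, n),
            sex=rng.integers(0, 2, n),
            education=rng.normal(11, 3, n),
            motion=rng.random(n) * 0.1,
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# difference maps
# ---------------------------------------------------------------------------

def test_state_difference(rng):
    task = rng.standard_normal((4, 4, 3))
    rest = rng.standard_normal((4, 4, 3))
    diff = state_difference(task, rest)
    for idx in np.ndindex(*task.shape):  # direct elementwise oracle
        assert diff[idx] == task[idx] - rest[idx]
    assert np.all(state_difference(task, task) == 0.0)
    assert state_difference(np.array([[[1.2]]]), np.array([[[0.7]]]))[0, 0, 0] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        state_difference(task, rest[:2])


# ---------------------------------------------------------------------------
# interaction F
# ---------------------------------------------------------------------------

def test_interaction_equals_squared_two_sample_t(rng):
    """Without covariates, the interaction F is exactly the squared pooled
    two-sample t on difference scores."""
    design = _design(8, 9, covariates=False)
    diffs = rng.standard_normal((17, 5, 4, 3))
    res = interaction_map(diffs, design, covariates=())
    d = diffs.reshape(17, -1)
    t, p = stats.ttest_ind(d[:8], d[8:], axis=0, equal_var=True)
    assert np.allclose(res.f_map.ravel(), t**2, atol=1e-10)
    assert np.allclose(res.p_map.ravel(), p, atol=1e-10)
    assert res.df == (1, 15)


def test_interaction_matches_mixed_anova_oracle(rng):
    """Cross-check against an independent mixed-ANOVA implementation."""
    pg = pytest.importorskip("pingouin")
    design = _design(6, 7, covariates=False)
    rest = rng.standard_normal((13, 2, 1, 1))
    task = rng.standard_normal((13, 2, 1, 1))
    res = interaction_map(task - rest, design, covariates=())
    for v in range(2):
        long = pd.DataFrame(
            {
                "subject": np.repeat(design["subject_id"], 2),
                "group": np.repeat(design["group"], 2),
                "state": ["rest", "task"] * 13,
                "y": np.column_stack([rest[:, v, 0, 0], task[:, v, 0, 0]]).ravel(),
            }
        )
        aov = pg.mixed_anova(data=long, dv="y", within="state",
                             between="group", subject="subject")
        f_oracle = float(aov.loc[aov["Source"] == "Interaction", "F"].iloc[0])
        assert res.f_map[v, 0, 0] == pytest.approx(f_oracle, rel=1e-8)


def test_interaction_invariant_to_state_constant_shift(rng):
    """Adding a constant to every map of one state leaves F untouched:
    difference scores absorb state main effects."""
    design = _design(6, 6)
    rest = rng.standard_normal((12, 4, 3, 2))
    task = rng.standard_normal((12, 4, 3, 2))
    base = interaction_map(task - rest, design)
    shifted = interaction_map((task + 5.0) - rest, design)
    assert np.allclose(base.f_map, shifted.f_map, atol=1e-8)


def test_interaction_type_i_rate_is_nominal(rng):
    """Null diffs: fraction of voxels with p < 0.01 inside the binomial band."""
    design = _design(16, 17)
    diffs = rng.standard_normal((33, 12, 10, 10))
    res = interaction_map(diffs, design)
    rate = (res.p_map < 0.01).mean()
    n_vox = res.p_map.size
    half_width = 1.96 * np.sqrt(0.01 * 0.99 / n_vox)
    assert abs(rate - 0.01) < half_width


def test_interaction_zero_variance_voxel(rng):
    design = _design(4, 4, covariates=False)
    diffs = np.zeros((8, 2, 1, 1))
    diffs[:, 1, 0, 0] = rng.standard_normal(8)
    res = interaction_map(diffs, design, covariates=())
    assert res.f_map[0, 0, 0] == 0.0 and res.p_map[0, 0, 0] == 1.0


def test_interaction_requires_three_per_group(rng):
    design = _design(2, 5, covariates=False)
    with pytest.raises(ValueError, match="fewer than 3"):
        interaction_map(rng.standard_normal((7, 2, 2, 2)), design, covariates=())


# ---------------------------------------------------------------------------
# Monte-Carlo extent threshold
# ---------------------------------------------------------------------------

def test_mc_threshold_alpha_one_and_bernoulli_expectation():
    mask = np.ones((25, 25, 16), dtype=bool)  # 10^4 voxels
    res = monte_carlo_cluster_threshold(
        mask, fwhm_mm=0.0, p_voxel=0.01, alpha=1.0, n_iter=300,
        connectivity=26, seed=3,
    )
    assert res.k_star == 1  # everything passes at alpha = 1
    # unsmoothed field: iid Bernoulli(p) voxels, expected count = p * V = 100
    assert res.mean_suprathreshold == pytest.approx(100.0, abs=3.0)


def test_mc_threshold_grows_with_smoothing():
    mask = np.ones((20, 20, 12), dtype=bool)
    common = dict(p_voxel=0.01, alpha=0.05, n_iter=300, connectivity=26, seed=4)
    rough = monte_carlo_cluster_threshold(mask, fwhm_mm=0.0, **common)
    smoothed = monte_carlo_cluster_threshold(mask, fwhm_mm=8.0, **common)
    assert rough.k_star <= 8  # an unsmoothed Bernoulli field only forms tiny clusters
    assert smoothed.k_star > rough.k_star


def test_mc_threshold_monotone_in_alpha():
    mask = np.ones((14, 14, 10), dtype=bool)
    common = dict(fwhm_mm=4.0, p_voxel=0.01, n_iter=300, connectivity=18, seed=5)
    strict = monte_carlo_cluster_threshold(mask, alpha=0.01, **common)
    loose = monte_carlo_cluster_threshold(mask, alpha=0.2, **common)
    assert strict.k_star >= loose.k_star


def test_mc_threshold_input_validation():
    mask = np.ones((5, 5, 5), dtype=bool)
    with pytest.raises(ValueError):
        monte_carlo_cluster_threshold(mask, 0.0, 0.01, alpha=1.5, n_iter=100)
    with pytest.raises(ValueError):
        monte_carlo_cluster_threshold(mask, 0.0, 0.01, alpha=0.05, n_iter=50)


def test_estimate_map_fwhm_recovers_applied_smoothness(rng):
    from scipy import ndimage

    true_fwhm = 6.0
    sigma = true_fwhm / (3.0 * 2.3548)
    maps = ndimage.gaussian_filter(rng.standard_normal((30, 30, 20)), sigma)
    est = estimate_map_fwhm(maps, np.ones((30, 30, 20), bool), 3.0)
    assert np.all(est > 0.6 * true_fwhm) and np.all(est < 1.2 * true_fwhm)


# ---------------------------------------------------------------------------
# cluster extraction
# ---------------------------------------------------------------------------

def _blob_maps(shape, voxels, stat=10.0):
    f = np.zeros(shape)
    p = np.ones(shape)
    for v in voxels:
        f[v] = stat
        p[v] = 1e-4
    return f, p


def test_extract_clusters_extent_rule():
    shape = (10, 10, 10)
    blob = [(x, y, z) for x in range(2, 7) for y in range(2, 8) for z in range(2, 5)]
    assert len(blob) == 90
    f, p = _blob_maps(shape, blob)
    table, labels = extract_clusters(f, p, 0.01, 85, connectivity=18)
    assert len(table) == 1 and table.loc[0, "size"] == 90
    assert (labels > 0).sum() == 90
    # raising the extent threshold past the blob size empties the table
    table96, _ = extract_clusters(f, p, 0.01, 96, connectivity=18)
    assert table96.empty


def test_extract_clusters_connectivity_semantics():
    """Two blobs touching only at a corner: separate under 18, merged under 26."""
    shape = (8, 8, 8)
    blob_a = [(x, y, 0) for x in (0, 1) for y in (0, 1)]
    blob_b = [(x, y, 1) for x in (2, 3) for y in (2, 3)]
    f, p = _blob_maps(shape, blob_a + blob_b)
    t18, _ = extract_clusters(f, p, 0.01, 1, connectivity=18)
    t26, _ = extract_clusters(f, p, 0.01, 1, connectivity=26)
    assert len(t18) == 2
    assert len(t26) == 1


def test_extract_clusters_peak_tiebreak_lexicographic():
    shape = (5, 5, 5)
    blob = [(2, 2, 2), (2, 2, 3), (2, 3, 2)]
    f, p = _blob_maps(shape, blob, stat=7.0)  # all peaks tie
    table, _ = extract_clusters(f, p, 0.01, 1, connectivity=26)
    assert (table.loc[0, ["peak_x", "peak_y", "peak_z"]] == [2, 2, 2]).all()


# ---------------------------------------------------------------------------
# post-hoc tests
# ---------------------------------------------------------------------------

def _cell_means_frame(rest_nc, task_nc, rest_m, task_m):
    n1, n2 = len(rest_nc), len(rest_m)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n1 + n2)],
            "group": ["NC"] * n1 + ["MCI"] * n2,
            "rest": np.concatenate([rest_nc, rest_m]),
            "task": np.concatenate([task_nc, task_m]),
        }
    )


def test_posthoc_identical_groups_give_zero_t(rng):
    vals = rng.standard_normal(4)
    other = rng.standard_normal(4)
    table = posthoc_t(_cell_means_frame(vals, other, vals, other))
    between = table[table["comparison"] == "NC vs MCI"]
    assert np.allclose(between["t"], 0.0, atol=1e-12)


def test_posthoc_matches_textbook_formulas(rng):
    a = rng.standard_normal(4) + 0.5
    b = rng.standard_normal(4)
    table = posthoc_t(_cell_means_frame(a, np.zeros(4), b, np.zeros(4)))
    row = table[(table["comparison"] == "NC vs MCI") & (table["state"] == "rest")].iloc[0]
    # pooled-variance two-sample t, written out directly
    sp2 = (3 * a.var(ddof=1) + 3 * b.var(ddof=1)) / 6
    t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
    assert row["t"] == pytest.approx(t_hand, abs=1e-12)
    # paired t for the NC task-vs-rest change
    d = np.zeros(4) - a
    t_paired = d.mean() / (d.std(ddof=1) / 2.0)
    row_nc = table[(table["comparison"] == "task vs rest") & (table["group"] == "NC")].iloc[0]
    assert row_nc["t"] == pytest.approx(t_paired, abs=1e-12)
    assert row_nc["direction"] == "decrease"


def test_posthoc_requires_two_per_group():
    frame = _cell_means_frame(np.array([1.0]), np.array([1.0]),
                              np.arange(3.0), np.arange(3.0))
    with pytest.raises(ValueError):
        posthoc_t(frame)


def test_cluster_cell_means_oracle(rng):
    design = _design(3, 3, covariates=False)
    rest = rng.standard_normal((6, 4, 4, 4))
    task = rng.standard_normal((6, 4, 4, 4))
    voxels = np.array([[0, 0, 0], [1, 2, 3], [3, 3, 3]])
    cm = cluster_cell_means(rest, task, voxels, design)
    manual = np.mean([rest[0][tuple(v)] for v in voxels])
    assert cm.loc[0, "rest"] == pytest.approx(manual, abs=1e-12)
    assert np.allclose(cm["change"], cm["task"] - cm["rest"])
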