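"""Kendall's W, neighbourhoods, ReHo maps, standardization and smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rehoband.core import BoldSeries, ReHoMap
from rehoband.phantom import PhantomConfig, PlantedEffect, block_cluster, generate_bold
from rehoband.reho import (
    fwhm_to_sigma_voxels,
    kendalls_w,
    neighborhood,
    reho_map,
    smooth,
    standardize,
)


# ---------------------------------------------------------------------------
# brute-force oracle: explicit average ranks + direct formula, pure python
# ---------------------------------------------------------------------------

def _avg_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for m in range(i, j + 1):
            ranks[order[m]] = avg
        i = j + 1
    return ranks


def kendalls_w_bruteforce(series_set):
    x = [list(map(float, row)) for row in series_set]
    k, n = len(x), len(x[0])
    ranks = [_avg_ranks(row) for row in x]
    rank_sums = [sum(ranks[i][t] for i in range(k)) for t in range(n)]
    mean_r = sum(rank_sums) / n
    s = sum((r - mean_r) ** 2 for r in rank_sums)
    tie = 0.0
    for row in x:
        for v in set(row):
            t_cnt = row.count(v)
            tie += t_cnt**3 - t_cnt
    denom = k * k * (n**3 - n) - k * tie
    return 12.0 * s / denom if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# neighbourhoods
# ---------------------------------------------------------------------------

def test_neighbourhood_counts():
    mask = np.ones((5, 5, 5), dtype=bool)
    assert len(neighborhood((2, 2, 2), mask, 26)) == 26
    assert len(neighborhood((2, 2, 2), mask, 6)) == 6
    assert len(neighborhood((2, 2, 2), mask, 18)) == 18


def test_neighbourhood_corner_enumeration():
    """Corner of a cubic mask: the 3x3x3 cube clipped to the grid leaves 7."""
    mask = np.ones((4, 4, 4), dtype=bool)
    nbrs = neighborhood((0, 0, 0), mask, 26)
    expected = {
        (x, y, z)
        for x in (0, 1) for y in (0, 1) for z in (0, 1)
        if (x, y, z) != (0, 0, 0)
    }
    assert set(nbrs) == expected and len(nbrs) == 7


def test_neighbourhood_outside_mask_errors():
    mask = np.zeros((3, 3, 3), dtype=bool)
    mask[1, 1, 1] = True
    with pytest.raises(ValueError):
        neighborhood((0, 0, 0), mask, 26)
    with pytest.raises(ValueError):
        neighborhood((5, 0, 0), mask, 26)


# ---------------------------------------------------------------------------
# Kendall's W
# ---------------------------------------------------------------------------

def test_kendalls_w_limits():
    base = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
    identical = np.tile(base, (4, 1))
    assert kendalls_w(identical) == pytest.approx(1.0, abs=1e-12)
    reversed_pair = np.vstack([base, -base])
    assert kendalls_w(reversed_pair) == pytest.approx(0.0, abs=1e-12)


def test_kendalls_w_worked_example():
    # rank patterns (1,2,3,4), (1,2,3,4), (4,3,2,1): S = 5, denominator 540
    x = np.array([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]], dtype=float)
    assert kendalls_w(x) == pytest.approx(1.0 / 9.0, abs=1e-12)
    assert kendalls_w_bruteforce(x) == pytest.approx(1.0 / 9.0, abs=1e-12)


def test_kendalls_w_matches_bruteforce_on_random_instances(rng):
    """100 random instances (k <= 5, n <= 8), half with ties, to 1e-12."""
    for trial in range(100):
        k = int(rng.integers(2, 6))
        n = int(rng.integers(2, 9))
        if trial % 2:
            x = rng.integers(0, 4, size=(k, n)).astype(float)  # heavy ties
        else:
            x = rng.standard_normal((k, n))
        if np.all(np.ptp(x, axis=1) == 0):
            continue
        assert kendalls_w(x) == pytest.approx(kendalls_w_bruteforce(x), abs=1e-12)


def test_kendalls_w_matches_friedman_statistic(rng):
    """Independent cross-check: W = Q / (k (n - 1)) with Friedman's chi-square
    over n time points treated as treatments and k series as blocks."""
    x = rng.standard_normal((6, 5))
    q, _ = stats.friedmanchisquare(*(x[:, t] for t in range(x.shape[1])))
    k, n = x.shape
    assert kendalls_w(x) == pytest.approx(q / (k * (n - 1)), abs=1e-12)


def test_kendalls_w_degenerate_all_constant():
    x = np.ones((3, 5))
    assert kendalls_w(x) == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1), st.integers(2, 5), st.integers(2, 8))
def test_kendalls_w_bounded(seed, k, n):
    x = np.random.default_rng(seed).integers(0, 5, size=(k, n)).astype(float)
    assert 0.0 <= kendalls_w(x) <= 1.0


def test_friedman_null_calibration(rng):
    """Under independence, k(n-1)W approximates chi-square(n-1): its mean is
    exactly n-1 and its variance close to 2(n-1) (Monte-Carlo check)."""
    k, n, reps = 10, 8, 2000
    q = np.empty(reps)
    for i in range(reps):
        q[i] = k * (n - 1) * kendalls_w(rng.standard_normal((k, n)))
    assert q.mean() == pytest.approx(n - 1, abs=0.3)
    assert q.var() == pytest.approx(2 * (n - 1), rel=0.15)


# ---------------------------------------------------------------------------
# ReHo maps
# ---------------------------------------------------------------------------

def test_reho_map_shared_signal_cluster(rng):
    """w = 1 cluster: interior voxels share one series, so W -> 1 there."""
    grid = (10, 10, 6)
    effect = PlantedEffect(
        cluster_voxels=block_cluster(grid, (4, 4, 3)),
        band="slow-5",
        coupling_by_cell={("NC", "rest"): 1.0},
    )
    series = generate_bold(grid, 154, 2.0, [effect], ("NC", "rest"),
                           rng=rng, global_weight=0.0)
    rmap = reho_map(series, 26)
    # the block spans x,y 3..6 and z 1..3, so (4, 4, 2) has its whole
    # 26-neighbourhood inside the shared-signal cluster
    assert rmap.values[4, 4, 2] > 0.95
    assert np.all(rmap.values >= 0) and np.all(rmap.values <= 1)


def test_reho_map_duplicated_voxel_series(rng):
    one = rng.standard_normal(30)
    data = np.broadcast_to(one, (3, 3, 3, 30)).copy()
    rmap = reho_map(BoldSeries(data, 2.0), 26)
    assert rmap.values[1, 1, 1] == pytest.approx(1.0, abs=1e-12)


def test_reho_map_independence_expectation(rng):
    """Pure independent noise: mean W over full-neighbourhood voxels ~ 1/27."""
    series = BoldSeries(rng.standard_normal((12, 12, 8, 154)), 2.0)
    rmap = reho_map(series, 26)
    interior = rmap.values[1:-1, 1:-1, 1:-1]
    assert interior.mean() == pytest.approx(1.0 / 27.0, abs=0.002)


def test_reho_map_empty_mask_errors(rng):
    data = rng.standard_normal((3, 3, 3, 10))
    with pytest.raises(ValueError):
        reho_map(BoldSeries(data, 2.0, mask=np.zeros((3, 3, 3), bool)), 26)


# ---------------------------------------------------------------------------
# standardization and smoothing
# ---------------------------------------------------------------------------

def test_standardize_hand_example():
    mask = np.zeros((3, 1, 1), dtype=bool)
    mask[:, 0, 0] = True
    vals = np.zeros((3, 1, 1))
    vals[:, 0, 0] = [0.2, 0.4, 0.6]  # mean 0.4, sample SD 0.2
    z = standardize(ReHoMap(vals, mask))
    assert np.allclose(z.values[:, 0, 0], [-1.0, 0.0, 1.0], atol=1e-12)


def test_standardize_properties_and_errors(rng):
    mask = np.ones((6, 6, 4), dtype=bool)
    z = standardize(ReHoMap(rng.random((6, 6, 4)), mask))
    inside = z.values[mask]
    assert inside.mean() == pytest.approx(0.0, abs=1e-8)
    assert inside.std(ddof=1) == pytest.approx(1.0, abs=1e-8)
    with pytest.raises(ValueError):
        standardize(ReHoMap(np.full((3, 3, 3), 0.5), np.ones((3, 3, 3), bool)))
    with pytest.raises(ValueError):
        standardize(z)  # already standardized


def test_smooth_identity_sigma_and_kernel():
    assert fwhm_to_sigma_voxels(4.0, 3.0)[0] == pytest.approx(0.56624, abs=1e-4)

    mask = np.ones((21, 21, 21), dtype=bool)
    impulse = np.zeros((21, 21, 21))
    impulse[10, 10, 10] = 1.0
    rmap = ReHoMap(impulse, mask, standardized=True)
    assert np.array_equal(smooth(rmap, 0.0).values, impulse)

    out = smooth(rmap, 6.0).values
    assert out.sum() == pytest.approx(1.0, abs=1e-6)  # normalized kernel
    assert np.allclose(out, out[::-1, :, :], atol=1e-12)  # radially symmetric
    assert np.allclose(out, np.transpose(out, (2, 1, 0)), atol=1e-12)

    with pytest.raises(ValueError):
        smooth(rmap, -1.0)
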