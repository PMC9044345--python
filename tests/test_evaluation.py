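"""PSNR/SSIM against brute-force oracles; aggregation; Friedman rank test."""

import numpy as np
import pytest
from scipy import stats

from despeckle.evaluation import (
    PSNR_CAP_DB,
    aggregate_runs,
    evaluate_pairs,
    friedman_test,
    psnr,
    ssim,
)
from despeckle.image import GrayImage, Scale
from despeckle.noise import SpeckleParams, add_speckle
from despeckle.training import dihedral_transform

RNG = np.random.default_rng(55)


def unit(pixels):
    return GrayImage(np.asarray(pixels, dtype=np.float64), Scale.UNIT)


# ----------------------------------------------------------------------- PSNR


def psnr_oracle(ref, test, vmax):
    mse = np.mean((np.asarray(ref) - np.asarray(test)) ** 2)
    return 10.0 * np.log10(vmax**2 / mse)


def test_uniform_difference_gives_exactly_twenty_db():
    a = unit(np.full((16, 16), 0.5))
    b = unit(np.full((16, 16), 0.6))
    assert psnr(a, b) == pytest.approx(10.0 * np.log10(1.0 / 0.01), abs=1e-12)
    assert psnr(a, b) == pytest.approx(20.0, abs=1e-9)


def test_psnr_matches_oracle_on_random_pairs():
    for _ in range(50):
        a, b = RNG.random((32, 32)), RNG.random((32, 32))
        assert psnr(unit(a), unit(b)) == pytest.approx(psnr_oracle(a, b, 1.0), abs=1e-6)


def test_identical_images_hit_the_cap():
    img = unit(RNG.random((16, 16)))
    assert psnr(img, img) == PSNR_CAP_DB


def test_psnr_uses_scale_maximum():
    a = GrayImage(np.full((8, 8), 100.0), Scale.EIGHT_BIT)
    b = GrayImage(np.full((8, 8), 110.0), Scale.EIGHT_BIT)
    assert psnr(a, b) == pytest.approx(10 * np.log10(255.0**2 / 100.0), abs=1e-9)


def test_psnr_invariant_under_shared_dihedral_transform():
    a, b = RNG.random((24, 24)), RNG.random((24, 24))
    base = psnr(unit(a), unit(b))
    for k in range(8):
        moved = psnr(unit(dihedral_transform(a, k)), unit(dihedral_transform(b, k)))
        assert moved == pytest.approx(base, abs=1e-10)


def test_psnr_decreases_with_noise_level():
    clean = unit(np.clip(RNG.random((64, 64)), 0.05, 0.95))
    means = []
    for sigma in (5.0, 15.0, 25.0, 50.0):
        vals = [
            psnr(clean, add_speckle(clean, SpeckleParams(sigma_8bit=sigma, seed=s)))
            for s in range(20)
        ]
        means.append(np.mean(vals))
    assert all(a > b for a, b in zip(means, means[1:]))


def test_psnr_shape_and_scale_mismatch_rejected():
    with pytest.raises(ValueError):
        psnr(unit(np.zeros((8, 8))), unit(np.zeros((8, 9))))
    with pytest.raises(ValueError):
        psnr(unit(np.zeros((8, 8))), GrayImage(np.zeros((8, 8)), Scale.EIGHT_BIT))


# ----------------------------------------------------------------------- SSIM


def ssim_oracle(x, y, vmax):
    """Direct windowed implementation: Gaussian 11x11, sigma 1.5, Wang-2004
    constants, population covariance, averaged over fully valid windows."""
    win = 11
    half = win // 2
    ax = np.arange(win) - half
    g = np.exp(-(ax**2) / (2 * 1.5**2))
    kernel = np.outer(g, g)
    kernel /= kernel.sum()
    c1, c2 = (0.01 * vmax) ** 2, (0.03 * vmax) ** 2
    h, w = x.shape
    values = []
    for i in range(half, h - half):
        for j in range(half, w - half):
            wx = x[i - half : i + half + 1, j - half : j + half + 1]
            wy = y[i - half : i + half + 1, j - half : j + half + 1]
            mx, my = np.sum(kernel * wx), np.sum(kernel * wy)
            vx = np.sum(kernel * (wx - mx) ** 2)
            vy = np.sum(kernel * (wy - my) ** 2)
            cxy = np.sum(kernel * (wx - mx) * (wy - my))
            values.append(
                ((2 * mx * my + c1) * (2 * cxy + c2))
                / ((mx**2 + my**2 + c1) * (vx + vy + c2))
            )
    return float(np.mean(values))


def test_ssim_matches_windowed_oracle_on_random_pairs():
    for _ in range(5):
        a, b = RNG.random((32, 32)), RNG.random((32, 32))
        assert ssim(unit(a), unit(b)) == pytest.approx(ssim_oracle(a, b, 1.0), abs=1e-6)


def test_ssim_of_identical_images_is_one():
    img = unit(RNG.random((16, 16)))
    assert ssim(img, img) == pytest.approx(1.0, abs=1e-12)


def test_ssim_luminance_term_penalizes_offset():
    a = unit(np.full((16, 16), 0.2))
    b = unit(np.full((16, 16), 0.8))
    assert ssim(a, b) < 0.5


def test_ssim_rejects_images_below_window():
    with pytest.raises(ValueError, match="11"):
        ssim(unit(np.zeros((8, 8))), unit(np.zeros((8, 8))))


# ---------------------------------------------------------------- aggregation


def test_aggregate_hand_values():
    agg = aggregate_runs([1.0, 2.0, 3.0])
    assert agg["mean"] == pytest.approx(2.0)
    assert agg["std"] == pytest.approx(1.0)  # n-1 denominator
    assert agg["n"] == 3
    flat = aggregate_runs([10.0, 10.0, 10.0])
    assert flat == {"mean": 10.0, "std": 0.0, "n": 3}


def test_aggregate_is_permutation_invariant():
    a = aggregate_runs([3.0, 1.0, 2.0])
    b = aggregate_runs([1.0, 2.0, 3.0])
    assert a == b


def test_aggregate_single_run_has_no_std():
    agg = aggregate_runs([5.0])
    assert agg["mean"] == 5.0 and agg["std"] is None and agg["n"] == 1


def test_aggregate_rejects_empty():
    with pytest.raises(ValueError):
        aggregate_runs([])


# ------------------------------------------------------------------- Friedman


def test_total_dominance_two_methods():
    scores = [[1.0, 2.0], [0.5, 0.9], [3.0, 3.1]]
    result = friedman_test(scores)
    assert result.mean_ranks == (1.0, 2.0)  # higher rank = better


def test_hand_computed_four_by_three_table():
    # per-image ranks (higher score = higher rank):
    #   (1,2,3), (1,3,2), (1,2,3), (2,1,3) -> mean ranks (1.25, 2.0, 2.75)
    scores = [
        [0.1, 0.5, 0.9],
        [0.2, 0.8, 0.6],
        [1.0, 2.0, 3.0],
        [0.4, 0.3, 0.7],
    ]
    n, k = 4, 3
    mean_ranks = (1.25, 2.0, 2.75)
    by_hand = 12 * n / (k * (k + 1)) * sum((r - (k + 1) / 2) ** 2 for r in mean_ranks)
    result = friedman_test(scores)
    assert result.mean_ranks == pytest.approx(mean_ranks)
    assert result.statistic == pytest.approx(by_hand, abs=1e-12)
    assert result.p_value == pytest.approx(stats.chi2.sf(by_hand, df=k - 1), abs=1e-12)


def test_mean_ranks_sum_to_rank_total():
    scores = RNG.random((10, 4))
    result = friedman_test(scores)
    assert sum(result.mean_ranks) == pytest.approx(4 * 5 / 2)


def test_statistic_invariant_under_monotone_transform():
    scores = RNG.random((8, 3))
    base = friedman_test(scores)
    cubed = friedman_test(scores**3)  # strictly monotone on positives
    assert cubed.statistic == pytest.approx(base.statistic, abs=1e-12)
    assert cubed.mean_ranks == pytest.approx(base.mean_ranks)


def test_all_tied_table_is_degenerate():
    result = friedman_test(np.ones((5, 3)))
    assert result.statistic == 0.0 and result.p_value == 1.0
    assert sum(result.mean_ranks) == pytest.approx(6.0)


def test_friedman_rejects_degenerate_shapes():
    with pytest.raises(ValueError):
        friedman_test([[1.0, 2.0]])
    with pytest.raises(ValueError):
        friedman_test([[1.0], [2.0]])


# ------------------------------------------------------------------ pipeline


def test_evaluate_pairs_lists():
    refs = [unit(RNG.random((16, 16))) for _ in range(3)]
    tests = [unit(np.clip(r.pixels + 0.05 * RNG.standard_normal((16, 16)), 0, 1)) for r in refs]
    metrics = evaluate_pairs(refs, tests)
    assert len(metrics["psnr"]) == 3 and len(metrics["ssim"]) == 3
    with pytest.raises(ValueError):
        evaluate_pairs(refs, tests[:2])
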