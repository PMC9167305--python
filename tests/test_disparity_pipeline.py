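"""Tests for WTA, LR-consistency refinement and the bad-pixel metric."""

import numpy as np
import pytest

import stereovol as sv
from stereovol.cost_volume import CostVolume
from stereovol.disparity_pipeline import (
    INVALID,
    MISMATCH,
    OCCLUSION,
    VALID,
    DisparityMap,
    OutlierLabels,
    error_rate,
    fill_outliers,
    lr_check,
    median_smooth,
    subpixel,
    wta,
)


def _vol(values, d_min=0):
    values = np.asarray(values, dtype=np.float64)
    return CostVolume(values=values, d_min=d_min, d_max=d_min + values.shape[2] - 1)


# ---------------------------------------------------------------------------
# WTA


def test_wta_unique_minimum_and_tie_break():
    vol = _vol(np.array([[[3.0, 1.0, 2.0]]]))
    assert wta(vol).values[0, 0] == 1
    vol = _vol(np.ones((2, 2, 4)), d_min=5)
    assert np.all(wta(vol).values == 5)  # ties break toward the smallest d


def test_wta_matches_argmin_loop(rng):
    values = rng.random((10, 10, 5))
    vol = _vol(values, d_min=2)
    disp = wta(vol).values
    for y in range(10):
        for x in range(10):
            assert disp[y, x] == 2 + int(np.argmin(values[y, x]))


# ---------------------------------------------------------------------------
# left-right consistency


def _warp_right_from_left(dl):
    """Exact right map: d_right(x - d, y) = d for each left pixel."""
    h, w = dl.shape
    dr = np.full((h, w), np.inf)
    for y in range(h):
        for x in range(w):
            t = x - int(dl[y, x])
            if t >= 0:
                dr[y, t] = dl[y, x]
    return dr


def test_lr_check_self_consistent_map_is_valid():
    dl = np.full((4, 12), 3.0)
    dr = _warp_right_from_left(dl)
    labels = lr_check(DisparityMap(dl), DisparityMap(dr, reference="right"), 0, 6)
    assert np.all(labels.labels[:, 3:] == VALID)


def test_lr_check_flags_large_disagreement():
    dl = np.full((1, 20), 10.0)
    dr = np.full((1, 20), 5.0)
    labels = lr_check(DisparityMap(dl), DisparityMap(dr, reference="right"), 0, 12)
    assert np.all(labels.labels[:, 10:] != VALID)
    # every pixel can still find a consistent candidate (d' in 4..6) -> mismatch
    assert np.all(labels.labels[:, 10:] == MISMATCH)


def test_lr_check_reference_and_integer_validation():
    dl = DisparityMap(np.zeros((2, 2)))
    with pytest.raises(ValueError):
        lr_check(dl, dl, 0, 3)
    frac = DisparityMap(np.full((2, 2), 0.5), reference="right")
    with pytest.raises(ValueError):
        lr_check(DisparityMap(np.full((2, 2), 0.5)), frac, 0, 3)


def test_lr_check_occlusion_labels_match_scene_mask():
    """Detected occlusions cover >= 90% of the fixture's occlusion band.

    The band must be wide compared to the ~1-px zone at its edges where
    foreground fattening makes the two views agree on a wrong disparity
    (those pixels pass the +-1 LR test and are unreachable by any
    consistency-based detector).
    """
    scene = sv.generate_disparity_scene(
        160, 120, [sv.SceneShape(kind="rect", offset=16, x0=70, y0=30, width=50, height=60)],
        base_disparity=4, seed=1,
    )
    left, right = sv.render_stereo_pair(scene, seed=1)
    res = sv.match_pair(left, right, sv.CostParams(d_min=0, d_max=24))
    band = scene.occlusion_mask
    hit = (res.labels.labels == OCCLUSION) & band
    assert hit.sum() / band.sum() >= 0.9


# ---------------------------------------------------------------------------
# filling


def test_fill_occlusion_takes_smallest_candidate():
    dl = np.full((5, 5), 9.0)
    dl[2, 0] = 4.0  # leftward candidate of the hole
    labels = np.full((5, 5), VALID, dtype=np.uint8)
    labels[2, 2] = OCCLUSION
    img = np.zeros((5, 5, 3), dtype=np.uint8)
    out = fill_outliers(DisparityMap(dl), OutlierLabels(labels), img)
    # nearest valid to the left is (2,1) with d=9; (2,0)=4 is hidden behind it
    assert out.values[2, 2] == 9.0
    labels[2, 1] = OCCLUSION  # now (2,0) with d=4 is the leftward candidate
    out = fill_outliers(DisparityMap(dl), OutlierLabels(labels), img)
    assert out.values[2, 2] == 4.0


def test_fill_mismatch_takes_closest_color():
    dl = np.full((3, 5), 5.0)
    dl[1, 0] = 7.0
    img = np.zeros((3, 5, 3), dtype=np.uint8)
    img[1, 2] = (100, 100, 100)
    img[1, 0] = (98, 100, 100)  # color-closest candidate carries d = 7
    labels = np.full((3, 5), VALID, dtype=np.uint8)
    labels[1, 1] = MISMATCH
    labels[1, 2] = MISMATCH
    out = fill_outliers(DisparityMap(dl), OutlierLabels(labels), img)
    assert out.values[1, 2] == 7.0


def test_fill_valid_map_unchanged(rng):
    dl = rng.integers(0, 9, size=(6, 6)).astype(np.float64)
    labels = OutlierLabels(np.full((6, 6), VALID, dtype=np.uint8))
    out = fill_outliers(DisparityMap(dl), labels, np.zeros((6, 6, 3), np.uint8))
    np.testing.assert_array_equal(out.values, dl)


def test_fill_never_invents_disparities(rng):
    dl = rng.integers(0, 9, size=(8, 8)).astype(np.float64)
    labels = (rng.random((8, 8)) < 0.4).astype(np.uint8)  # mix valid/occlusion
    valid_values = set(dl[labels == VALID].tolist())
    out = fill_outliers(
        DisparityMap(dl), OutlierLabels(labels), np.zeros((8, 8, 3), np.uint8)
    )
    filled = out.values[labels != VALID]
    assert set(filled[np.isfinite(filled)].tolist()) <= valid_values


# ---------------------------------------------------------------------------
# subpixel


def test_subpixel_symmetric_costs_keep_integer():
    values = np.zeros((1, 1, 3))
    values[0, 0] = [2.0, 0.0, 2.0]
    out = subpixel(DisparityMap(np.array([[1.0]])), _vol(values))
    assert out.values[0, 0] == 1.0


def test_subpixel_worked_example():
    values = np.zeros((1, 1, 3))
    values[0, 0] = [2.0, 0.0, 1.0]
    out = subpixel(DisparityMap(np.array([[1.0]])), _vol(values))
    assert out.values[0, 0] == pytest.approx(1 + 1 / 6, abs=1e-12)


@pytest.mark.parametrize("vertex", [0.0, 0.3, -0.3, 0.49, -0.49])
def test_subpixel_recovers_parabola_vertex(vertex):
    d_star = 3 + vertex
    ds = np.arange(7, dtype=np.float64)
    costs = 0.7 * (ds - d_star) ** 2 + 0.2
    values = np.tile(costs, (2, 2, 1))
    disp = DisparityMap(np.full((2, 2), 3.0))
    out = subpixel(disp, _vol(values))
    np.testing.assert_allclose(out.values, d_star, atol=1e-9)


def test_subpixel_shift_bounded_by_half(rng):
    values = rng.random((10, 10, 6))
    vol = _vol(values)
    disp = wta(vol)
    out = subpixel(disp, vol)
    shift = out.values - disp.values
    assert np.abs(shift).max() <= 0.5 + 1e-12


def test_subpixel_keeps_boundary_disparities():
    values = np.zeros((1, 2, 3))
    values[0, 0] = [0.0, 1.0, 2.0]  # minimum at d_min
    values[0, 1] = [2.0, 1.0, 0.0]  # minimum at d_max
    disp = DisparityMap(np.array([[0.0, 2.0]]))
    out = subpixel(disp, _vol(values))
    np.testing.assert_array_equal(out.values, [[0.0, 2.0]])


# ---------------------------------------------------------------------------
# median


def test_median_constant_and_spike():
    d = np.full((7, 7), 4.0)
    out = median_smooth(DisparityMap(d), 3)
    np.testing.assert_array_equal(out.values, d)
    d[3, 3] = 99.0
    out = median_smooth(DisparityMap(d), 3)
    assert out.values[3, 3] == 4.0


def test_median_matches_window_sort_oracle(rng):
    d = rng.random((9, 8)) * 10
    d[rng.random((9, 8)) < 0.2] = INVALID
    out = median_smooth(DisparityMap(d.copy()), 3)
    for y in range(9):
        for x in range(8):
            vals = [
                d[r, c]
                for r in range(max(y - 1, 0), min(y + 2, 9))
                for c in range(max(x - 1, 0), min(x + 2, 8))
                if np.isfinite(d[r, c])
            ]
            if vals:
                assert out.values[y, x] == pytest.approx(np.median(vals))
            else:
                assert not np.isfinite(out.values[y, x])


def test_median_rejects_even_kernel():
    with pytest.raises(ValueError):
        median_smooth(DisparityMap(np.zeros((4, 4))), 4)


# ---------------------------------------------------------------------------
# error rate


def test_error_rate_examples():
    gt = np.array([[0.0, 5.0, 10.0]])
    est = DisparityMap(np.array([[0.0, 7.0, 10.5]]))
    assert error_rate(est, gt) == pytest.approx(1 / 3)
    assert error_rate(DisparityMap(gt.copy()), gt) == 0.0
    assert error_rate(DisparityMap(gt + 1.0), gt) == 0.0  # |1| is not > 1
    invalid = DisparityMap(np.full((1, 3), INVALID))
    assert error_rate(invalid, gt) == 1.0


def test_error_rate_occlusion_exclusion():
    gt = np.array([[3.0, 3.0, 3.0, 3.0]])
    occ = np.array([[True, False, False, False]])
    est = DisparityMap(np.array([[9.0, 3.0, 3.0, 3.0]]))
    assert error_rate(est, gt, occ, exclude_occluded=True) == 0.0
    assert error_rate(est, gt) == pytest.approx(1 / 4)
    with pytest.raises(ValueError):
        error_rate(est, gt, None, exclude_occluded=True)


# ---------------------------------------------------------------------------
# end-to-end refinement properties


@pytest.mark.parametrize("seed", range(5))
def test_refinement_does_not_increase_error(seed):
    scene = sv.generate_disparity_scene(
        64, 48, [sv.SceneShape(kind="rect", offset=4, x0=24, y0=12, width=14, height=14)],
        base_disparity=5, seed=seed,
    )
    left, right = sv.render_stereo_pair(scene, seed=seed)
    res = sv.match_pair(left, right, sv.CostParams(d_min=0, d_max=12))
    r_refined = error_rate(res.disparity, scene.disparity_gt)
    r_raw = error_rate(res.raw_disparity, scene.disparity_gt)
    assert r_refined <= r_raw


def test_pipeline_determinism():
    scene = sv.generate_disparity_scene(
        48, 32, [sv.SceneShape(kind="disk", offset=3, cx=24, cy=16, radius=8)],
        base_disparity=4, seed=2,
    )
    left, right = sv.render_stereo_pair(scene, seed=2)
    a = sv.match_pair(left, right, sv.CostParams(d_min=0, d_max=9))
    b = sv.match_pair(left, right, sv.CostParams(d_min=0, d_max=9))
    np.testing.assert_array_equal(a.disparity.values, b.disparity.values)
    np.testing.assert_array_equal(a.labels.labels, b.labels.labels)
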