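"""Unit and property tests for the intensity-based coefficients."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rwcoloc import (
    dense_rank_transform,
    full_report,
    manders_m1_m2,
    overlap_coefficient_r,
    overlap_k1_k2,
    pearson_correlation,
    rank_weight_map,
    rwc_coefficients,
)
from conftest import random_pair


def naive_rwc(a, b, thr_a, thr_b, k=0.0):
    """Per-pixel loop reference implementation of RWC1/RWC2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)

    def ranks(img):
        levels = sorted(set(img.ravel().tolist()), reverse=True)
        lookup = {v: i + 1 for i, v in enumerate(levels)}
        return {(r, c): lookup[img[r, c]] for r in range(img.shape[0])
                for c in range(img.shape[1])}, len(levels)

    ra, na = ranks(a)
    rb, nb = ranks(b)
    rn = max(na, nb) * (1.0 + k)
    num1 = den1 = num2 = den2 = 0.0
    for pos in ra:
        av, bv = a[pos], b[pos]
        w = (rn - abs(ra[pos] - rb[pos])) / rn
        if av > thr_a:
            den1 += av
            if bv > thr_b:
                num1 += av * w
        if bv > thr_b:
            den2 += bv
            if av > thr_a:
                num2 += bv * w
    return (num1 / den1 if den1 else 0.0, num2 / den2 if den2 else 0.0)


class TestDenseRank:
    def test_descending_dense_ranks_with_ties(self):
        rm = dense_rank_transform(np.array([[255, 128], [128, 0]], dtype=np.uint8))
        assert rm.n_ranks == 3
        assert rm.ranks.tolist() == [[1, 2], [2, 3]]

    def test_constant_image_is_single_rank(self):
        rm = dense_rank_transform(np.full((2, 2), 7, dtype=np.uint8))
        assert rm.n_ranks == 1
        assert (rm.ranks == 1).all()

    def test_grid_channel_has_sixteen_ranks_brightest_first(self, grid_pairs):
        a, _ = grid_pairs[0]
        rm = dense_rank_transform(a)
        assert rm.n_ranks == 16
        assert rm.ranks[a.pixels == 240].tolist() == [1] * (128 * 128)

    def test_mask_restricts_grey_level_count(self):
        img = np.array([[10, 20], [30, 40]], dtype=np.uint8)
        mask = np.array([[True, True], [False, False]])
        rm = dense_rank_transform(img, mask)
        assert rm.n_ranks == 2
        assert rm.ranks.tolist() == [[2, 1], [0, 0]]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            dense_rank_transform(np.ones((2, 2), dtype=np.uint8), np.zeros((2, 2), bool))

    def test_monotone_intensity_remap_preserves_ranks(self, rng):
        img = rng.integers(0, 100, (6, 6)).astype(np.uint8)
        remapped = (img.astype(np.int64) * 2 + 11)  # strictly increasing remap
        r1 = dense_rank_transform(img)
        r2 = dense_rank_transform(remapped)
        assert np.array_equal(r1.ranks, r2.ranks)
        assert r1.n_ranks == r2.n_ranks


class TestWeights:
    def test_equal_ranks_give_unit_weight(self, rng):
        img = rng.integers(0, 50, (5, 5)).astype(np.uint8)
        for k in (0.0, 0.3, 1.0):
            wm = rank_weight_map(dense_rank_transform(img), dense_rank_transform(img), k)
            assert (wm.weights == 1.0).all()

    def test_weight_formula_values(self):
        # two channels with 16 ranks each; one pixel with ranks 14 and 3
        a = np.arange(16, dtype=np.uint8).reshape(4, 4) * 15 + 15
        b = a[::-1, ::-1]
        wm = rank_weight_map(dense_rank_transform(a), dense_rank_transform(b))
        assert wm.rn == 16
        ra = dense_rank_transform(a).ranks
        rb = dense_rank_transform(b).ranks
        pos = np.argwhere((ra == 14) & (rb == 3))[0]
        assert wm.weights[tuple(pos)] == pytest.approx(5 / 16)  # (16-11)/16

    def test_extreme_rank_difference_weight(self):
        # D = Rn-1 gives weight 1/Rn at k=0 and (Rn+1)/(2Rn) at k=1
        a = np.array([[10, 20, 30, 40]], dtype=np.uint8)
        b = np.array([[40, 30, 20, 10]], dtype=np.uint8)
        wm0 = rank_weight_map(dense_rank_transform(a), dense_rank_transform(b), 0.0)
        wm1 = rank_weight_map(dense_rank_transform(a), dense_rank_transform(b), 1.0)
        rn = wm0.rn
        assert wm0.weights.min() == pytest.approx(1 / rn)
        assert wm1.weights.min() == pytest.approx((rn + 1) / (2 * rn))

    def test_weights_nondecreasing_in_k(self, rng):
        a, b = random_pair(rng)
        ra, rbm = dense_rank_transform(a), dense_rank_transform(b)
        prev = rank_weight_map(ra, rbm, 0.0).weights
        for k in (0.25, 0.5, 0.75, 1.0):
            cur = rank_weight_map(ra, rbm, k).weights
            assert (cur >= prev - 1e-15).all()
            prev = cur


class TestRWC:
    def test_identical_images_fully_colocalized(self, rng):
        img = rng.integers(1, 200, (6, 6)).astype(np.uint8)
        assert rwc_coefficients(img, img) == (1.0, 1.0)

    def test_grid_vs_180_rotation_threshold_15pct(self, grid_pairs):
        a, b = grid_pairs[2]
        r1, r2 = rwc_coefficients(a, b, (36, 36))
        assert round(r1, 2) == 0.48
        assert round(r2, 2) == 0.48

    def test_grid_vs_180_rotation_no_threshold(self, grid_pairs):
        a, b = grid_pairs[2]
        r1, r2 = rwc_coefficients(a, b)
        # closed form: sum over segments k of 15k*(16-|17-2k|)/16 / sum 15k
        expected = sum(k * (16 - abs(17 - 2 * k)) / 16 for k in range(1, 17)) / 136
        assert r1 == pytest.approx(expected)
        assert r1 == pytest.approx(0.5)
        assert r2 == pytest.approx(r1)

    def test_two_pixel_swap(self):
        r1, r2 = rwc_coefficients(np.array([[100, 200]]), np.array([[200, 100]]))
        assert (r1, r2) == (0.5, 0.5)

    def test_matches_naive_loop_oracle(self, rng):
        for _ in range(25):
            a, b = random_pair(rng)
            thr_a = int(rng.integers(0, 100))
            thr_b = int(rng.integers(0, 100))
            k = float(rng.uniform(0, 1))
            got = rwc_coefficients(a, b, (thr_a, thr_b), k)
            want = naive_rwc(a, b, thr_a, thr_b, k)
            assert got[0] == pytest.approx(want[0], abs=1e-12)
            assert got[1] == pytest.approx(want[1], abs=1e-12)

    def test_dominated_by_manders(self, rng):
        for _ in range(10):
            a, b = random_pair(rng)
            thr = (int(rng.integers(0, 80)), int(rng.integers(0, 80)))
            r1, r2 = rwc_coefficients(a, b, thr)
            m1, m2 = manders_m1_m2(a, b, thr)
            assert r1 <= m1 + 1e-12 and r2 <= m2 + 1e-12
            assert 0.0 <= r1 <= 1.0 and 0.0 <= r2 <= 1.0

    def test_equals_manders_when_ranks_agree(self, rng):
        # identical rank structure (monotone remap of one channel): D=0 everywhere
        a = rng.integers(1, 120, (6, 6)).astype(np.uint8)
        b = (a.astype(np.int64) + 30).astype(np.uint8)
        thr = (0, 0)
        assert rwc_coefficients(a, b, thr) == manders_m1_m2(a, b, thr)

    def test_channel_swap_symmetry(self, rng):
        a, b = random_pair(rng)
        r1, r2 = rwc_coefficients(a, b, (20, 40))
        s1, s2 = rwc_coefficients(b, a, (40, 20))
        assert (r1, r2) == (s2, s1)

    def test_rwc_nondecreasing_in_k_sens(self, rng):
        a, b = random_pair(rng)
        vals = [rwc_coefficients(a, b, (10, 10), k)[0] for k in (0, 0.25, 0.5, 1.0)]
        assert all(v2 >= v1 - 1e-12 for v1, v2 in zip(vals, vals[1:]))

    def test_zero_denominator_reports_zero(self):
        a = np.zeros((3, 3), dtype=np.uint8)
        b = np.ones((3, 3), dtype=np.uint8)
        # channel A has no above-threshold signal: RWC1 denominator is 0;
        # nothing co-occurs, so RWC2 is 0 as well
        assert rwc_coefficients(a, b, (0, 0)) == (0.0, 0.0)


class TestClassicalCoefficients:
    def test_pearson_identical(self, rng):
        img = rng.integers(0, 200, (5, 5)).astype(np.uint8)
        assert pearson_correlation(img, img) == pytest.approx(1.0)

    def test_pearson_grid_vs_complement_is_minus_one(self, grid_pairs):
        a, b = grid_pairs[2]  # B = 255 - A exactly
        assert pearson_correlation(a, b) == pytest.approx(-1.0)

    def test_pearson_constant_channel_is_flagged_nan(self):
        a = np.full((3, 3), 5, dtype=np.uint8)
        b = np.arange(9, dtype=np.uint8).reshape(3, 3)
        assert math.isnan(pearson_correlation(a, b))

    @pytest.mark.parametrize(
        "a,b,expected",
        [([3, 4], [4, 3], 24 / 25), ([1, 0], [0, 1], 0.0), ([5, 9], [5, 9], 1.0)],
    )
    def test_overlap_r_values(self, a, b, expected):
        r = overlap_coefficient_r(np.array([a], dtype=np.uint8), np.array([b], dtype=np.uint8))
        assert r == pytest.approx(expected)

    @pytest.mark.parametrize(
        "a,b,expected",
        [([2], [4], (2.0, 0.5)), ([3, 4], [4, 3], (0.96, 0.96)), ([7, 7], [7, 7], (1.0, 1.0))],
    )
    def test_k1_k2_values(self, a, b, expected):
        k1, k2 = overlap_k1_k2(np.array([a], dtype=np.uint8), np.array([b], dtype=np.uint8))
        assert (k1, k2) == pytest.approx(expected)

    def test_manders_no_threshold_is_one_for_positive_pair(self, rng):
        a = rng.integers(1, 200, (5, 5)).astype(np.uint8)
        b = rng.integers(1, 200, (5, 5)).astype(np.uint8)
        assert manders_m1_m2(a, b) == (1.0, 1.0)

    def test_manders_grid_vs_90_rotation(self, grid_pairs):
        a, b = grid_pairs[1]
        m1, m2 = manders_m1_m2(a, b, (36, 36))
        assert round(m1, 4) == 0.9098
        assert round(m2, 4) == 0.8346

    def test_manders_disjoint_supports(self):
        a = np.array([[10, 0]], dtype=np.uint8)
        b = np.array([[0, 10]], dtype=np.uint8)
        assert manders_m1_m2(a, b) == (0.0, 0.0)


class TestFullReport:
    def test_identical_positive_images_all_ones(self, rng):
        img = rng.integers(1, 200, (6, 6)).astype(np.uint8)
        rep = full_report(img, img)
        for name in ("pc", "r", "k1", "k2", "m1", "m2", "rwc1", "rwc2"):
            assert getattr(rep, name) == pytest.approx(1.0), name

    def test_identical_grid_pair_thresholded(self, grid_pairs):
        a, b = grid_pairs[0]
        rep = full_report(a, b, (36, 36))
        assert (rep.m1, rep.m2, rep.rwc1, rep.rwc2) == (1.0, 1.0, 1.0, 1.0)

    def test_anticorrelated_grid_pair(self, grid_pairs):
        a, b = grid_pairs[2]
        rep = full_report(a, b, (36, 36))
        assert round(rep.rwc1, 2) == 0.48
        assert rep.pc == pytest.approx(-1.0)

    def test_undefined_values_do_not_abort_others(self):
        a = np.full((3, 3), 9, dtype=np.uint8)  # constant: pc undefined
        b = np.arange(1, 10, dtype=np.uint8).reshape(3, 3)
        rep = full_report(a, b)
        assert math.isnan(rep.pc)
        assert rep.m1 == 1.0


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 255), st.integers(0, 255)), min_size=4, max_size=36
    ),
    k=st.floats(0, 1),
)
def test_rwc_bounds_and_domination_property(data, k):
    """RWC1/RWC2 stay in [0,1] and never exceed the Manders values."""
    n = len(data)
    w = int(math.sqrt(n))
    data = data[: w * w]
    a = np.array([p[0] for p in data], dtype=np.uint8).reshape(w, -1)
    b = np.array([p[1] for p in data], dtype=np.uint8).reshape(w, -1)
    r1, r2 = rwc_coefficients(a, b, (0, 0), k)
    m1, m2 = manders_m1_m2(a, b, (0, 0))
    assert 0.0 <= r1 <= 1.0 and 0.0 <= r2 <= 1.0
    assert r1 <= m1 + 1e-12 and r2 <= m2 + 1e-12
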