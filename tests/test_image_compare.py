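import numpy as np
import pytest

from flexcompare.core import (
    SimilarityTransform,
    SusceptibilityImage,
    ValidationError,
)
from flexcompare.image_compare import (
    compare_pair,
    fit_similarity,
    gap_measure,
    image_distance,
    interpolate_gaps,
    refine_by_maximum_similarity,
    register_onto,
    resize_image,
    warp_image,
)


def sweep_oracle(chi, mask):
    """Independent gap-fill oracle: literal sweep-by-sweep hand simulation
    with explicit neighbor loops (values frozen at sweep start)."""
    chi = chi.copy()
    mask = mask.copy()
    m = chi.shape[0]
    while mask.any():
        snapshot = chi.copy()
        snap_mask = mask.copy()
        for j in range(m):
            for k in range(m):
                if not snap_mask[j, k]:
                    continue
                vals = []
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        if dj == dk == 0:
                            continue
                        nj, nk = j + dj, k + dk
                        if 0 <= nj < m and 0 <= nk < m and not snap_mask[nj, nk]:
                            vals.append(snapshot[nj, nk])
                if vals:
                    chi[j, k] = sum(vals) / len(vals)
                    mask[j, k] = False
    return chi


class TestInterpolateGaps:
    def test_center_gap_constant_neighbors(self):
        chi = np.full((3, 3), 0.4)
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        out = interpolate_gaps(SusceptibilityImage("p", np.where(mask, 0, chi), mask))
        assert out.chi[1, 1] == pytest.approx(0.4)
        # original gap recorded for the gap measure
        assert out.gap_mask[1, 1]

    def test_mean_rule(self):
        chi = np.zeros((3, 3))
        chi[0] = [0, 0, 0]
        chi[1] = [0, 0, 1]
        chi[2] = [1, 1, 1]
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        out = interpolate_gaps(SusceptibilityImage("p", chi, mask))
        assert out.chi[1, 1] == pytest.approx(0.5)

    def test_block_fill_matches_sweep_oracle(self, rng):
        chi = rng.random((5, 5))
        chi = np.clip(0.5 * (chi + chi.T), 0, 1)
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        chi = np.where(mask, 0.0, chi)
        out = interpolate_gaps(SusceptibilityImage("p", chi, mask))
        assert np.allclose(out.chi, sweep_oracle(chi, mask), atol=1e-12)

    def test_nongap_pixels_untouched(self, rng):
        chi = np.clip(rng.random((6, 6)), 0, 1)
        chi = 0.5 * (chi + chi.T)
        mask = np.zeros((6, 6), bool)
        mask[2, 3] = mask[3, 2] = True
        out = interpolate_gaps(SusceptibilityImage("p", np.where(mask, 0, chi), mask))
        assert np.allclose(out.chi[~mask], chi[~mask])

    def test_all_gap_rejected(self):
        mask = np.ones((3, 3), bool)
        with pytest.raises(ValidationError, match="all pixels"):
            interpolate_gaps(SusceptibilityImage("p", np.zeros((3, 3)), mask))

    def test_no_gaps_is_copy(self, smooth_image):
        out = interpolate_gaps(smooth_image)
        assert np.array_equal(out.chi, smooth_image.chi)
        assert out.chi is not smooth_image.chi


class TestResize:
    def test_same_size_identity(self, smooth_image):
        out = resize_image(smooth_image, smooth_image.m)
        assert np.allclose(out.chi, smooth_image.chi, atol=1e-9)

    def test_constant_preserved(self):
        img = SusceptibilityImage("c", np.full((5, 5), 0.7))
        out = resize_image(img, 11)
        assert np.allclose(out.chi, 0.7, atol=1e-12)

    def test_linear_ramp_reproduced_in_interior(self):
        # cubic-convolution bicubic reproduces linear functions exactly
        # wherever the 4-tap stencil stays inside the image
        ramp = np.add.outer(np.arange(4), np.arange(4)) / 6.0
        out = resize_image(SusceptibilityImage("r", ramp), 8)
        src = (np.arange(8) + 0.5) * 0.5 - 0.5
        expected = np.add.outer(src, src) / 6.0
        interior = slice(3, 5)  # stencil fully interior for 4 -> 8
        assert np.allclose(
            out.chi[interior, interior], expected[interior, interior], atol=1e-6
        )

    def test_linear_ramp_larger(self):
        n, t = 12, 24
        ramp = np.add.outer(np.arange(n), np.arange(n)) / (2.0 * (n - 1))
        out = resize_image(SusceptibilityImage("r", ramp), t)
        src = (np.arange(t) + 0.5) * (n / t) - 0.5
        expected = np.add.outer(src, src) / (2.0 * (n - 1))
        assert np.allclose(out.chi[4:-4, 4:-4], expected[4:-4, 4:-4], atol=1e-6)

    def test_target_too_small(self, smooth_image):
        with pytest.raises(ValidationError, match=">= 2"):
            resize_image(smooth_image, 1)

    def test_values_clamped(self, rng):
        chi = np.zeros((6, 6))
        chi[2:4, 2:4] = 1.0  # sharp edge makes bicubic overshoot
        out = resize_image(SusceptibilityImage("p", chi), 13)
        assert out.chi.min() >= 0.0 and out.chi.max() <= 1.0

    def test_gap_mask_nearest(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True
        img = SusceptibilityImage("p", np.zeros((4, 4)), mask)
        filled = interpolate_gaps(img)
        out = resize_image(filled, 8)
        assert out.gap_mask[0, 0]
        assert out.gap_mask.sum() == 4  # the corner source pixel covers 2x2


class TestFitSimilarity:
    def test_identity_pairs(self):
        pts = [((1.0, 1.0), (1.0, 1.0)), ((9.0, 4.0), (9.0, 4.0))]
        tf = fit_similarity(pts)
        assert tf.scale == pytest.approx(1.0)
        assert tf.rotation == pytest.approx(0.0)
        assert tf.translation == pytest.approx((0.0, 0.0))

    def test_pure_translation(self):
        pts = [((0.0, 0.0), (3.0, -2.0)), ((5.0, 5.0), (8.0, 3.0))]
        tf = fit_similarity(pts)
        assert tf.scale == pytest.approx(1.0)
        assert tf.translation == pytest.approx((3.0, -2.0))

    def test_rotation_and_scale_recovery(self):
        true = SimilarityTransform(2.0, np.pi / 2, (0.0, 0.0))
        src = np.array([[1.0, 2.0], [4.0, 1.0], [2.0, 5.0]])
        pts = [(tuple(p), tuple(q)) for p, q in zip(src, true.apply(src))]
        tf = fit_similarity(pts)
        assert tf.scale == pytest.approx(2.0, abs=1e-9)
        assert tf.rotation == pytest.approx(np.pi / 2, abs=1e-9)
        assert np.allclose(tf.translation, (0.0, 0.0), atol=1e-9)

    def test_exact_with_two_points(self, rng):
        true = SimilarityTransform(1.3, 0.4, (2.0, -1.0))
        src = rng.random((2, 2)) * 10
        pts = [(tuple(p), tuple(q)) for p, q in zip(src, true.apply(src))]
        tf = fit_similarity(pts)
        assert np.allclose(tf.apply(src), true.apply(src), atol=1e-9)

    def test_coincident_moving_points_degenerate(self):
        pts = [((1.0, 1.0), (0.0, 0.0)), ((1.0, 1.0), (5.0, 5.0))]
        with pytest.raises(ValidationError, match="degenerate"):
            fit_similarity(pts)

    def test_too_few_points(self):
        with pytest.raises(ValidationError, match="at least 2"):
            fit_similarity([((0.0, 0.0), (0.0, 0.0))])


class TestImageDistance:
    def test_identical_images(self, smooth_image):
        assert image_distance(smooth_image, smooth_image) == 0.0

    def test_forced_2x2_case(self):
        a = SusceptibilityImage("a", np.array([[0.0, 1.0], [1.0, 0.0]]))
        b = SusceptibilityImage("b", np.ones((2, 2)))
        assert image_distance(a, b) == pytest.approx(0.5)

    def test_mutual_gap_case(self):
        # squared diffs {0.04, 0.09, 0.16} on defined pixels -> 0.29/4
        mask = np.array([[True, False], [False, False]])
        a = SusceptibilityImage(
            "a", np.array([[0.0, 0.2], [0.3, 0.4]]), mask
        )
        b = SusceptibilityImage(
            "b", np.array([[0.0, 0.4], [0.6, 0.8]]), mask
        )
        assert image_distance(a, b) == pytest.approx(0.0725)

    def test_symmetric_in_arguments(self, smooth_image, rng):
        other = SusceptibilityImage(
            "o", np.clip(smooth_image.chi + 0.05 * rng.random(smooth_image.chi.shape), 0, 1)
        )
        assert image_distance(smooth_image, other) == pytest.approx(
            image_distance(other, smooth_image)
        )

    def test_dimension_mismatch(self, smooth_image):
        small = SusceptibilityImage("s", np.zeros((3, 3)))
        with pytest.raises(ValidationError, match="mismatch"):
            image_distance(smooth_image, small)


class TestGapMeasure:
    def test_gap_free(self, smooth_image):
        assert gap_measure(smooth_image, smooth_image) == 0.0

    def test_union_count(self):
        m = 10
        a_mask = np.zeros((m, m), bool)
        b_mask = np.zeros((m, m), bool)
        a_mask[0, :5] = True  # 5 pixels
        b_mask[0, 3:7] = True  # overlap of 2, union = 7
        a = SusceptibilityImage("a", np.zeros((m, m)), a_mask)
        b = SusceptibilityImage("b", np.zeros((m, m)), b_mask)
        assert gap_measure(a, b) == pytest.approx(0.07)

    def test_all_gap_base(self):
        a = SusceptibilityImage("a", np.zeros((4, 4)), np.ones((4, 4), bool))
        b = SusceptibilityImage("b", np.zeros((4, 4)))
        assert gap_measure(a, b) == 1.0

    def test_monotone_in_union(self, rng):
        m = 8
        mask1 = rng.random((m, m)) < 0.1
        mask2 = mask1 | (rng.random((m, m)) < 0.1)
        z = np.zeros((m, m))
        g1 = gap_measure(
            SusceptibilityImage("a", z, mask1), SusceptibilityImage("b", z)
        )
        g2 = gap_measure(
            SusceptibilityImage("a", z, mask2), SusceptibilityImage("b", z)
        )
        assert g2 >= g1


class TestWarp:
    def test_identity_warp_exact(self, smooth_image):
        out = warp_image(smooth_image, SimilarityTransform())
        assert np.allclose(out.chi, smooth_image.chi, atol=1e-9)
        assert not out.gap_mask.any()

    def test_translation_creates_edge_gaps(self, smooth_image):
        tf = SimilarityTransform(translation=(3.0, 0.0))
        out = warp_image(smooth_image, tf)
        # base pixels x<3 sample moving pixels x<0: undefined
        assert out.gap_mask[:, :2].all()
        assert not out.gap_mask[:, 5:].any()


class TestRefine:
    def test_perfect_init_kept(self, smooth_image):
        tf = refine_by_maximum_similarity(
            smooth_image, smooth_image, SimilarityTransform(), max_evals=60
        )
        d = image_distance(smooth_image, warp_image(smooth_image, tf))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_shift(self, smooth_image):
        m = smooth_image.m
        shifted = np.empty_like(smooth_image.chi)
        shifted[:, 2:] = smooth_image.chi[:, :-2]
        shifted[:, :2] = smooth_image.chi[:, :1]
        moving = SusceptibilityImage("m", shifted)
        init = SimilarityTransform()
        d0 = image_distance(smooth_image, warp_image(moving, init))
        tf = refine_by_maximum_similarity(moving, smooth_image, init)
        d1 = image_distance(smooth_image, warp_image(moving, tf))
        assert abs(tf.translation[0] - (-2.0)) < 0.5
        assert abs(tf.translation[1]) < 0.5
        assert d1 < d0

    def test_never_worse_than_init(self, smooth_image, rng):
        other = SusceptibilityImage(
            "o",
            np.clip(
                smooth_image.chi + 0.1 * rng.random(smooth_image.chi.shape), 0, 1
            ),
        )
        for _ in range(3):
            init = SimilarityTransform(
                1.0 + 0.1 * (rng.random() - 0.5),
                0.05 * (rng.random() - 0.5),
                (2 * rng.random() - 1, 2 * rng.random() - 1),
            )
            d0 = image_distance(smooth_image, warp_image(other, init))
            tf = refine_by_maximum_similarity(
                other, smooth_image, init, max_evals=80
            )
            d1 = image_distance(smooth_image, warp_image(other, tf))
            assert d1 <= d0 + 1e-15


class TestComparePair:
    def test_identical_images_zero(self, smooth_image):
        other = SusceptibilityImage("other", smooth_image.chi.copy())
        rec = compare_pair(smooth_image, other, refine=False)
        assert rec.euclidean == pytest.approx(0.0, abs=1e-12)
        assert rec.gap_measure == 0.0

    def test_swap_invariance(self, smooth_image, rng):
        other = SusceptibilityImage(
            "other",
            np.clip(
                smooth_image.chi + 0.03 * rng.random(smooth_image.chi.shape), 0, 1
            ),
        )
        rec1 = compare_pair(smooth_image, other, refine=False)
        rec2 = compare_pair(other, smooth_image, refine=False)
        assert rec1.euclidean == rec2.euclidean
        assert rec1.gap_measure == rec2.gap_measure
        assert rec1.pair_label == rec2.pair_label

    def test_register_onto_reports_diagnostics(self, smooth_image):
        res = register_onto(smooth_image, smooth_image, refine=False)
        assert res.euclidean == pytest.approx(0.0, abs=1e-12)
        assert res.initial_euclidean == pytest.approx(res.euclidean, abs=1e-12)
        assert res.transform.scale == pytest.approx(1.0)
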