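"""Porosity imaging: rendering, thresholding, contour and area measures."""
import numpy as np
import pytest

from canopyflow.porosity import (EmptyLayerError, ProjectionImage,
                                 outer_contour_area, porosity_from_mask,
                                 preprocess, render_projection, windward_area)


def square_mesh(side=100.0):
    v = np.array([[0, 0, 0], [side, 0, 0], [side, side, 0], [0, side, 0]],
                 float)
    f = np.array([[0, 1, 2], [0, 2, 3]])
    return v, f


class TestRender:
    def test_axis_aligned_square_block(self):
        img = render_projection([square_mesh()], "top",
                                bounds=((0, 0), (100, 100)), resolution=100)
        assert img.mm_per_pixel == 1.0
        assert (img.pixels == 0).sum() == 100 * 100

    def test_resolution_invariance(self):
        from canopyflow.plant import make_leaf_template
        m = make_leaf_template("three_lobed", 7859.10).to_mesh()
        a = []
        for res in (256, 512):
            img = render_projection([m], "top", resolution=res)
            a.append(windward_area(img.pixels == 0, img.mm_per_pixel))
        assert abs(a[1] - a[0]) / a[0] < 0.005

    def test_disjoint_additivity(self):
        v1, f1 = square_mesh(40.0)
        v2 = v1 + np.array([60.0, 0, 0])
        bounds = ((0, 0), (100, 100))
        both = render_projection([(v1, f1), (v2, f1)], "top", bounds=bounds,
                                 resolution=200)
        one = render_projection([(v1, f1)], "top", bounds=bounds, resolution=200)
        two = render_projection([(v2, f1)], "top", bounds=bounds, resolution=200)
        assert ((both.pixels == 0).sum()
                == (one.pixels == 0).sum() + (two.pixels == 0).sum())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            render_projection([], "top")
        with pytest.raises(ValueError):
            render_projection([square_mesh()], "sideways")


class TestPreprocess:
    def test_noiseless_round_trip(self):
        img = render_projection([square_mesh(50.0)], "top",
                                bounds=((-10, -10), (90, 90)), resolution=128)
        mask = preprocess(img)
        # identical up to the 4 corner pixels the 3x3 median rounds off
        assert (mask != (img.pixels == 0)).sum() <= 4

    def test_salt_and_pepper_robustness(self, rng):
        img = render_projection([square_mesh(50.0)], "top",
                                bounds=((-10, -10), (90, 90)), resolution=128)
        truth = img.pixels == 0
        noisy = img.pixels.copy()
        flips = rng.random(noisy.shape) < 0.01
        noisy[flips] = 255 - noisy[flips]
        mask = preprocess(ProjectionImage(noisy, img.mm_per_pixel))
        assert (mask != truth).mean() < 0.005

    def test_polarity_flag(self):
        img = render_projection([square_mesh(50.0)], "top",
                                bounds=((-10, -10), (90, 90)), resolution=128)
        inverted = ProjectionImage(255 - img.pixels, img.mm_per_pixel)
        assert np.array_equal(preprocess(img, "dark"),
                              preprocess(inverted, "light"))
        assert np.array_equal(preprocess(img, "auto"),
                              preprocess(inverted, "auto"))

    def test_no_contrast_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            preprocess(ProjectionImage(np.full((32, 32), 128, np.uint8), 1.0))


class TestContourAndArea:
    def test_full_block_hull(self):
        mask = np.zeros((30, 30), bool)
        mask[5:15, 5:15] = True
        assert outer_contour_area(mask, 1.0) == pytest.approx(100.0)
        assert outer_contour_area(mask, 1.0, pixel_extent_correction=False) \
            == pytest.approx(81.0)
        assert outer_contour_area(mask, 2.0) == pytest.approx(400.0)

    def test_hull_spans_disjoint_blocks(self):
        mask = np.zeros((40, 40), bool)
        mask[:5, :5] = True
        mask[35:, 35:] = True
        s = outer_contour_area(mask, 1.0)
        assert s > windward_area(mask, 1.0)

    def test_hull_contains_foreground(self, rng):
        for _ in range(5):
            mask = rng.random((25, 25)) < 0.2
            if mask.sum() < 3:
                continue
            assert (outer_contour_area(mask, 1.0)
                    >= windward_area(mask, 1.0) - 1e-9)

    def test_too_few_pixels(self):
        mask = np.zeros((10, 10), bool)
        mask[2, 2] = True
        with pytest.raises(EmptyLayerError):
            outer_contour_area(mask, 1.0)
        mask[5, 5] = mask[8, 8] = True  # collinear
        with pytest.raises(EmptyLayerError):
            outer_contour_area(mask, 1.0)

    def test_empty_windward_area(self):
        assert windward_area(np.zeros((5, 5), bool), 1.0) == 0.0


class TestPorosityModes:
    def test_ring_mask_half_porosity(self):
        """36-pixel ring + 14 interior pixels inside a 10x10 hull:
        A = 50, S = 100, so both conventions read exactly 0.50."""
        mask = np.zeros((14, 14), bool)
        mask[2:12, 2:12] = True
        interior = np.zeros_like(mask)
        interior[3:11, 3:11] = True
        mask &= ~interior
        filled = 0
        for i in range(3, 11):
            for j in range(3, 11):
                if filled < 14:
                    mask[i, j] = True
                    filled += 1
        lp = porosity_from_mask(mask, 1.0)
        assert lp.area_windward == pytest.approx(50.0)
        assert lp.area_contour == pytest.approx(100.0)
        assert lp.p_literal == pytest.approx(0.5)
        assert lp.p_optical == pytest.approx(0.5)

    def test_modes_sum_to_one(self, rng):
        for _ in range(5):
            mask = rng.random((30, 30)) < 0.3
            lp = porosity_from_mask(mask, 1.0)
            assert lp.p_literal + lp.p_optical == pytest.approx(1.0, abs=1e-12)
            assert 0.0 <= lp.p_literal <= 1.0
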