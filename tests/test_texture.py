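"""GLCM construction and Haralick-style texture statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bcicm as B
from bcicm.errors import (
    DegenerateCorrelationError,
    GLCMContractError,
    InvalidInputError,
    NoPairsError,
)
from bcicm.texture import GLCM

from conftest import brute_force_glcm


def glcm_from_probs(mapping, n_levels):
    probs = np.zeros((n_levels, n_levels))
    for (i, j), p in mapping.items():
        probs[i, j] = p
    return GLCM(counts=np.zeros_like(probs, dtype=int), probs=probs)


def directional_params(n_levels, angle=0, symmetric=False, distance=1):
    return B.GLCMParams(distance=distance, angles=(angle,), n_levels=n_levels,
                        symmetric=symmetric, average_angles=False)


class TestQuantize:
    def test_constant_image_maps_to_single_level(self):
        img = B.quantize_image(np.full((5, 5), 128), 8)
        assert len(np.unique(img.pixels)) == 1

    def test_extremes_map_to_extreme_bins(self):
        img = B.quantize_image(np.array([[0, 255]]), 2)
        assert img.pixels.tolist() == [[0, 1]]

    def test_ramp_fills_uniform_bins_equally(self):
        # 256-pixel ramp into 4 bins: exactly 64 pixels per level
        img = B.quantize_image(np.arange(256).reshape(16, 16), 4)
        counts = np.bincount(img.pixels.ravel(), minlength=4)
        assert counts.tolist() == [64, 64, 64, 64]

    def test_monotone(self):
        rng = np.random.default_rng(0)
        raw = rng.integers(0, 256, size=(12, 12))
        img = B.quantize_image(raw, 8)
        order = np.argsort(raw.ravel())
        assert np.all(np.diff(img.pixels.ravel()[order]) >= 0)

    def test_empty_image_rejected(self):
        with pytest.raises(InvalidInputError):
            B.quantize_image(np.empty((0, 3)), 8)


class TestComputeGLCM:
    def test_horizontal_pairs(self):
        img = B.GrayImage(np.array([[0, 0], [1, 1]]), 2)
        g = B.compute_glcm(img, directional_params(2, angle=0))
        assert g.counts.tolist() == [[1, 0], [0, 1]]

    def test_vertical_pairs_land_off_diagonal(self):
        img = B.GrayImage(np.array([[0, 0], [1, 1]]), 2)
        g = B.compute_glcm(img, directional_params(2, angle=90))
        off_diag = g.counts - np.diag(np.diag(g.counts))
        assert off_diag.sum() == 2 and np.count_nonzero(off_diag) == 1

    def test_constant_image_all_pairs_identical(self):
        M, N, c = 4, 6, 2
        img = B.GrayImage(np.full((M, N), c), 4)
        g = B.compute_glcm(img, directional_params(4, angle=0))
        assert g.counts[c, c] == M * (N - 1) and g.counts.sum() == M * (N - 1)

    def test_too_small_for_offset(self):
        img = B.GrayImage(np.array([[0, 1]]), 2)
        with pytest.raises(NoPairsError):
            B.compute_glcm(img, directional_params(2, angle=0, distance=5))

    @pytest.mark.parametrize("symmetric", [False, True])
    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    def test_matches_brute_force_on_random_images(self, angle, symmetric):
        rng = np.random.default_rng(42)
        for _ in range(25):
            M, N = rng.integers(2, 7, size=2)
            n_levels = int(rng.integers(2, 5))
            px = rng.integers(0, n_levels, size=(M, N))
            img = B.GrayImage(px, n_levels)
            got = B.compute_glcm(img, directional_params(n_levels, angle, symmetric))
            expected = brute_force_glcm(px, n_levels, 1, angle, symmetric)
            assert np.array_equal(got.counts, expected)
            assert got.probs.sum() == pytest.approx(1.0)

    def test_symmetric_equals_reverse_direction_sum(self):
        # symmetric counting of theta equals theta plus its 180-degree pair
        rng = np.random.default_rng(7)
        px = rng.integers(0, 4, size=(6, 6))
        img = B.GrayImage(px, 4)
        for angle in (0, 45, 90, 135):
            sym = B.compute_glcm(img, directional_params(4, angle, symmetric=True)).counts
            fwd = brute_force_glcm(px, 4, 1, angle, symmetric=False)
            assert np.array_equal(sym, fwd + fwd.T)

    def test_angle_average_is_mean_of_normalized_tables(self):
        rng = np.random.default_rng(9)
        px = rng.integers(0, 3, size=(5, 5))
        img = B.GrayImage(px, 3)
        params = B.GLCMParams(n_levels=3, symmetric=True, average_angles=True)
        avg = B.compute_glcm(img, params).probs
        singles = [
            B.compute_glcm(img, directional_params(3, a, symmetric=True)).probs
            for a in (0, 45, 90, 135)
        ]
        assert np.allclose(avg, np.mean(singles, axis=0))


class TestStatistics:
    def test_worked_examples(self):
        # frozen hand-computed sums over small explicit tables
        assert B.asm(glcm_from_probs({(0, 0): 1.0}, 2)) == pytest.approx(1.0)
        assert B.asm(glcm_from_probs({(0, 0): 0.5, (1, 1): 0.5}, 2)) == pytest.approx(0.5)
        assert B.con(glcm_from_probs({(0, 0): 0.5, (1, 1): 0.5}, 2)) == pytest.approx(0.0)
        assert B.con(glcm_from_probs({(0, 1): 1.0}, 2)) == pytest.approx(1.0)
        assert B.con(glcm_from_probs({(0, 2): 0.5, (2, 0): 0.5}, 3)) == pytest.approx(4.0)
        assert B.idm(glcm_from_probs({(0, 0): 0.5, (1, 1): 0.5}, 2)) == pytest.approx(1.0)
        assert B.idm(glcm_from_probs({(0, 1): 1.0}, 2)) == pytest.approx(0.5)
        assert B.idm(glcm_from_probs({(0, 0): 0.5, (0, 2): 0.5}, 3)) == pytest.approx(0.6)
        assert B.cor(glcm_from_probs({(0, 0): 0.5, (1, 1): 0.5}, 2)) == pytest.approx(1.0)
        assert B.cor(glcm_from_probs({(0, 1): 0.5, (1, 0): 0.5}, 2)) == pytest.approx(-1.0)
        assert B.ent(glcm_from_probs({(0, 0): 1.0}, 2)) == pytest.approx(0.0)
        assert B.ent(
            glcm_from_probs({(0, 0): 0.25, (0, 1): 0.25, (1, 0): 0.25, (1, 1): 0.25}, 2)
        ) == pytest.approx(2.0)
        assert B.ent(
            glcm_from_probs({(0, 0): 0.5, (0, 1): 0.25, (1, 0): 0.25}, 2)
        ) == pytest.approx(1.5)

    def test_uniform_asm_is_one_over_cells(self):
        n = 3
        probs = np.full((n, n), 1.0 / n**2)
        assert B.asm(GLCM(counts=np.ones((n, n), int), probs=probs)) == pytest.approx(1 / n**2)

    def test_degenerate_correlation_raises(self):
        img = B.GrayImage(np.full((4, 4), 1), 4)
        g = B.compute_glcm(img, directional_params(4))
        with pytest.raises(DegenerateCorrelationError):
            B.cor(g)

    def test_unnormalized_table_rejected(self):
        bad = GLCM(counts=np.ones((2, 2), int), probs=np.ones((2, 2)))
        for stat in (B.asm, B.con, B.idm, B.cor, B.ent):
            with pytest.raises(GLCMContractError):
                stat(bad)


@st.composite
def small_images(draw):
    n_levels = draw(st.integers(2, 5))
    M = draw(st.integers(2, 8))
    N = draw(st.integers(2, 8))
    seed = draw(st.integers(0, 2**16))
    px = np.random.default_rng(seed).integers(0, n_levels, size=(M, N))
    return B.GrayImage(px, n_levels)


class TestProperties:
    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(small_images())
    def test_feature_ranges(self, img):
        params = B.GLCMParams(n_levels=img.n_levels)
        g = B.compute_glcm(img, params)
        assert 0 < B.asm(g) <= 1
        assert B.con(g) >= 0
        assert 0 < B.idm(g) <= 1
        assert B.ent(g) >= 0
        try:
            assert -1 - 1e-12 <= B.cor(g) <= 1 + 1e-12
        except DegenerateCorrelationError:
            pass

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(small_images())
    def test_contrast_zero_iff_idm_one_iff_diagonal(self, img):
        g = B.compute_glcm(img, B.GLCMParams(n_levels=img.n_levels))
        diagonal_only = np.allclose(g.probs, np.diag(np.diag(g.probs)))
        assert (B.con(g) == pytest.approx(0.0, abs=1e-12)) == diagonal_only
        assert (B.idm(g) == pytest.approx(1.0)) == diagonal_only

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(small_images())
    def test_transpose_invariance_under_angle_averaging(self, img):
        params = B.GLCMParams(n_levels=img.n_levels, symmetric=True, average_angles=True)
        vec_a = B.extract_feature_vector(img, params).as_array()
        vec_b = B.extract_feature_vector(
            B.GrayImage(img.pixels.T.copy(), img.n_levels), params
        ).as_array()
        assert np.allclose(vec_a, vec_b)

    def test_counts_total_equals_valid_pairs(self):
        rng = np.random.default_rng(5)
        px = rng.integers(0, 3, size=(5, 7))
        img = B.GrayImage(px, 3)
        g = B.compute_glcm(img, directional_params(3, angle=0))
        assert g.counts.sum() == 5 * 6


class TestTamura:
    def test_constant_image_coarseness_is_one(self):
        assert B.tamura_coarseness(B.GrayImage(np.zeros((16, 16), int), 8)) == 1.0

    def test_coarser_checkerboard_scores_higher(self):
        def checker(period, size=32):
            r, c = np.indices((size, size))
            return B.GrayImage((((r // period) + (c // period)) % 2 * 7), 8)

        assert B.tamura_coarseness(checker(8)) > B.tamura_coarseness(checker(2))

    def test_upscaling_never_decreases_coarseness(self):
        rng = np.random.default_rng(0)
        for _ in range(8):
            a = rng.integers(0, 8, size=(8, 8))
            up = np.kron(a, np.ones((2, 2), dtype=int))
            assert B.tamura_coarseness(B.GrayImage(up, 8)) >= B.tamura_coarseness(
                B.GrayImage(a, 8)
            )


class TestExtractVector:
    def test_composition_of_worked_examples(self):
        img = B.GrayImage(np.array([[0, 0], [1, 1]]), 2)
        vec = B.extract_feature_vector(img, directional_params(2, angle=0))
        assert np.allclose(vec.as_array(), [0.5, 0.0, 1.0, 1.0])

    def test_constant_image_correlation_fallback(self):
        img = B.GrayImage(np.full((4, 4), 3), 8)
        with pytest.warns(RuntimeWarning):
            vec = B.extract_feature_vector(img, B.GLCMParams())
        assert np.allclose(vec.as_array(), [1.0, 0.0, 1.0, 0.0])

    def test_optional_components_appended_in_order(self):
        rng = np.random.default_rng(1)
        img = B.GrayImage(rng.integers(0, 8, (16, 16)), 8)
        vec = B.extract_feature_vector(img, B.GLCMParams(), include_optional=True)
        arr = vec.as_array()
        assert arr.shape == (6,)
        assert arr[4] == vec.ent and arr[5] == vec.coarseness

    def test_matches_skimage_reference(self):
        # independent cross-check against the established GLCM implementation
        skimage_feature = pytest.importorskip("skimage.feature")
        rng = np.random.default_rng(2)
        px = rng.integers(0, 8, size=(20, 20))
        ours = B.compute_glcm(B.GrayImage(px, 8), directional_params(8, angle=0, symmetric=True))
        ref = skimage_feature.graycomatrix(
            px.astype(np.uint8), distances=[1], angles=[0], levels=8,
            symmetric=True, normed=True,
        )[:, :, 0, 0]
        assert np.allclose(ours.probs, ref)
        assert B.con(ours) == pytest.approx(
            skimage_feature.graycoprops(ref[:, :, None, None], "contrast").item()
        )
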