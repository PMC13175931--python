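import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from octnss.io import GrayImage
from octnss.neutrosophic import (
    NeutroMaps,
    NeutroParams,
    gradient_magnitude,
    normalize_image,
    nss_map,
    pairwise_similarity,
    tif_maps,
)
from oracles import sobel_naive


def _gray(arr):
    return GrayImage.from_array(np.asarray(arr, dtype=float))


class TestNormalize:
    def test_three_level_image(self):
        out = normalize_image(_gray([[0, 128, 255]] * 3))
        expected = np.array([0.0, 128 / (255 + 1e-8), 255 / (255 + 1e-8)])
        assert np.allclose(out[0], expected, atol=1e-12)

    def test_constant_image_maps_to_zero(self):
        assert np.all(normalize_image(_gray(np.full((5, 5), 7.0))) == 0)

    def test_output_min_is_zero(self):
        rng = np.random.default_rng(3)
        out = normalize_image(_gray(rng.uniform(50, 200, (8, 8))))
        assert out.min() == 0.0
        assert out.max() < 1.0

    def test_non_finite_rejected(self):
        img = GrayImage(np.full((3, 3), np.inf), orig_min=0, orig_max=1)
        with pytest.raises(ValueError):
            normalize_image(img)

    @settings(deadline=None, derandomize=True)
    @given(
        k=st.floats(0.5, 3.0),
        c=st.floats(-50.0, 50.0),
        seed=st.integers(0, 100),
    )
    def test_scale_and_shift_invariance(self, k, c, seed):
        """Normalization is invariant under affine rescaling of intensities."""
        rng = np.random.default_rng(seed)
        base = rng.uniform(0, 255, (6, 6))
        base.flat[0], base.flat[-1] = 0.0, 255.0  # pin a nontrivial range
        a = normalize_image(_gray(base))
        b = normalize_image(_gray(k * base + c))
        assert np.allclose(a, b, atol=1e-6)


class TestGradient:
    def test_constant_raster_has_zero_gradient(self):
        g = gradient_magnitude(np.full((5, 7), 0.3))
        assert g.gd_min == g.gd_max == 0.0
        assert np.all(g.Gd == 0)

    def test_horizontal_ramp_interior_gradient_is_8c(self):
        c = 0.01
        ramp = np.tile(np.arange(9) * c, (9, 1))
        g = gradient_magnitude(ramp)
        assert np.allclose(g.Gd[1:-1, 1:-1], 8 * c, atol=1e-12)

    def test_transpose_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, (9, 13))
        assert np.allclose(gradient_magnitude(x.T).Gd, gradient_magnitude(x).Gd.T)

    def test_matches_naive_loop_sobel(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, (12, 10))
        assert np.allclose(gradient_magnitude(x).Gd, sobel_naive(x), atol=1e-12)

    def test_too_small_raster_rejected(self):
        with pytest.raises(ValueError):
            gradient_magnitude(np.zeros((2, 5)))


class TestTIFMaps:
    def test_extreme_gradient_pixels(self):
        norm = np.linspace(0, 1, 25).reshape(5, 5)
        grad = gradient_magnitude(norm)
        maps = tif_maps(norm, grad)
        at_max = grad.Gd == grad.gd_max
        at_min = grad.Gd == grad.gd_min
        assert np.all(maps.I[at_max] < 1e-7)
        assert np.all(maps.I[at_min] == 1.0)

    def test_constant_image_yields_full_indeterminacy(self):
        norm = np.zeros((5, 5))
        maps = tif_maps(norm, gradient_magnitude(norm))
        assert np.all(maps.I == 1.0)

    def test_falsity_is_complement_of_truth(self):
        rng = np.random.default_rng(2)
        norm = rng.uniform(0, 1, (8, 8))
        maps = tif_maps(norm, gradient_magnitude(norm))
        assert np.allclose(maps.F, 1 - maps.T, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tif_maps(np.zeros((4, 4)), gradient_magnitude(np.zeros((5, 5))))


class TestPairwiseSimilarity:
    def test_self_similarity_is_one(self):
        assert pairwise_similarity((0.3, 0.4, 0.5), (0.3, 0.4, 0.5)) == pytest.approx(1.0)

    def test_orthogonal_triples(self):
        assert pairwise_similarity((1, 0, 0), (0, 1, 0)) == 0.0

    def test_half_triple_against_ideal(self):
        val = pairwise_similarity((1, 0, 0), (0.5, 0.5, 0.5))
        assert val == pytest.approx(0.5 / np.sqrt(0.75), abs=1e-10)
        assert val == pytest.approx(0.57735, abs=1e-5)

    def test_symmetry(self):
        a, b = (0.2, 0.9, 0.8), (0.7, 0.1, 0.3)
        assert pairwise_similarity(a, b) == pairwise_similarity(b, a)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            pairwise_similarity((0, 0, 0), (1, 0, 0))


class TestNSSMap:
    def test_ideal_and_null_pixels(self):
        maps = NeutroMaps(
            T=np.array([[1.0, 0.0, 0.0]]),
            I=np.array([[0.0, 0.5, 1.0]]),
            F=np.array([[0.0, 1.0, 1.0]]),
        )
        s = nss_map(maps).S
        assert s[0, 0] == pytest.approx(1.0)
        assert s[0, 1] == 0.0
        assert s[0, 2] == 0.0

    def test_closed_form_example(self):
        maps = NeutroMaps(T=[[0.8]], I=[[0.3]], F=[[0.2]])
        assert nss_map(maps).S[0, 0] == pytest.approx(0.8 / np.sqrt(0.77), abs=1e-12)
        assert nss_map(maps).S[0, 0] == pytest.approx(0.91168, abs=1e-5)

    def test_pixelwise_equals_pairwise_against_ideal(self):
        """Closed-form map agrees with a per-pixel cosine-similarity loop."""
        rng = np.random.default_rng(17)
        norm = rng.uniform(0, 1, (16, 16))
        maps = tif_maps(norm, gradient_magnitude(norm))
        s = nss_map(maps).S
        for y in range(16):
            for x in range(16):
                ref = pairwise_similarity(
                    (maps.T[y, x], maps.I[y, x], maps.F[y, x]), (1.0, 0.0, 0.0)
                )
                assert abs(s[y, x] - ref) <= 1e-12

    def test_monotone_in_truth_with_complementary_falsity(self):
        t = np.linspace(0.01, 1.0, 200)
        for i_fixed in (0.0, 0.3, 1.0):
            maps = NeutroMaps(
                T=t[None, :], I=np.full((1, t.size), i_fixed), F=(1 - t)[None, :]
            )
            s = nss_map(maps).S[0]
            assert np.all(np.diff(s) > 0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        arrays(
            np.float64,
            (6, 6),
            elements=st.floats(0, 255, allow_nan=False, allow_infinity=False),
        )
    )
    def test_all_maps_stay_in_unit_interval(self, pixels):
        img = GrayImage.from_array(pixels)
        norm = normalize_image(img)
        maps = tif_maps(norm, gradient_magnitude(norm))
        s = nss_map(maps).S
        for r in (maps.T, maps.I, maps.F, s):
            assert r.min() >= 0.0 and r.max() <= 1.0


def test_epsilon_must_be_positive():
    with pytest.raises(ValueError):
        NeutroParams(epsilon=0.0)
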