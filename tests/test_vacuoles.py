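import numpy as np
import pytest

from physio.errors import (
    DegenerateRescaleError,
    EmptyMaskError,
    InsufficientDepthError,
    InvalidParameterError,
    UndefinedRatioError,
    UnimodalHistogramError,
)
from physio.synth import VacuoleStackParams, gen_vacuole_stack
from physio.traceio import ImageStack
from physio.vacuoles import (
    binarize_and_ratio,
    crop_roi,
    mask_soma,
    max_project3,
    score_vacuolization,
    second_peak_threshold,
    to_8bit,
    valley_threshold,
)


def two_population_image(vac_level=40, cyto_level=200, vac_frac=0.3,
                         sigma=8.0, size=100, seed=0):
    """Disc-shaped soma on black background with a dark sector."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[:size, :size]
    r = np.hypot(yy - size / 2, xx - size / 2)
    soma = r < size * 0.4
    img = np.zeros((size, size), dtype=float)
    img[soma] = cyto_level
    dark = soma & (xx < size / 2 - size * 0.4 * (1 - 2 * vac_frac))
    img[dark] = vac_level
    img += rng.normal(0, sigma, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), soma, dark


class TestTo8Bit:
    def test_full_range_16bit_divides_by_257(self):
        planes = np.array([[[0, 257], [514, 65535]]], dtype=np.uint16)
        out = to_8bit(ImageStack(planes))
        np.testing.assert_array_equal(out.planes, [[[0, 1], [2, 255]]])

    def test_8bit_passes_through(self):
        stack = ImageStack(np.arange(16, dtype=np.uint8).reshape(1, 4, 4))
        assert to_8bit(stack) is stack

    def test_global_gain_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 8000, (3, 16, 16)).astype(np.uint16)
        a = to_8bit(ImageStack(base))
        b = to_8bit(ImageStack((base * 8).astype(np.uint16)))
        np.testing.assert_array_equal(a.planes, b.planes)

    def test_constant_stack_rejected(self):
        with pytest.raises(DegenerateRescaleError):
            to_8bit(ImageStack(np.full((2, 4, 4), 7, dtype=np.uint16)))


class TestCrop:
    def test_centred_crop_is_100_square(self):
        stack = ImageStack(np.zeros((2, 512, 512), dtype=np.uint8))
        out = crop_roi(stack, (256, 256), 100)
        assert out.planes.shape == (2, 100, 100)

    def test_exact_rows_and_cols(self):
        planes = np.tile(np.arange(512, dtype=np.uint8), (1, 512, 1))
        out = crop_roi(ImageStack(planes), (256, 256), 100)
        assert out.planes[0, 0, 0] == 206 % 256
        assert out.planes[0, 0, -1] == 49  # 305 mod 256

    def test_border_centre_clipped(self):
        stack = ImageStack(np.zeros((1, 120, 120), dtype=np.uint8))
        out = crop_roi(stack, (10, 10), 100)
        assert out.planes.shape[1] < 100

    def test_crop_of_crop_same_centre_is_identity(self):
        rng = np.random.default_rng(1)
        stack = ImageStack(rng.integers(0, 255, (1, 300, 300),
                                        dtype=np.uint8))
        once = crop_roi(stack, (150, 150), 100)
        twice = crop_roi(once, (50, 50), 100)
        np.testing.assert_array_equal(once.planes, twice.planes)

    def test_centre_outside_rejected(self):
        stack = ImageStack(np.zeros((1, 64, 64), dtype=np.uint8))
        with pytest.raises(InvalidParameterError):
            crop_roi(stack, (100, 100))


class TestProjection:
    def test_three_identical_planes_project_to_themselves(self):
        plane = np.arange(16, dtype=np.uint8).reshape(4, 4)
        stack = ImageStack(np.stack([plane] * 3))
        np.testing.assert_array_equal(max_project3(stack, 0), plane)

    def test_projection_takes_pixelwise_max(self):
        planes = np.stack([np.full((4, 4), v, dtype=np.uint8)
                           for v in (1, 2, 3)])
        np.testing.assert_array_equal(max_project3(ImageStack(planes), 0), 3)

    def test_insufficient_depth_raises(self):
        stack = ImageStack(np.zeros((2, 4, 4), dtype=np.uint8))
        with pytest.raises(InsufficientDepthError):
            max_project3(stack, 0)


class TestMaskSoma:
    def test_mask_area_close_to_projected_soma(self):
        p = VacuoleStackParams(seed=4)
        stack, truth = gen_vacuole_stack(p)
        s8 = to_8bit(stack)
        proj = max_project3(s8, truth["nucleus_plane"] - 1)
        mask = mask_soma(proj)
        true_area = truth["black_pixels"] + truth["white_pixels"]
        assert mask.sum() == pytest.approx(true_area, rel=0.10)

    def test_manual_mask_returned_verbatim(self):
        proj = np.zeros((10, 10), dtype=np.uint8)
        manual = np.zeros((10, 10), dtype=bool)
        manual[2:5, 2:5] = True
        np.testing.assert_array_equal(mask_soma(proj, manual), manual)

    def test_all_background_image_raises(self):
        proj = np.zeros((32, 32), dtype=np.uint8)
        with pytest.raises(EmptyMaskError):
            mask_soma(proj)


class TestSecondPeakThreshold:
    def test_returns_second_highest_peak_intensity(self):
        # construct in-mask values with a tall dark peak and a smaller
        # bright one: heights ~500 at 30 vs ~300 at 180
        rng = np.random.default_rng(2)
        vals = np.concatenate([
            np.clip(rng.normal(30, 3, 5000), 0, 255),
            np.clip(rng.normal(180, 3, 3000), 0, 255),
        ])
        img = vals.reshape(80, 100).astype(np.uint8)
        mask = np.ones_like(img, dtype=bool)
        thr = second_peak_threshold(img, mask)
        assert abs(thr - 180) <= 5

    def test_two_population_image_threshold_near_cytoplasm_mode(self):
        # heavily vacuolated cell: the dark mode dominates and the
        # cytoplasmic mode is the second-highest peak
        img, soma, dark = two_population_image(vac_frac=0.6)
        thr = second_peak_threshold(img, soma)
        assert abs(thr - 200) <= 10

    def test_unimodal_image_raises(self):
        img, soma, _ = two_population_image(vac_frac=0.0)
        with pytest.raises(UnimodalHistogramError):
            second_peak_threshold(img, soma)


class TestBinarize:
    def test_counts_and_ratio(self):
        img = np.zeros((20, 10), dtype=np.uint8)
        img[:4] = 10    # 40 dark pixels
        img[4:] = 200   # 160 bright pixels
        mask = np.ones_like(img, dtype=bool)
        res = binarize_and_ratio(img, mask, 100)
        assert (res.black_pixels, res.white_pixels) == (40, 160)
        assert res.bw_ratio == pytest.approx(0.25)

    def test_no_black_pixels_ratio_zero(self):
        img = np.full((10, 10), 200, dtype=np.uint8)
        res = binarize_and_ratio(img, np.ones_like(img, bool), 100)
        assert res.bw_ratio == 0.0

    def test_boundary_pixels_equal_to_threshold_are_white(self):
        img = np.full((10, 10), 100, dtype=np.uint8)
        res = binarize_and_ratio(img, np.ones_like(img, bool), 100)
        assert res.black_pixels == 0

    def test_zero_white_pixels_undefined(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(UndefinedRatioError):
            binarize_and_ratio(img, np.ones_like(img, bool), 100)

    def test_empty_mask_rejected(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(EmptyMaskError):
            binarize_and_ratio(img, np.zeros_like(img, bool), 100)


class TestFullScoring:
    def test_ratio_ladder_monotone_and_within_15_percent(self):
        measured, truths = [], []
        for frac in (0.1, 0.3, 0.5):
            p = VacuoleStackParams(target_volume_fraction=frac, seed=11)
            stack, truth = gen_vacuole_stack(p)
            res = score_vacuolization(stack, truth["nucleus_plane"])
            measured.append(res.bw_ratio)
            truths.append(truth["bw_ratio"])
        assert measured[0] < measured[1] < measured[2]
        for m, t in zip(measured, truths):
            assert m == pytest.approx(t, rel=0.15)

    def test_zero_vacuole_stack_scores_zero(self):
        stack, truth = gen_vacuole_stack(VacuoleStackParams(seed=2))
        res = score_vacuolization(stack, truth["nucleus_plane"])
        assert res.bw_ratio == 0.0
        assert res.flag == "unimodal"

    def test_score_invariant_to_global_gain(self):
        p = VacuoleStackParams(target_volume_fraction=0.3, seed=6)
        stack, truth = gen_vacuole_stack(p)
        dimmed = ImageStack((stack.planes // 4).astype(np.uint16),
                            voxel_size_nm=stack.voxel_size_nm)
        a = score_vacuolization(stack, truth["nucleus_plane"])
        b = score_vacuolization(dimmed, truth["nucleus_plane"])
        assert a.bw_ratio == pytest.approx(b.bw_ratio, rel=0.02)

    def test_deterministic_scoring(self):
        p = VacuoleStackParams(target_volume_fraction=0.2, seed=8)
        stack, truth = gen_vacuole_stack(p)
        a = score_vacuolization(stack, truth["nucleus_plane"])
        b = score_vacuolization(stack, truth["nucleus_plane"])
        assert (a.black_pixels, a.white_pixels, a.threshold) == \
            (b.black_pixels, b.white_pixels, b.threshold)


def test_valley_threshold_lies_between_the_modes():
    img, soma, _ = two_population_image(vac_frac=0.4)
    cut = valley_threshold(img, soma)
    assert 60 < cut < 180
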