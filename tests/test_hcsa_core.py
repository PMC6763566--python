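import numpy as np
import pytest
from hypothesis import given, strategies as st

from hcsa.errors import ConfigError, DegenerateContrastError, DegenerateInputError
from hcsa.geometry import RoiMask, rasterize_polygon
from hcsa.hcsa_core import (
    classify_hb,
    compute_hb_contrast,
    measure_blush,
    otsu_threshold,
)
from hcsa.io_formats import ImageSeries, RunConfig

from oracles import otsu_attains_maximum, otsu_exhaustive


class TestOtsu:
    def test_two_point_distribution_splits_the_masses(self):
        values = np.array([0.0] * 50 + [1.0] * 50)
        res = otsu_threshold(values, 256)
        assert 0.0 < res.threshold < 1.0
        assert classify_hb(values, res).sum() == 50
        # every separating edge scores the same; ties go to the lowest
        assert res.threshold == pytest.approx(1.0 / 256)

    def test_bimodal_matches_exhaustive_search(self, rng):
        values = np.concatenate(
            [rng.normal(0.2, 0.05, 500), rng.normal(0.8, 0.05, 500)]
        )
        res = otsu_threshold(values, 256)
        _, crit_oracle, _, _ = otsu_exhaustive(values, 256)
        assert otsu_attains_maximum(res, values, 256)
        assert res.between_class_variance == pytest.approx(crit_oracle, rel=1e-9)

    @pytest.mark.parametrize("kind", ["uniform", "unimodal", "bimodal", "eightbit"])
    def test_random_histograms_match_exhaustive_search(self, kind, rng):
        for _ in range(10):
            if kind == "uniform":
                v = rng.uniform(0, 1, 400)
            elif kind == "unimodal":
                v = rng.normal(0.5, 0.1, 400)
            elif kind == "bimodal":
                v = np.concatenate(
                    [rng.normal(0.25, 0.07, 200), rng.normal(0.75, 0.07, 200)]
                )
            else:
                v = rng.integers(0, 256, 400).astype(float)
            res = otsu_threshold(v, 256)
            assert otsu_attains_maximum(res, v, 256)

    def test_threshold_lies_in_histogram_range(self, rng):
        v = rng.normal(0, 1, 100)
        res = otsu_threshold(v, 64)
        lo, hi = res.histogram_range
        assert lo < res.threshold < hi
        assert res.between_class_variance >= 0

    @given(
        a=st.floats(min_value=0.1, max_value=50),
        b=st.floats(min_value=-10, max_value=10),
    )
    def test_affine_rescaling_classifies_identical_pixels(self, a, b):
        rng = np.random.default_rng(42)
        v = np.concatenate([rng.normal(0.3, 0.05, 150), rng.normal(0.7, 0.05, 150)])
        r0 = otsu_threshold(v, 256)
        r1 = otsu_threshold(a * v + b, 256)
        np.testing.assert_array_equal(
            classify_hb(v, r0), classify_hb(a * v + b, r1)
        )

    def test_identical_values_are_degenerate(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.ones(10), 256)


def _two_channel_series(weak, strong):
    frames = np.stack([np.asarray(weak), np.asarray(strong)], axis=-1)
    return ImageSeries(
        frames=frames.astype(np.float64),
        bit_depth=16,
        channel_names=("red", "green"),
    )


class TestContrast:
    def test_channel_difference_formula(self):
        # series raw-difference range [-0.1, 0.9]; pixel (0.9 - 0.2) -> 0.8
        weak = np.array([[[0.9, 0.0]], [[0.4, 0.9]]])
        strong = np.array([[[0.2, 0.1]], [[0.5, 0.0]]])
        series = _two_channel_series(weak, strong)
        stack = compute_hb_contrast(series, RunConfig())
        assert stack.norm_min == pytest.approx(-0.1)
        assert stack.norm_max == pytest.approx(0.9)
        assert stack.frames[0, 0, 0] == pytest.approx(0.8)

    def test_uniform_series_is_degenerate(self):
        weak = np.ones((3, 4, 4))
        series = _two_channel_series(weak, weak)
        with pytest.raises(DegenerateContrastError):
            compute_hb_contrast(series, RunConfig())

    def test_missing_channel_role_is_config_error(self):
        series = _two_channel_series(np.zeros((2, 2, 2)), np.ones((2, 2, 2)))
        cfg = RunConfig()
        cfg.channel_roles = {"weak": "red"}
        with pytest.raises(ConfigError):
            compute_hb_contrast(series, cfg)

    def test_single_channel_inverted_makes_dark_blood_bright(self):
        frames = np.array([[[10.0, 200.0]], [[100.0, 150.0]]])
        series = ImageSeries(frames=frames, bit_depth=16)
        stack = compute_hb_contrast(
            series, RunConfig(contrast_mode="single_channel_inverted")
        )
        assert stack.frames[0, 0, 0] == pytest.approx(1.0)  # darkest pixel
        assert stack.frames[0, 0, 1] == pytest.approx(0.0)  # brightest pixel

    def test_phantom_blood_brighter_than_myocardium(self, default_phantom):
        params, series, rois, truth = default_phantom
        stack = compute_hb_contrast(series, RunConfig())
        h, w = params.image_shape
        cx, cy = (w - 1) / 2, (h - 1) / 2
        yy, xx = np.mgrid[0:h, 0:w]
        for i in range(series.n_frames):
            s = truth.phase[i]
            a = params.blood_semi_axes_es[0] + (
                params.blood_semi_axes_ed[0] - params.blood_semi_axes_es[0]
            ) * s
            b = params.blood_semi_axes_es[1] + (
                params.blood_semi_axes_ed[1] - params.blood_semi_axes_es[1]
            ) * s
            blood = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1
            outer = ((xx - cx) / (a + params.wall_thickness_px)) ** 2 + (
                (yy - cy) / (b + params.wall_thickness_px)
            ) ** 2 <= 1
            wall = outer & ~blood
            assert stack.frames[i][blood].mean() > stack.frames[i][wall].mean()


class TestBlush:
    def _mask(self):
        return rasterize_polygon([(2, 2), (2, 12), (12, 12), (12, 2)], (16, 16))

    def test_all_below_threshold_gives_zero(self):
        m = self._mask()
        frame = np.zeros((16, 16))
        b = measure_blush(frame, m, 0.5)
        assert b.blush_px == 0 and b.roi_area_px == m.area_px

    def test_all_above_threshold_fills_roi(self):
        m = self._mask()
        b = measure_blush(np.ones((16, 16)), m, 0.5)
        assert b.blush_px == b.roi_area_px == m.area_px

    def test_blush_monotone_nonincreasing_in_threshold(self, rng):
        m = self._mask()
        frame = rng.uniform(0, 1, (16, 16))
        counts = [measure_blush(frame, m, t).blush_px for t in np.linspace(0, 1, 21)]
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_phantom_ed_blush_recovers_analytic_blood_area(self, default_phantom):
        params, series, rois, truth = default_phantom
        from hcsa.pipeline import quantify

        res = quantify(series, rois)
        assert res.metrics.EDBA == pytest.approx(truth.EDBA_true, rel=0.05)
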