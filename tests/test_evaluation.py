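"""ROI statistics, contrast, CNR, line profiles and edge widths."""

import math

import numpy as np
import pytest

import kernelfuse as kf
from kernelfuse.evaluation import (ROI, LineProfileSpec, cnr, default_roi_plan,
                                   edge_width, evaluate, gm_wm_contrast,
                                   line_profile, roi_stats)


class TestRoiStats:
    def test_listed_values(self):
        img = np.full((9, 9), 5.0)
        img[4, 3:6] = [1.0, 2.0, 3.0]
        roi = ROI(center=(4, 4), axes=(0.6, 1.2))
        mean, std = roi_stats(img, roi)
        assert mean == pytest.approx(2.0) and std == pytest.approx(1.0)

    def test_constant_roi_has_zero_std(self):
        mean, std = roi_stats(np.full((16, 16), 7.0), ROI((8, 8), (3, 3)))
        assert std == 0.0

    def test_noise_roi_covers_about_a_thousand_pixels(self, default_spec, roi_plan):
        m = roi_plan["noise"].mask((512, 512))
        expected = 240.0 / default_spec.spacing**2   # 2.4 cm^2 in pixels
        assert m.sum() == pytest.approx(expected, rel=0.02)

    def test_roi_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            roi_stats(np.zeros((16, 16)), ROI((2, 2), (5, 5)))


class TestContrastAndCnr:
    def test_noise_free_phantom_contrast_is_thirteen(self, phantom, roi_plan):
        assert gm_wm_contrast(phantom, roi_plan["gm"], roi_plan["wm"]) == pytest.approx(13.0)

    def test_contrast_is_symmetric_in_the_rois(self, phantom, roi_plan):
        a = gm_wm_contrast(phantom, roi_plan["gm"], roi_plan["wm"])
        b = gm_wm_contrast(phantom, roi_plan["wm"], roi_plan["gm"])
        assert a == b

    def test_cnr_of_reported_contrast_and_noise_pair(self):
        # contrast 12.44 HU over noise 2.65 HU
        assert cnr(12.44, 2.65) == pytest.approx(4.694, abs=0.01)

    def test_cnr_homogeneity_and_zero_contrast(self):
        assert cnr(0.0, 3.0) == 0.0
        assert cnr(10.0, 4.0) == pytest.approx(cnr(10.0, 2.0) / 2.0)
        with pytest.raises(ValueError):
            cnr(5.0, 0.0)


class TestLineProfile:
    def test_constant_image_gives_constant_profile(self):
        p = line_profile(np.full((32, 32), 4.0), LineProfileSpec((2, 2), (29, 29), 50))
        assert np.allclose(p, 4.0)

    def test_two_sample_profile_hits_exact_pixel_values(self, rng):
        img = rng.normal(size=(16, 16))
        p = line_profile(img, LineProfileSpec((3, 4), (10, 12), 2))
        assert p[0] == pytest.approx(img[3, 4])
        assert p[1] == pytest.approx(img[10, 12])

    def test_profile_across_the_fracture_shows_a_local_minimum(self, default_spec):
        spec = kf.PhantomSpec(fracture_angle_deg=90.0)   # gap along +y
        truth = kf.make_phantom(spec, seed=0)
        quiet_sharp = kf.KernelSpec(name="sharp", psf_sigma_mm=0.3, boost_gain=0.8,
                                    noise_hu={})
        img = kf.simulate_series(truth, quiet_sharp, 1.0)
        c = (spec.grid - 1) / 2.0
        y_mid = c + (spec.skull_outer_axes[0] - 3.0) / spec.spacing
        prof = line_profile(img, LineProfileSpec(
            (y_mid, c - 12), (y_mid, c + 12), 49))
        mid = len(prof) // 2
        assert prof[mid] < prof[4] and prof[mid] < prof[-5]

    def test_endpoint_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            line_profile(np.zeros((8, 8)), LineProfileSpec((0, 0), (9, 9)))


class TestEdgeWidth:
    def test_gaussian_blurred_step_width_matches_quantile_difference(self):
        # 10-90% width of an erf edge = (z_0.9 - z_0.1) * sigma = 2.5631 sigma
        from scipy.special import erf
        sigma = 4.0
        x = np.arange(200, dtype=float)
        profile = 0.5 * (1 + erf((x - 100) / (sigma * np.sqrt(2))))
        w = edge_width(profile)
        assert w == pytest.approx(2.5631 * sigma, rel=0.02)

    def test_width_is_offset_invariant(self):
        from scipy.special import erf
        x = np.arange(120, dtype=float)
        p = 0.5 * (1 + erf((x - 60) / 3.0))
        assert edge_width(p + 500.0) == pytest.approx(edge_width(p))

    def test_ideal_step_width_vanishes_with_sampling_density(self):
        # same physical extent, 10x denser sampling -> 10x smaller 10-90 width
        coarse = edge_width(np.repeat([0.0, 1.0], 10), sample_spacing=1.0)
        fine = edge_width(np.repeat([0.0, 1.0], 100), sample_spacing=0.1)
        assert fine == pytest.approx(coarse / 10.0, rel=1e-6)
        assert fine < 0.1

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError):
            edge_width(np.ones(20))


class TestEvaluate:
    @pytest.fixture(scope="class")
    def small_test_set(self):
        examples, _ = kf.make_dataset(kf.PhantomSpec(), n_slices=2, seed=77)
        return examples

    def test_zero_residual_model_has_unit_noise_reduction(self, small_test_set):
        # anchored on the sharp-LD input, output == input -> factor exactly 1
        net = kf.build_model(kf.ModelConfig(anchor="sharp"), seed=0)
        report = evaluate(net, small_test_set, compose=False)
        for row in report.rows:
            assert row["noise_reduction_factor"] == pytest.approx(1.0)

    def test_report_has_one_row_per_slice_and_consistent_cnr(self, small_test_set):
        net = kf.build_model(seed=0)
        report = evaluate(net, small_test_set)
        assert len(report.rows) == 2
        for row in report.rows:
            assert row["cnr_output"] == pytest.approx(
                row["contrast_output"] / row["noise_output"])

    def test_smooth_rd_metrics_close_the_loop_with_calibration(self, small_test_set):
        net = kf.build_model(seed=0)
        report = evaluate(net, small_test_set)
        noise = report.mean("noise_smooth_rd")
        assert noise == pytest.approx(6.0, rel=0.25)   # single-slice sampling scatter

    def test_sharpness_ordering_smooth_blurrier_than_sharp(self, phantom, default_spec):
        from kernelfuse.evaluation import _profile_step, _skull_profile_spec
        quiet_s = kf.KernelSpec(name="smooth", psf_sigma_mm=1.0, noise_hu={})
        quiet_q = kf.KernelSpec(name="sharp", psf_sigma_mm=0.3, boost_gain=0.8,
                                noise_hu={})
        spec_line = _skull_profile_spec(default_spec)
        step = _profile_step(spec_line)
        w_s = edge_width(line_profile(kf.simulate_series(phantom, quiet_s, 1.0), spec_line),
                         step)
        w_q = edge_width(line_profile(kf.simulate_series(phantom, quiet_q, 1.0), spec_line),
                         step)
        assert w_s > w_q
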