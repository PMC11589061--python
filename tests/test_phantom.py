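"""Phantom geometry, series simulation and slab averaging."""

import numpy as np
import pytest

import kernelfuse as kf
from kernelfuse.evaluation import roi_stats
from kernelfuse.phantom import slab_weights, interslice_rho_for_slab, validate_kernel_pair


class TestPhantomGeometry:
    def test_gray_white_contrast_is_exact_on_noise_free_image(self, phantom, roi_plan):
        gm = roi_stats(phantom, roi_plan["gm"])[0]
        wm = roi_stats(phantom, roi_plan["wm"])[0]
        assert abs(gm - wm) == pytest.approx(13.0, abs=1e-12)

    def test_same_seed_reproduces_identical_image(self, default_spec):
        a = kf.make_phantom(default_spec, seed=5)
        b = kf.make_phantom(default_spec, seed=5)
        assert np.array_equal(a.pixels, b.pixels)

    def test_background_far_from_head_is_air(self, phantom):
        assert phantom.pixels[5, 5] == -1000.0

    def test_contains_all_tissue_classes(self, phantom, default_spec):
        vals = phantom.pixels
        for hu in (default_spec.hu_cortical, default_spec.hu_wm, default_spec.hu_gm,
                   default_spec.hu_csf, default_spec.hu_vitreous, default_spec.hu_scalp):
            assert np.any(vals == hu)

    def test_fracture_gap_pierces_the_skull(self, default_spec):
        with_gap = kf.make_phantom(default_spec, seed=1).pixels
        without = kf.make_phantom(
            kf.PhantomSpec(fracture=False), seed=1).pixels
        changed = with_gap != without
        assert changed.any()
        assert np.all(with_gap[changed] == default_spec.hu_fracture_gap)

    def test_vitreous_region_hosts_the_noise_roi(self, phantom, roi_plan):
        mean, std = roi_stats(phantom, roi_plan["noise"])
        assert mean == 10.0 and std == 0.0

    @pytest.mark.parametrize("bad", [
        dict(hu_gm=20.0, hu_wm=25.0),
        dict(hu_cortical=50.0),
        dict(eye_radius_mm=5.0),
        dict(grid=16),
        dict(scalp_axes=(140.0, 78.0)),
    ])
    def test_invalid_specs_are_rejected(self, bad):
        with pytest.raises(ValueError):
            kf.PhantomSpec(**bad)


class TestSeriesSimulation:
    def test_zero_noise_magnitude_returns_psf_convolved_truth(self, phantom):
        quiet = kf.KernelSpec(name="smooth", psf_sigma_mm=1.0, noise_hu={})
        out = kf.simulate_series(phantom, quiet, 1.0, seed=0)
        ref = kf.simulate_series(phantom, quiet, 0.5, seed=99)
        assert np.array_equal(out.pixels, ref.pixels)  # noise-free: dose/seed irrelevant

    def test_psf_preserves_mean_of_uniform_region(self, phantom, roi_plan):
        for kern in (kf.smooth_kernel(), kf.sharp_kernel()):
            quiet = kf.KernelSpec(name=kern.name, psf_sigma_mm=kern.psf_sigma_mm,
                                  boost_gain=kern.boost_gain,
                                  boost_sigma_mm=kern.boost_sigma_mm, noise_hu={})
            out = kf.simulate_series(phantom, quiet, 1.0)
            assert roi_stats(out, roi_plan["noise"])[0] == pytest.approx(10.0, abs=0.5)

    def test_dose_monotonicity_of_measured_roi_noise(self, phantom, roi_plan):
        k = kf.smooth_kernel()
        std_ld = roi_stats(kf.simulate_series(phantom, k, 0.25, seed=3), roi_plan["noise"])[1]
        std_rd = roi_stats(kf.simulate_series(phantom, k, 1.0, seed=3), roi_plan["noise"])[1]
        assert std_ld > std_rd

    def test_shared_base_gives_correlated_noise_independent_bases_do_not(self, phantom):
        import kernelfuse.phantom as P
        ks, kq = kf.smooth_kernel(), kf.sharp_kernel()
        blur_s = P._apply_psf(phantom.pixels, ks, phantom.spacing)
        blur_q = P._apply_psf(phantom.pixels, kq, phantom.spacing)
        base = np.random.default_rng(5).standard_normal(phantom.shape)
        n_s = kf.simulate_series(phantom, ks, 0.25, shared_noise=base).pixels - blur_s
        n_q = kf.simulate_series(phantom, kq, 0.25, shared_noise=base).pixels - blur_q
        assert np.corrcoef(n_s.ravel(), n_q.ravel())[0, 1] > 0.1
        n_s2 = kf.simulate_series(phantom, ks, 0.25, seed=21).pixels - blur_s
        n_q2 = kf.simulate_series(phantom, kq, 0.25, seed=22).pixels - blur_q
        assert abs(np.corrcoef(n_s2.ravel(), n_q2.ravel())[0, 1]) < 0.05

    def test_noise_power_law_passes_through_both_calibration_points(self):
        k = kf.sharp_kernel()
        assert k.noise_hu_at(1.0) == 34.5
        assert k.noise_hu_at(0.25) == 80.1
        assert 34.5 < k.noise_hu_at(0.5) < 80.1

    def test_invalid_dose_rejected(self, phantom):
        with pytest.raises(ValueError):
            kf.simulate_series(phantom, kf.smooth_kernel(), 0.0)

    def test_kernel_pair_ordering_enforced(self):
        noisy_smooth = kf.KernelSpec(name="smooth", psf_sigma_mm=1.0,
                                     noise_hu={1.0: 50.0, 0.25: 90.0})
        with pytest.raises(ValueError):
            validate_kernel_pair(noisy_smooth, kf.sharp_kernel())


class TestSlabAveraging:
    def test_single_slice_identity(self, phantom):
        sl = kf.simulate_series(phantom, kf.smooth_kernel(), 1.0, seed=1)
        out = kf.make_thick_reference([sl], sl.thickness)
        assert np.array_equal(out.pixels, sl.pixels)

    @pytest.mark.parametrize("target,expect_n", [(5.0, 7), (1.5, 2), (2.0, 3)])
    def test_weights_sum_to_one_for_fractional_spans(self, target, expect_n):
        w = slab_weights(16, 0.75, target)
        assert len(w) == expect_n
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_averages_as_inverse_sqrt_k(self, rng):
        # k full slices of independent unit noise -> slab std ~ 1/sqrt(k)
        k = 4
        slices = [kf.CTImage(rng.standard_normal((64, 64)), spacing=1.0, thickness=1.0)
                  for _ in range(k)]
        slab = kf.make_thick_reference(slices, float(k))
        assert slab.pixels.std() == pytest.approx(1.0 / np.sqrt(k), rel=0.1)

    def test_interslice_correlation_solves_the_slab_calibration(self):
        rho = interslice_rho_for_slab(0.75, 5.0, 6.0, 3.2)
        w = slab_weights(16, 0.75, 5.0)
        lag = np.abs(np.arange(len(w))[:, None] - np.arange(len(w))[None, :])
        achieved = 6.0 * np.sqrt(w @ (rho ** lag) @ w)
        assert achieved == pytest.approx(3.2, rel=1e-6)

    def test_too_short_stack_is_rejected(self, phantom):
        sl = kf.simulate_series(phantom, kf.smooth_kernel(), 1.0, seed=1)
        with pytest.raises(ValueError):
            kf.make_thick_reference([sl, sl], 5.0)


class TestDataset:
    def test_examples_have_four_series_plus_truth_on_one_grid(self, small_dataset):
        examples, _ = small_dataset
        assert len(examples) == 3
        for ex in examples:
            assert len(ex.images()) == 5
            assert {im.shape for im in ex.images()} == {(512, 512)}
            assert ex.smooth_ld.dose == 0.25 and ex.smooth_rd.dose == 1.0

    def test_manifest_reload_reproduces_pixels_bit_exactly(self, small_dataset):
        examples, manifest = small_dataset
        reloaded, _ = kf.load_dataset(manifest)
        for a, b in zip(examples, reloaded):
            for im_a, im_b in zip(a.images(), b.images()):
                assert np.array_equal(im_a.pixels, im_b.pixels)

    def test_different_seeds_give_different_anatomy(self, default_spec):
        a, _ = kf.make_dataset(default_spec, n_slices=1, seed=1)
        b, _ = kf.make_dataset(default_spec, n_slices=1, seed=2)
        assert not np.array_equal(a[0].truth.pixels, b[0].truth.pixels)

    def test_ld_and_rd_share_the_same_anatomy(self, small_dataset):
        examples, _ = small_dataset
        ex = examples[0]
        # noise-free anatomy is common: correlation of LD and RD residual vs truth
        assert ex.smooth_ld.spacing == ex.smooth_rd.spacing
        diff = ex.smooth_ld.pixels - ex.smooth_rd.pixels
        assert np.abs(diff).mean() < 30  # differs only by noise, not anatomy
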