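import numpy as np
import pytest

import nucleoflux as nf
from nucleoflux.detect import DetectionParams, FWHM_FACTOR


def brute_force_otsu(image, nbins=256):
    """Independent oracle: exhaustive inter-class-variance maximization."""
    hist, edges = np.histogram(image.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    hist = hist.astype(float)
    best_t, best_v = None, -1.0
    for k in range(1, nbins):
        w0, w1 = hist[:k].sum(), hist[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:k] * centers[:k]).sum() / w0
        m1 = (hist[k:] * centers[k:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, centers[k - 1]
    return best_t


class TestMip:
    def test_single_slice_identity(self):
        arr = np.random.default_rng(0).uniform(0, 10, (1, 8, 8))
        assert np.array_equal(nf.max_intensity_projection(nf.ImageStack(arr)), arr[0])

    def test_single_bright_voxel(self):
        arr = np.zeros((5, 6, 7))
        arr[3, 2, 4] = 100.0
        mip = nf.max_intensity_projection(nf.ImageStack(arr))
        assert mip[2, 4] == 100.0
        assert (mip > 0).sum() == 1

    def test_projection_max_equals_stack_max(self, rendered_default):
        stack, _, _ = rendered_default
        assert nf.max_intensity_projection(stack).max() == stack.voxels.max()

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            nf.ImageStack(np.zeros((0, 4, 4)))


class TestOtsu:
    def test_bimodal_threshold_between_modes(self):
        img = np.array([[0.0] * 8, [10.0] * 8])
        t = nf.otsu_threshold(img)
        assert 0.0 < t < 10.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_8bit(self, seed):
        img = np.random.default_rng(seed).integers(0, 256, (40, 40)).astype(float)
        assert nf.otsu_threshold(img) == pytest.approx(brute_force_otsu(img), rel=1e-9)

    def test_shift_property(self):
        img = np.random.default_rng(3).integers(0, 200, (30, 30)).astype(float)
        assert nf.otsu_threshold(img + 17.0) == pytest.approx(
            nf.otsu_threshold(img) + 17.0, abs=1e-9
        )

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            nf.otsu_threshold(np.full((8, 8), 3.0))


class TestFitUnit:
    def test_noise_free_spot_recovers_fwhm(self, single_spot_stack):
        center, fwhm, chi2, bg, ok = nf.fit_unit(single_spot_stack, (32, 32, 10))
        assert ok
        assert fwhm == pytest.approx(FWHM_FACTOR * 1.3, rel=0.02)
        assert center[0] == pytest.approx(32.0, abs=0.05)
        assert center[1] == pytest.approx(32.0, abs=0.05)
        assert center[2] == pytest.approx(10.0, abs=0.2)
        assert chi2 == pytest.approx(0.0, abs=1e-9)

    def test_amplitude_scale_invariance(self, single_spot_stack):
        doubled = nf.ImageStack(single_spot_stack.voxels * 2.0, z_aspect=3.0)
        c1, f1, *_ = nf.fit_unit(single_spot_stack, (32, 32, 10))
        c2, f2, *_ = nf.fit_unit(doubled, (32, 32, 10))
        assert c1 == pytest.approx(c2, abs=1e-6)
        assert f1 == pytest.approx(f2, rel=1e-6)

    def test_out_of_bounds_seed_rejected(self, single_spot_stack):
        with pytest.raises(ValueError):
            nf.fit_unit(single_spot_stack, (100, 100, 10))


class TestIntegralIntensity:
    def test_single_voxel_sphere(self):
        arr = np.zeros((7, 9, 9))
        arr[3, 4, 4] = 50.0
        stack = nf.ImageStack(arr, z_aspect=3.0)
        v = nf.integral_intensity(stack, (4.0, 4.0, 3.0), 1.5)
        assert v == pytest.approx(50.0)

    def test_monotone_in_radius(self, rendered_default):
        _, _, records = rendered_default
        params = DetectionParams()
        for rec in records:
            vals = [rec.integral(r) for r in params.radii]
            assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_matches_numeric_gaussian_mass(self, single_spot_stack):
        measured = nf.integral_intensity(single_spot_stack, (32.0, 32.0, 10.0), 4.0)
        zz, yy, xx = np.mgrid[0:21, 0:64, 0:64]
        d = np.sqrt((xx - 32.0) ** 2 + (yy - 32.0) ** 2 + (3.0 * (zz - 10.0)) ** 2)
        oracle = single_spot_stack.voxels[d <= 4.0].sum()
        assert measured == pytest.approx(oracle, rel=0.05)

    def test_invalid_radius_and_outside_sphere(self, single_spot_stack):
        with pytest.raises(ValueError):
            nf.integral_intensity(single_spot_stack, (32, 32, 10), 0.0)
        with pytest.raises(ValueError):
            nf.integral_intensity(single_spot_stack, (500.0, 500.0, 10.0), 2.0)


class TestDetectUnits:
    def test_noise_free_scene_exact(self, rendered_noise_free, noise_free_scene):
        _, truth, records = rendered_noise_free
        assert len(records) == noise_free_scene.units_per_cell
        m = nf.match_to_ground_truth(records, truth, radius=1.0, z_aspect=3.0)
        assert m["n_matched"] == noise_free_scene.units_per_cell

    def test_noisy_scene_recall_precision(self, rendered_default):
        _, truth, records = rendered_default
        m = nf.match_to_ground_truth(records, truth, radius=2.0, z_aspect=3.0)
        assert m["recall"] >= 0.9
        assert m["precision"] >= 0.9

    def test_blank_stack_few_spurious(self, default_scene):
        stack, _ = nf.render_scene(default_scene, level=0.0, seed=13)
        assert len(nf.detect_units(stack)) <= 2

    def test_translation_equivariance(self):
        scene = nf.SceneConfig(
            shape=(11, 96, 96), units_per_cell=5, nucleoplasmic_foci=0,
            poisson_gain=0.0, read_noise_sd=0.0,
        )
        stack, _ = nf.render_scene(scene, level=1.0, seed=8)
        shifted = nf.ImageStack(np.roll(stack.voxels, (0, 4, 6), axis=(0, 1, 2)), 3.0)
        r1 = nf.detect_units(stack)
        r2 = nf.detect_units(shifted)
        assert len(r1) == len(r2)
        c1 = sorted((round(r.x, 1), round(r.y, 1)) for r in r1)
        c2 = sorted((round(r.x - 6, 1), round(r.y - 4, 1)) for r in r2)
        for (x1, y1), (x2, y2) in zip(c1, c2):
            assert abs(x1 - x2) <= 0.2 and abs(y1 - y2) <= 0.2

    def test_sorted_by_report_integral(self, rendered_default):
        _, _, records = rendered_default
        vals = [r.integral(1.5) for r in records]
        assert vals == sorted(vals, reverse=True)

    def test_records_to_frame_layout(self, rendered_default):
        _, _, records = rendered_default
        frame = nf.records_to_frame(records)
        assert "I_1.5" in frame.columns and "I_4.0" in frame.columns
        assert len(frame) == len(records)


class TestCountUnits:
    def test_empty(self):
        assert nf.count_units([]) == 0

    def test_threshold_filtering(self, rendered_default):
        _, _, records = rendered_default
        assert nf.count_units(records, 0.0) == len(records)
        huge = 10 * max(r.integral(1.5) for r in records)
        assert nf.count_units(records, huge) == 0


class TestLinearity:
    def test_mean_integral_linear_in_level(self, noise_free_scene):
        """Measured mean unit integral recovers planted ratios within 5%."""
        means = {}
        for lev in (0.5, 1.0, 1.5):
            stack, _ = nf.render_scene(noise_free_scene, level=lev, seed=17)
            rec = nf.detect_units(stack)
            means[lev] = np.mean([r.integral(1.5) for r in rec])
        assert means[1.0] / means[0.5] == pytest.approx(2.0, rel=0.05)
        assert means[1.5] / means[0.5] == pytest.approx(3.0, rel=0.05)
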