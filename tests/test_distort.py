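import itertools

import numpy as np
import pytest

from ecgpaper import distort, paper_render as pr
from ecgpaper.errors import ParameterError
from ecgpaper.paper_render import PaperImage


def brute_force_seam_cost(e: np.ndarray) -> float:
    """Exhaustive minimum over all 8-connected column-monotone paths."""
    n, m = e.shape
    best = np.inf
    for path in itertools.product(range(m), repeat=n):
        if all(abs(path[i] - path[i - 1]) <= 1 for i in range(1, n)):
            best = min(best, sum(e[i, path[i]] for i in range(n)))
    return best


@pytest.fixture()
def white():
    return PaperImage(np.full((120, 120, 3), 255, np.uint8), dpi=200)


class TestGaussianKernel:
    def test_normalized_and_symmetric_when_centered(self):
        k = distort.gaussian_kernel(2.0, 9, (0, 0))
        assert k.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(k, np.rot90(k), atol=1e-12)

    def test_large_sigma_near_uniform(self):
        k = distort.gaussian_kernel(50.0, 5)
        assert k.max() / k.min() < 1.05

    def test_offset_displaces_argmax(self):
        k = distort.gaussian_kernel(2.0, 9, (1, 0))
        r, c = np.unravel_index(k.argmax(), k.shape)
        assert (r, c) == (4, 5)

    def test_even_size_rejected(self):
        with pytest.raises(ParameterError):
            distort.gaussian_kernel(2.0, 8)


class TestCreases:
    def test_zero_creases_identity(self, white):
        out = distort.apply_creases(white, distort.CreaseSpec(n_creases=0))
        np.testing.assert_array_equal(out.pixels, white.pixels)

    def test_single_vertical_crease_dips_at_center(self, white):
        spec = distort.CreaseSpec(n_creases=1, angle_deg=90.0, sigma=1.5,
                                  kernel_size=7, intensity=0.5)
        out = distort.apply_creases(white, spec)
        prof = out.pixels[:, :, 0].mean(axis=0)
        assert abs(int(np.argmin(prof)) - 60) <= 1
        # untouched far from the line
        assert prof[0] == 255 and prof[-1] == 255

    def test_offset_kernel_asymmetric_profile(self, white):
        spec = distort.CreaseSpec(n_creases=1, angle_deg=90.0, sigma=2.0,
                                  kernel_size=11, kernel_offset=(3, 0),
                                  intensity=0.5)
        out = distort.apply_creases(white, spec)
        dark = 255.0 - out.pixels[:, :, 0].mean(axis=0)
        c = int(np.argmax(dark))
        left = dark[max(c - 8, 0):c].sum()
        right = dark[c + 1:c + 9].sum()
        assert abs(left - right) > 0.05 * (left + right)


class TestMinErrorBoundaryCut:
    def test_zero_surface_leftmost_path(self):
        path, cost = distort.min_error_boundary_cut(np.zeros((4, 3)))
        assert cost == 0.0
        np.testing.assert_array_equal(path, 0)

    def test_valley_column(self):
        e = np.array([[1, 0, 1], [1, 0, 1], [1, 0, 1]], float)
        path, cost = distort.min_error_boundary_cut(e)
        assert cost == 0.0
        np.testing.assert_array_equal(path, 1)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 7))
            m = int(rng.integers(1, 6))
            e = rng.integers(0, 10, (n, m)).astype(float)
            _, cost = distort.min_error_boundary_cut(e)
            assert cost == pytest.approx(brute_force_seam_cost(e))

    def test_path_is_8_connected(self):
        rng = np.random.default_rng(7)
        e = rng.random((20, 9))
        path, _ = distort.min_error_boundary_cut(e)
        assert np.all(np.abs(np.diff(path)) <= 1)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            distort.min_error_boundary_cut(np.empty((0, 3)))


class TestQuilting:
    def test_out_equals_patch_is_single_patch(self):
        tex = distort.wrinkle_seed_texture((96, 96), seed=1)
        spec = distort.QuiltSpec(seed_texture=tex, patch=48, overlap=8,
                                 out_size=(48, 48), seed=2)
        out = distort.quilt_texture(spec)
        # one unmodified 48x48 window of the seed texture
        found = any(
            np.array_equal(out, tex[r:r + 48, c:c + 48])
            for r in range(49) for c in range(49))
        assert found

    def test_constant_seed_gives_constant_output(self):
        spec = distort.QuiltSpec(seed_texture=np.full((64, 64), 7.0),
                                 patch=32, overlap=6, out_size=(80, 80),
                                 seed=0)
        out = distort.quilt_texture(spec)
        assert np.all(out == 7.0)

    def test_deterministic_per_seed(self):
        spec = lambda s: distort.QuiltSpec(out_size=(100, 100), seed=s)
        a = distort.quilt_texture(spec(5))
        b = distort.quilt_texture(spec(5))
        c = distort.quilt_texture(spec(6))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_chosen_seam_no_worse_than_midline(self):
        rng = np.random.default_rng(3)
        old = rng.uniform(0, 255, (40, 8))
        new = rng.uniform(0, 255, (40, 8))
        e = (old - new) ** 2
        path, cost = distort.min_error_boundary_cut(e)
        midline_cost = e[:, e.shape[1] // 2].sum()
        assert cost <= midline_cost

    def test_patch_larger_than_seed_rejected(self):
        with pytest.raises(ParameterError):
            distort.QuiltSpec(seed_texture=np.zeros((20, 20)), patch=48,
                              overlap=8)


class TestWrinkleBlend:
    def test_alpha_zero_identity(self, white):
        tex = distort.wrinkle_seed_texture((120, 120), 0)
        out = distort.apply_wrinkles(white, tex, 0.0)
        np.testing.assert_array_equal(out.pixels, white.pixels)

    def test_constant_texture_identity(self, white):
        out = distort.apply_wrinkles(white, np.full((120, 120), 42.0), 0.9)
        np.testing.assert_array_equal(out.pixels, white.pixels)

    def test_alpha_one_proportional_to_texture(self):
        base = PaperImage(np.full((64, 64, 3), 200, np.uint8), dpi=200)
        tex = distort.wrinkle_seed_texture((64, 64), 2)
        out = distort.apply_wrinkles(base, tex, 1.0)
        r = np.corrcoef(out.pixels[:, :, 0].ravel().astype(float),
                        tex.ravel())[0, 1]
        assert r > 0.99

    def test_alpha_out_of_range(self, white):
        with pytest.raises(ParameterError):
            distort.apply_wrinkles(white, np.ones((120, 120)), 1.5)


class TestProjective:
    def test_identity_matrix(self, page):
        img, truth = page
        out, gt = distort.projective_transform(
            img, truth, distort.ProjectiveSpec(np.eye(3)))
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1)
        np.testing.assert_allclose(gt.segments[0].rows,
                                   truth.segments[0].rows, atol=1e-9)

    def test_translation_shifts_polylines_exactly(self, page):
        img, truth = page
        m = np.array([[1, 0, 12.0], [0, 1, -7.0], [0, 0, 1]])
        _, gt = distort.projective_transform(img, truth,
                                             distort.ProjectiveSpec(m))
        np.testing.assert_allclose(
            gt.segments[0].cols, truth.segments[0].cols + 12.0)
        np.testing.assert_allclose(
            gt.segments[0].rows, truth.segments[0].rows - 7.0)

    def test_perspective_matches_manual_homogeneous_math(self):
        m = np.array([[1.01, 0.02, 3.0],
                      [-0.01, 0.99, -2.0],
                      [0.0005, 0.0, 1.0]])
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 80.0], [100.0, 80.0]])
        from ecgpaper.paper_render import GroundTruth, SegmentTruth
        seg = SegmentTruth("X", 0, 1, pts[:, 0], pts[:, 1], 0, 1.0, 1.0)
        gt = GroundTruth(segments=[seg]).transform_points(m)
        for (x, y), cx, cy in zip(pts, gt.segments[0].cols,
                                  gt.segments[0].rows):
            xh = m @ np.array([x, y, 1.0])
            assert cx == pytest.approx(xh[0] / xh[2], abs=1e-6)
            assert cy == pytest.approx(xh[1] / xh[2], abs=1e-6)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ParameterError):
            distort.ProjectiveSpec(np.zeros((3, 3)))


class TestImagingNoise:
    def test_zero_levels_identity(self, white):
        out = distort.add_gaussian_noise(white, 0.0, 0)
        out = distort.add_poisson_noise(out, 0.0, 0)
        out = distort.add_salt_pepper(out, 0.0, 0)
        np.testing.assert_array_equal(out.pixels, white.pixels)

    def test_salt_pepper_extreme_density(self):
        img = PaperImage(np.full((1000, 1000, 3), 128, np.uint8), dpi=72)
        out = distort.add_salt_pepper(img, 1.0, seed=0)
        vals = np.unique(out.pixels)
        assert set(vals.tolist()) <= {0, 255}
        frac0 = float(np.mean(out.pixels[:, :, 0] == 0))
        sigma = np.sqrt(0.25 / 1e6)
        assert abs(frac0 - 0.5) < 3 * sigma

    def test_salt_pepper_channels_jointly(self):
        img = PaperImage(np.full((200, 200, 3), 128, np.uint8), dpi=72)
        out = distort.add_salt_pepper(img, 0.3, seed=1)
        extreme = (out.pixels == 0) | (out.pixels == 255)
        assert np.array_equal(extreme[:, :, 0], extreme[:, :, 1])
        assert np.array_equal(extreme[:, :, 0], extreme[:, :, 2])

    def test_gaussian_std_on_midgray(self):
        img = PaperImage(np.full((600, 600, 3), 128, np.uint8), dpi=72)
        out = distort.add_gaussian_noise(img, 10.0, seed=3)
        assert out.pixels.astype(float).std() == pytest.approx(10.0, rel=0.02)

    def test_poisson_clipped_and_nonnegative_shift(self):
        img = PaperImage(np.full((100, 100, 3), 250, np.uint8), dpi=72)
        out = distort.add_poisson_noise(img, 20.0, seed=4)
        assert out.pixels.max() <= 255
        assert out.pixels.astype(float).mean() >= 250.0


class TestColorTemperature:
    def test_identity_at_6600(self):
        img = PaperImage(np.full((50, 50, 3), 128, np.uint8), dpi=72)
        out = distort.apply_color_temperature(img, 6600.0)
        shifts = np.abs(out.pixels.astype(float) - 128).mean(axis=(0, 1))
        assert np.all(shifts < 2.0)

    def test_orange_and_blue_tinges(self):
        img = PaperImage(np.full((50, 50, 3), 128, np.uint8), dpi=72)
        cold = distort.apply_color_temperature(img, 1000.0).pixels
        warm = distort.apply_color_temperature(img, 40000.0).pixels
        assert cold[:, :, 0].mean() > cold[:, :, 2].mean()
        assert warm[:, :, 2].mean() > warm[:, :, 0].mean()

    def test_red_minus_blue_monotone_in_kelvin(self):
        img = PaperImage(np.full((20, 20, 3), 128, np.uint8), dpi=72)
        diffs = []
        for k in (1000, 2500, 5000, 6600, 12000, 25000, 40000):
            px = distort.apply_color_temperature(img, k).pixels.astype(float)
            diffs.append(px[:, :, 0].mean() - px[:, :, 2].mean())
        assert np.all(np.diff(diffs) < 1e-9)

    def test_out_of_range_rejected(self):
        img = PaperImage(np.full((10, 10, 3), 128, np.uint8), dpi=72)
        with pytest.raises(ParameterError):
            distort.apply_color_temperature(img, 500.0)


class TestDistortionProfiles:
    def test_clean_profile_is_identity(self, white):
        out, _ = distort.apply_distortion_profile(white, None, "clean")
        np.testing.assert_array_equal(out.pixels, white.pixels)

    def test_scanner_profile_applies_and_logs(self, page):
        img, truth = page
        out, gt = distort.apply_distortion_profile(img, truth, "scanner",
                                                   seed=1)
        ops = [op for op, _ in out.provenance]
        for expected in ("apply_creases", "apply_wrinkles",
                         "apply_color_temperature", "add_gaussian_noise"):
            assert expected in ops
        assert gt is truth          # no geometric ops in this profile

    def test_yaml_profile_round_trip(self, white, tmp_path):
        cfg = tmp_path / "profile.yaml"
        cfg.write_text("creases:\n  n_creases: 1\n  angle_deg: 90\n"
                       "  sigma: 1.5\n  kernel_size: 7\n  intensity: 0.4\n")
        out, _ = distort.apply_distortion_profile(
            white, None, distort.load_distortion_profile(str(cfg)))
        assert [op for op, _ in out.provenance] == ["apply_creases"]
        assert (out.pixels != white.pixels).any()
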