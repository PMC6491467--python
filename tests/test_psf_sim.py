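"""Simulator physics: diffraction limit, binning, rendering, reproducibility."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from psfdecode import psf_sim as ps
from psfdecode.config import ConfigurationError, GridConfig, OpticalConfig

MATCHED = OpticalConfig(sample_index=1.51, particle_depth_um=0.0)


def fit_gaussian_width_nm(image: np.ndarray, pixel_nm: float = 100.0) -> float:
    """Isotropic Gaussian LSQ fit; returns 2*sigma in nm."""
    n = image.shape[0]
    c = (np.arange(n) + 0.5 - n / 2) * pixel_nm
    X, Y = np.meshgrid(c, c)

    def g(xy, a, x0, y0, s, off):
        X, Y = xy
        return (a * np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2 * s**2)) + off).ravel()

    p, _ = curve_fit(
        g, (X, Y), image.ravel(),
        p0=[image.max(), 0, 0, 150.0, float(image.min())], maxfev=5000,
    )
    return 2.0 * abs(p[3])


class TestDiffractionLimit:
    def test_matched_index_profile_matches_airy(self):
        """In the matched-index, in-focus limit the integral is the Airy pattern."""
        r = np.linspace(0.0, 700.0, 1401)  # covers the central three lobes
        profile = ps.radial_intensity_profile(MATCHED, 0.0, r)
        profile /= profile[0]
        airy = ps.airy_intensity(MATCHED, r)
        assert np.max(np.abs(profile - airy)) < 0.01

    def test_first_zero_at_rayleigh_radius(self):
        expected = 0.61 * MATCHED.emission_wavelength_nm / MATCHED.numerical_aperture
        r = np.linspace(150.0, 350.0, 2001)
        profile = ps.radial_intensity_profile(MATCHED, 0.0, r)
        first_zero = r[int(np.argmin(profile))]
        assert abs(first_zero - expected) / expected < 0.02

    def test_in_focus_center_is_global_maximum(self, grid):
        stack = ps.generate_psf_stack(MATCHED, GridConfig(z_range_nm=100.0))
        iz, iy, ix = np.unravel_index(np.argmax(stack.values), stack.values.shape)
        n = stack.values.shape[1]
        assert stack.z_positions_nm[iz] == 0.0
        assert abs(iy - (n - 1) / 2) <= 1 and abs(ix - (n - 1) / 2) <= 1
        assert stack.values.max() == 1.0  # peak normalization


class TestStackGeneration:
    def test_slice_count_and_z_grid(self, fine_stacks):
        stack = fine_stacks[600]
        assert stack.n_slices == 61
        assert stack.z_positions_nm[0] == -600.0 and stack.z_positions_nm[-1] == 600.0
        np.testing.assert_allclose(np.diff(stack.z_positions_nm), 20.0)

    def test_nonnegative_and_finite(self, fine_stacks):
        for stack in fine_stacks.values():
            assert np.all(stack.values >= 0)
            assert np.all(np.isfinite(stack.values))

    def test_longer_wavelength_is_wider(self, detector_stacks):
        """PSF size scales with emission wavelength (the color signature)."""
        w600 = fit_gaussian_width_nm(detector_stacks[600].slice_at(0.0))
        w700 = fit_gaussian_width_nm(detector_stacks[700].slice_at(0.0))
        assert w700 > w600
        # proportionality: ratio close to 700/600
        assert w700 / w600 == pytest.approx(700.0 / 600.0, rel=0.05)

    def test_on_axis_psf_reflection_symmetric(self, detector_stacks):
        for z in (0.0, 200.0, -200.0):
            img = detector_stacks[700].slice_at(z)
            np.testing.assert_allclose(img, img[::-1, :], rtol=1e-8, atol=1e-12)
            np.testing.assert_allclose(img, img[:, ::-1], rtol=1e-8, atol=1e-12)

    def test_defocus_broadens_psf(self, detector_stacks):
        for sign in (+1, -1):
            widths = [
                fit_gaussian_width_nm(detector_stacks[600].slice_at(sign * z))
                for z in (0.0, 100.0, 200.0, 300.0, 400.0)
            ]
            assert np.all(np.diff(widths) > -2.0)  # nondecreasing within fit noise

    def test_index_mismatch_breaks_axial_symmetry(self, detector_stacks):
        """Depth-induced spherical aberration distinguishes +z from -z."""
        a = detector_stacks[700].slice_at(250.0)
        b = detector_stacks[700].slice_at(-250.0)
        assert np.linalg.norm(a - b) / np.linalg.norm(a) > 0.05


class TestDownsampling:
    def test_flux_conserved_over_covered_region(self, fine_stacks, grid):
        stack = fine_stacks[600]
        binned = ps.downsample_to_detector(stack, grid)
        b = grid.binning_factor
        ny = binned.values.shape[1] * b
        covered = stack.values[:, :ny, :ny].sum(axis=(1, 2))
        np.testing.assert_allclose(
            binned.values.sum(axis=(1, 2)), covered, rtol=1e-10
        )

    def test_binning_matches_explicit_loop(self):
        rng = np.random.default_rng(0)
        values = rng.random((3, 40, 40))
        stack = ps.PSFStack(values, [-20.0, 0.0, 20.0], 5.0, 600.0)
        binned = ps.downsample_to_detector(stack, GridConfig())
        for iz in range(3):
            for iy in range(2):
                for ix in range(2):
                    expected = sum(
                        values[iz, iy * 20 + a, ix * 20 + b]
                        for a in range(20)
                        for b in range(20)
                    )
                    assert binned.values[iz, iy, ix] == pytest.approx(
                        expected, rel=1e-12
                    )

    def test_constant_field_scales_by_binning_area(self):
        stack = ps.PSFStack(np.full((3, 60, 60), 2.5), [-20, 0, 20], 5.0, 600.0)
        binned = ps.downsample_to_detector(stack, GridConfig())
        assert binned.values.shape == (3, 3, 3)
        np.testing.assert_allclose(binned.values, 2.5 * 400)

    def test_output_dimensions_floor(self):
        stack = ps.PSFStack(np.ones((2, 510, 505)), [0, 20], 5.0, 600.0)
        binned = ps.downsample_to_detector(stack, GridConfig())
        assert binned.values.shape == (2, 25, 25)

    def test_non_integer_binning_rejected(self):
        stack = ps.PSFStack(np.ones((2, 50, 50)), [0, 20], 7.0, 600.0)
        with pytest.raises(ConfigurationError):
            ps.downsample_to_detector(stack, GridConfig())


class TestRendering:
    def test_zero_photons_zero_background_gives_zeros(self, fine_stacks, grid):
        truth = ps.EmitterTruth(photons=0.0, background=0.0)
        img, _ = ps.render_molecule_image(fine_stacks[600], truth, grid, 42)
        assert np.all(img == 0)

    def test_expected_roi_sum_is_photons_plus_background(self, fine_stacks, grid):
        truth = ps.EmitterTruth(z_nm=140.0, photons=5000.0, background=10.0)
        expected = ps.expected_molecule_image(fine_stacks[600], truth, grid)
        roi = expected[: grid.roi_size_px, : grid.roi_size_px]
        assert roi.sum() == pytest.approx(5000.0 + 10.0 * grid.roi_size_px**2)

    def test_poisson_mean_variance_identity(self, fine_stacks, grid):
        truth = ps.EmitterTruth(z_nm=100.0, photons=5000.0, background=10.0)
        expected = ps.expected_molecule_image(fine_stacks[600], truth, grid)
        rng = np.random.default_rng(5)
        draws = rng.poisson(expected, size=(10000, *expected.shape))
        bright = expected > 20.0  # enough counts for a stable variance estimate
        mean = draws.mean(axis=0)[bright]
        var = draws.var(axis=0)[bright]
        assert np.max(np.abs(var - mean) / mean) < 0.05

    def test_same_seed_same_image(self, fine_stacks, grid):
        truth = ps.EmitterTruth(z_nm=-200.0, photons=3000.0, background=10.0)
        img1, _ = ps.render_molecule_image(fine_stacks[600], truth, grid, 7)
        img2, _ = ps.render_molecule_image(fine_stacks[600], truth, grid, 7)
        np.testing.assert_array_equal(img1, img2)

    def test_z_outside_stack_range_rejected(self, fine_stacks, grid):
        truth = ps.EmitterTruth(z_nm=700.0)
        with pytest.raises(ValueError, match="outside"):
            ps.expected_molecule_image(fine_stacks[600], truth, grid)


class TestBenchmarkDataset:
    def test_counts_and_labels(self, optics, grid, fine_stacks):
        ds = ps.generate_benchmark_dataset(
            [optics[600], optics[700]], grid, 20, rng_seed=1,
            stacks=[fine_stacks[600], fine_stacks[700]],
        )
        assert len(ds) == 40
        labels = [t.color_label for _, t in ds]
        assert labels.count(0) == 20 and labels.count(1) == 20
        for img, _ in ds:
            assert img.shape == (grid.patch_size_px, grid.patch_size_px)

    def test_seeded_reproducibility(self, optics, grid, fine_stacks):
        kwargs = dict(
            grid=grid, n_per_color=10, rng_seed=3,
            stacks=[fine_stacks[600], fine_stacks[700]],
        )
        ds1 = ps.generate_benchmark_dataset([optics[600], optics[700]], **kwargs)
        ds2 = ps.generate_benchmark_dataset([optics[600], optics[700]], **kwargs)
        for (a, ta), (b, tb) in zip(ds1, ds2):
            np.testing.assert_array_equal(a, b)
            assert ta == tb

    def test_empty_color_set_rejected(self, grid):
        with pytest.raises(ConfigurationError):
            ps.generate_benchmark_dataset([], grid, 10)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(numerical_aperture=-1.0),
            dict(numerical_aperture=1.6, immersion_index=1.51),
            dict(sample_index=0.5),
            dict(emission_wavelength_nm=1200.0),
        ],
    )
    def test_bad_optics_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            OpticalConfig(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(pixel_size_nm=102.0),
            dict(z_range_nm=610.0),
            dict(patch_size_px=12),
            dict(roi_size_px=10),
        ],
    )
    def test_bad_grid_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            GridConfig(**kwargs)

    def test_negative_photons_rejected(self):
        with pytest.raises(ValueError):
            ps.EmitterTruth(photons=-1.0)
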