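"""Physics of image formation: Langevin PSF, signal synthesis, blur, noise."""

import numpy as np
import pytest
from scipy.optimize import brentq

from mpi_deblur.forward_model import (
    ConfigurationError,
    DomainError,
    SimulationParams,
    add_noise,
    blur,
    build_psf,
    langevin,
    langevin_derivative,
    simulate_signal,
    synth_noise_field,
    total_magnetization,
)


class TestLangevin:
    def test_zero_limit(self):
        assert langevin(0.0) == 0.0

    def test_odd_symmetry_exact(self):
        for xi in [1e-6, 1e-3, 0.5, 1.0, 5.0, 50.0]:
            assert langevin(-xi) == -langevin(xi)

    def test_high_precision_value_at_one(self):
        # independent oracle: 50-digit evaluation of coth(1) - 1
        import sympy

        exact = float(sympy.coth(1) - 1)
        assert langevin(1.0) == pytest.approx(exact, abs=1e-12)

    def test_range_open_interval(self, rng):
        xi = rng.uniform(-500, 500, size=200)
        out = langevin(xi)
        assert np.all(np.abs(out) < 1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(DomainError):
            langevin(np.nan)
        with pytest.raises(DomainError):
            langevin_derivative(np.inf)

    def test_series_branch_accuracy(self):
        # the small-|xi| series agrees with a high-precision evaluation
        import sympy

        xi = 0.005  # inside the series branch
        exact = float(sympy.N(sympy.coth(sympy.Rational(1, 200)) - 200, 30))
        assert langevin(xi) == pytest.approx(exact, rel=1e-10)
        exact_d = float(sympy.N(200**2 - sympy.csch(sympy.Rational(1, 200)) ** 2, 30))
        assert langevin_derivative(xi) == pytest.approx(exact_d, rel=1e-10)


class TestLangevinDerivative:
    def test_zero_limit_is_one_third(self):
        assert langevin_derivative(0.0) == pytest.approx(1.0 / 3.0, abs=1e-15)

    def test_even_symmetry_exact(self):
        for xi in [1e-4, 0.3, 1.0, 10.0]:
            assert langevin_derivative(-xi) == langevin_derivative(xi)

    @pytest.mark.parametrize("xi", [0.5, 1.0, 2.0])
    def test_matches_finite_difference_of_langevin(self, xi):
        h = 1e-6
        fd = (langevin(xi + h) - langevin(xi - h)) / (2 * h)
        assert langevin_derivative(xi) == pytest.approx(fd, abs=1e-6)

    def test_positive_and_monotone_decreasing(self):
        xi = np.linspace(0, 30, 400)
        vals = langevin_derivative(xi)
        assert np.all(vals > 0)
        assert np.all(np.diff(vals) < 1e-15)


class TestSimulationParams:
    def test_published_defaults(self):
        p = SimulationParams()
        assert p.mu0 == pytest.approx(4e-7 * np.pi)
        assert p.particle_diameter_nm == 20.0
        assert p.temperature_k == 293.0
        assert p.boltzmann_k == 1.28e-23
        assert p.magnetic_moment == 6.75e-18
        assert p.gradient == 6.0
        assert p.snr_db_range == (5.0, 15.0)

    def test_validation(self):
        with pytest.raises(ConfigurationError):
            SimulationParams(gradient=-1.0)
        with pytest.raises(ConfigurationError):
            SimulationParams(snr_db_range=(15.0, 5.0))


class TestPsf:
    def test_normalized_symmetric_unimodal(self, psf):
        v = psf.values
        assert v.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(v, np.rot90(v, 2), atol=0)
        center = (v.shape[0] // 2, v.shape[1] // 2)
        assert np.argmax(v) == np.ravel_multi_index(center, v.shape)
        assert np.sum(v == v.max()) == 1

    def test_invariants_hold_across_parameter_variations(self):
        for g, hsat in [(3.0, 1.6e-5), (6.0, 8e-6), (12.0, 3e-5)]:
            p = SimulationParams(gradient=g, h_sat=hsat)
            k = build_psf(p, fov_mm=24.0, grid_px=31)
            assert k.values.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(k.values, np.rot90(k.values, 2))

    def test_doubling_gradient_halves_fwhm(self, params):
        fine = dict(fov_mm=33.6, grid_px=501)
        f1 = build_psf(params, **fine).fwhm_mm()
        f2 = build_psf(SimulationParams(gradient=12.0), **fine).fwhm_mm()
        assert f2 == pytest.approx(f1 / 2, rel=0.02)

    def test_fwhm_matches_bisection_oracle(self, params):
        # oracle: xi_half solves L'(xi) = 1/6 on [1, 5]
        xi_half = brentq(lambda x: langevin_derivative(x) - 1.0 / 6.0, 1.0, 5.0, xtol=1e-10)
        expected_mm = 2.0 * xi_half / params.xi_per_mm
        measured = build_psf(params, fov_mm=33.6, grid_px=501).fwhm_mm()
        assert measured == pytest.approx(expected_mm, rel=1e-3)

    def test_resolution_inverse_in_gradient(self):
        fwhms = {}
        for g in (3.0, 6.0, 12.0):
            k = build_psf(SimulationParams(gradient=g), fov_mm=40.0, grid_px=801)
            fwhms[g] = k.fwhm_mm()
        products = [g * f for g, f in fwhms.items()]
        assert max(products) / min(products) == pytest.approx(1.0, rel=0.02)

    def test_grid_validation(self, params):
        with pytest.raises(ConfigurationError):
            build_psf(params, fov_mm=10.0, grid_px=4)
        with pytest.raises(ConfigurationError):
            build_psf(params, fov_mm=-1.0, grid_px=5)


class TestBlur:
    def test_delta_reproduces_psf(self, psf):
        img = np.zeros((50, 50))
        img[25, 25] = 1.0
        out = blur(img, psf)
        k = psf.values
        assert np.allclose(out[25 - 10 : 25 + 11, 25 - 10 : 25 + 11], k, atol=1e-12)

    def test_uniform_invariance_in_interior(self, psf):
        out = blur(np.ones((50, 50)), psf)
        interior = out[10:-10, 10:-10]
        assert interior.max() - interior.min() < 1e-9

    def test_matches_bruteforce_convolution(self, rng):
        image = rng.random((9, 9))
        kernel = rng.random((3, 3))
        kernel /= kernel.sum()

        # brute-force true convolution with symmetric padding
        padded = np.pad(image, 1, mode="symmetric")
        expected = np.zeros_like(image)
        for i in range(9):
            for j in range(9):
                acc = 0.0
                for a in range(3):
                    for b in range(3):
                        acc += kernel[a, b] * padded[i + (2 - a), j + (2 - b)]
                expected[i, j] = acc

        from mpi_deblur.forward_model import PsfKernel, SimulationParams

        out = blur(image, PsfKernel(kernel, 1.0, SimulationParams()))
        assert np.allclose(out, expected, atol=1e-12)

    def test_linearity(self, psf, rng):
        x = rng.random((50, 50))
        y = rng.random((50, 50))
        lhs = blur(2.0 * x + 3.0 * y, psf)
        rhs = 2.0 * blur(x, psf) + 3.0 * blur(y, psf)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_intensity_conservation_interior_feature(self, psf):
        img = np.zeros((50, 50))
        img[20:30, 20:30] = 1.0  # ~2 FWHM from every border
        out = blur(img, psf)
        assert out.sum() == pytest.approx(img.sum(), rel=0.01)
        assert np.all(out >= 0)

    def test_oversized_kernel_rejected(self, params):
        big = build_psf(params, fov_mm=48.0, grid_px=61)
        with pytest.raises(ValueError, match="fit"):
            blur(np.ones((50, 50)), big)


class TestAddNoise:
    def test_realized_snr_exact(self, rng):
        image = rng.random((50, 50)) + 0.1
        field = synth_noise_field((50, 50), 0.0, 7)
        out = add_noise(image, 10.0, field)
        noise = out.values - image
        measured = 10 * np.log10(np.mean(image**2) / np.mean(noise**2))
        assert measured == pytest.approx(10.0, abs=1e-9)
        assert out.realized_snr_db == pytest.approx(10.0, abs=1e-9)

    def test_infinite_snr_is_identity(self, rng):
        image = rng.random((20, 20))
        out = add_noise(image, np.inf, synth_noise_field((20, 20), 0.0, 7))
        assert np.array_equal(out.values, image)

    def test_power_ratio_between_5_and_15_db(self, rng):
        image = rng.random((40, 40)) + 0.2
        field = synth_noise_field((40, 40), 1.0, 3)
        n5 = add_noise(image, 5.0, field).values - image
        n15 = add_noise(image, 15.0, field).values - image
        ratio = np.mean(n5**2) / np.mean(n15**2)
        assert ratio == pytest.approx(10.0, abs=1e-9)

    def test_zero_power_image_rejected(self):
        with pytest.raises(ValueError, match="zero power"):
            add_noise(np.zeros((10, 10)), 10.0, np.ones((10, 10)))


class TestNoiseField:
    def test_deterministic_per_seed(self):
        a = synth_noise_field((30, 30), 2.0, 42)
        b = synth_noise_field((30, 30), 2.0, 42)
        assert np.array_equal(a, b)

    def test_zero_mean(self):
        field = synth_noise_field((100, 100), 0.0, 9)
        assert abs(field.mean()) < 5 * field.std() / 100

    def test_correlation_increases_with_smoothing(self):
        def lag1(f):
            return float(np.mean(f[:, :-1] * f[:, 1:]) / np.mean(f**2))

        acs = [lag1(synth_noise_field((80, 80), c, 11)) for c in (0.0, 1.0, 3.0)]
        assert acs[0] < acs[1] < acs[2]

    def test_negative_correlation_rejected(self):
        with pytest.raises(ValueError):
            synth_noise_field((10, 10), -1.0, 0)


class TestSignal:
    def test_zero_phantom_zero_signal(self, params):
        trace = simulate_signal(np.zeros(50), params, 20.0, 64)
        assert np.all(trace.values == 0)

    def test_impulse_peak_at_ffp_crossing(self, params):
        rho = np.zeros(51)
        rho[25] = 1.0
        trace = simulate_signal(rho, params, 20.0, 501)
        peak = np.argmax(np.abs(trace.values))
        nearest = np.argmin(np.abs(trace.ffp_positions_mm))
        assert abs(int(peak) - int(nearest)) <= 1

    def test_symmetric_pair_gives_antisymmetric_signal(self, params):
        rho = np.zeros(51)
        rho[15] = 1.0
        rho[35] = 1.0
        n = 401
        trace = simulate_signal(rho, params, 20.0, n)
        s = trace.values
        scale = np.abs(s).max()
        assert np.allclose(s, -s[::-1], atol=1e-9 * scale)

    def test_trapezoid_integral_recovers_magnetization_change(self, params):
        rho = np.zeros(51)
        rho[20:30] = 1.0
        n = 2001
        trace = simulate_signal(rho, params, 20.0, n)
        m = total_magnetization(rho, params, trace.ffp_positions_mm)
        half = n // 2  # integrate over the first half-period (monotone sweep)
        integral = np.trapezoid(trace.values[: half + 1], trace.times[: half + 1])
        change = m[half] - m[0]
        assert integral == pytest.approx(change, rel=0.01)

    def test_small_sample_count_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_signal(np.ones(10), params, 10.0, 8)
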