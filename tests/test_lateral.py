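"""Radial grids, angular-to-radial conversion and beam convolution."""

import numpy as np
import pytest

from protonboltz.angular import AngularDist, build_theta_grid
from protonboltz.lateral import (
    RadialDist,
    angular_to_radial,
    build_radial_grid,
    delta_radial,
    fourier_radial_profile,
    gaussian_beam_convolve,
    interpolate_radial,
    mean_radius_update,
)


class TestRadialGrid:
    def test_nodes_solve_defining_equation(self):
        r = build_radial_grid(sigma=0.5, rmax=2.0, dy=0.025)
        # sigma-scaled section: 1 - dy*(i-1) = exp(-r^2/2 sigma^2)
        for i in range(1, 30):
            assert 1.0 - 0.025 * i == pytest.approx(
                np.exp(-r[i] ** 2 / (2 * 0.25)), abs=1e-12)

    def test_uniform_extension(self):
        r = build_radial_grid(sigma=0.5, rmax=2.0)
        d = np.diff(r)
        assert r[0] == 0.0
        assert r[-1] >= 2.0 - d[-1]
        assert np.allclose(d[-4:], d[-1], rtol=1e-9)


class TestMeanRadius:
    def test_zero_angle_stays_on_axis(self):
        rho = 0.0
        for i in range(5):
            rho = mean_radius_update(rho, 0.0, 0.0, float(i), float(i + 1))
        assert rho == 0.0

    def test_first_step_half_tangent(self):
        rho = mean_radius_update(0.0, 0.0, 0.02, 0.0, 1.5)
        assert rho == pytest.approx(0.5 * np.tan(0.02) * 1.5)

    def test_constant_angle_closed_form(self):
        theta = 0.03
        rho, z = 0.0, 0.0
        rho = mean_radius_update(rho, 0.0, theta, 0.0, 1.0)
        for i in range(1, 10):
            rho = mean_radius_update(rho, theta, theta, float(i), float(i + 1))
        # telescoping sum: half-step start plus constant-angle drift
        assert rho == pytest.approx(np.tan(theta) * 9.5, rel=1e-12)

    def test_decreasing_depths_raise(self):
        with pytest.raises(ValueError):
            mean_radius_update(0.0, 0.0, 0.01, 2.0, 1.0)


@pytest.fixture()
def gauss_angular():
    theta = build_theta_grid()
    sig = 0.02
    phi = np.exp(-theta**2 / (2 * sig**2)) / (2 * np.pi * sig**2)
    return AngularDist(z=5.0, theta=theta, phi=phi)


class TestAngularToRadial:
    def test_scaling_identity(self, gauss_angular):
        tb, rb = gauss_angular.theta_bar, 0.3
        r = np.linspace(0.0, 2.0, 400)
        rad = angular_to_radial(gauss_angular, tb, rb, r, fluence=1.0)
        # shape property: the profile at rho and the angular density at
        # theta_bar*rho/rho_bar agree up to one global normalization
        ref = np.interp(tb * r / rb, gauss_angular.theta, gauss_angular.phi,
                        left=gauss_angular.phi[0], right=0.0)
        sel = ref > 1e-3 * ref.max()
        ratio = rad.phi[sel] / ref[sel]
        assert np.allclose(ratio, ratio[0], rtol=1e-9)

    def test_renormalized_to_fluence(self, gauss_angular):
        r = np.linspace(0.0, 2.0, 800)
        rad = angular_to_radial(gauss_angular, gauss_angular.theta_bar, 0.25,
                                r, fluence=0.8)
        assert rad.plane_integral() == pytest.approx(0.8, rel=0.01)

    def test_entrance_delta(self, gauss_angular):
        r = np.linspace(0.0, 2.0, 100)
        rad = angular_to_radial(gauss_angular, 0.0, 0.0, r)
        assert rad.is_delta


class TestInterpolateRadial:
    def _pair(self):
        r = np.linspace(0.0, 2.0, 200)
        lo = RadialDist(z=1.0, r=r, phi=np.exp(-r**2), fluence=1.0)
        hi = RadialDist(z=2.0, r=r, phi=0.5 * np.exp(-r**2 / 4), fluence=0.9)
        return lo, hi

    def test_endpoints(self):
        lo, hi = self._pair()
        assert np.allclose(interpolate_radial(1.0, lo, hi).phi, lo.phi)
        assert np.allclose(interpolate_radial(2.0, lo, hi).phi, hi.phi)

    def test_midpoint_is_mean(self):
        lo, hi = self._pair()
        mid = interpolate_radial(1.5, lo, hi)
        assert np.allclose(mid.phi, 0.5 * (lo.phi + hi.phi))

    def test_convexity(self):
        lo, hi = self._pair()
        mid = interpolate_radial(1.3, lo, hi)
        assert np.all(mid.phi >= 0)
        assert min(lo.plane_integral(), hi.plane_integral()) - 1e-9 \
            <= mid.plane_integral() \
            <= max(lo.plane_integral(), hi.plane_integral()) + 1e-9

    def test_bracket_violation(self):
        lo, hi = self._pair()
        with pytest.raises(ValueError):
            interpolate_radial(0.5, lo, hi)


class TestGaussianBeamConvolve:
    def test_delta_pencil_reproduces_source(self):
        r = np.linspace(0.0, 2.5, 300)
        out = gaussian_beam_convolve(delta_radial(r), 0.5)
        ref = np.exp(-r**2 / 0.5) / (2 * np.pi * 0.25)
        assert np.allclose(out.phi, ref, rtol=1e-9)

    def test_narrow_source_reproduces_pencil(self):
        """A source much narrower than the pencil barely changes it."""
        r = np.linspace(0.0, 3.0, 400)
        s2 = 0.36
        phi = np.exp(-r**2 / (2 * s2)) / (2 * np.pi * s2)
        pencil = RadialDist(z=5.0, r=r, phi=phi, fluence=1.0)
        sig = 0.1
        out = gaussian_beam_convolve(pencil, sig)
        sel = r < 1.5
        # exact: the analytically widened Gaussian; the widening itself is
        # bounded by the small variance ratio
        ref = np.exp(-r**2 / (2 * (s2 + sig**2))) / (2 * np.pi * (s2 + sig**2))
        assert np.allclose(out.phi[sel], ref[sel], rtol=1e-3)
        assert np.allclose(out.phi[sel], phi[sel], rtol=0.07)

    def test_against_cartesian_sum_oracle(self):
        """Quadrature convolution matches a direct 2-D Cartesian sum."""
        r = np.linspace(0.0, 3.0, 240)
        s2 = 0.09
        phi = np.exp(-r**2 / (2 * s2)) / (2 * np.pi * s2) \
            + 0.05 * np.exp(-r / 0.8)
        norm = 2 * np.pi * np.trapezoid(phi * r, r)
        phi = phi / norm
        pencil = RadialDist(z=5.0, r=r, phi=phi, fluence=1.0)
        sig = 0.5
        out = gaussian_beam_convolve(pencil, sig)
        # oracle: brute-force sum on a Cartesian grid
        ax = np.linspace(-3.0, 3.0, 601)
        xx, yy = np.meshgrid(ax, ax)
        rr = np.sqrt(xx**2 + yy**2)
        src = np.interp(rr, r, phi, right=0.0)
        cell = (ax[1] - ax[0]) ** 2
        for r0 in (0.0, 0.4, 1.0):
            g = np.exp(-((xx - r0) ** 2 + yy**2) / (2 * sig**2)) \
                / (2 * np.pi * sig**2)
            ref = np.sum(src * g) * cell
            got = np.interp(r0, out.r, out.phi)
            assert got == pytest.approx(ref, rel=0.01)

    def test_variance_additivity(self):
        r = np.linspace(0.0, 4.0, 500)
        s2 = 0.16
        phi = np.exp(-r**2 / (2 * s2)) / (2 * np.pi * s2)
        pencil = RadialDist(z=5.0, r=r, phi=phi, fluence=1.0)
        sig = 0.4
        out = gaussian_beam_convolve(pencil, sig)
        assert out.second_moment() == pytest.approx(
            pencil.second_moment() + 2 * sig**2, rel=0.01)

    def test_fluence_conserved(self):
        r = np.linspace(0.0, 4.0, 500)
        phi = np.exp(-r**2 / 0.2) / (np.pi * 0.2)
        pencil = RadialDist(z=5.0, r=r, phi=phi, fluence=1.0)
        out = gaussian_beam_convolve(pencil, 0.3)
        assert out.plane_integral() == pytest.approx(1.0, rel=0.005)


class TestFourierProfile:
    def test_gaussian_kernels_compose_analytically(self):
        """Product of Gaussian characteristic functions inverts exactly."""
        arg = np.geomspace(0.05, 2e4, 140)
        sig_theta = 0.01
        char = [np.exp(-0.5 * sig_theta**2 * arg**2)]
        lever = np.array([10.0])
        q = np.linspace(0.0, 60.0, 500)
        r = np.linspace(0.0, 1.0, 200)
        phi = fourier_radial_profile(char, arg, lever, q, r, sigma_beam=0.05)
        s2 = (sig_theta * 10.0) ** 2 + 0.05**2
        ref = np.exp(-r**2 / (2 * s2)) / (2 * np.pi * s2)
        assert np.allclose(phi, ref, rtol=0.02, atol=1e-4 * ref.max())
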