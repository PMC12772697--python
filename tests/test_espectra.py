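"""Energy grid construction, spectrum propagation and interpolation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from protonboltz.constants import beta_squared
from protonboltz.espectra import (
    EmptySpectrumError,
    Spectrum,
    build_energy_grid,
    composed_sigma,
    conditional_spectrum_normal,
    delta_spectrum,
    interpolate_spectrum,
    mean_energy,
    propagate_spectrum,
)
from protonboltz.materials import ConfigurationError, delta_e_max, xi


class TestEnergyGrid:
    def test_first_edge_is_zero(self, grid100):
        assert grid100.edges[0] == 0.0

    def test_last_spacing_is_de_min(self, grid100):
        assert grid100.edges[-1] - grid100.edges[-2] == pytest.approx(
            grid100.de_min, rel=1e-9)

    def test_recurrence_oracle(self):
        """Edges follow the geometric-then-uniform recurrence exactly."""
        de_max, de_min, e_s, e_init = 0.5, 0.1, 175.0, 220.0
        g = build_energy_grid(e_init, de_max, de_min, e_s)
        q = (e_s - de_max) / (e_s - de_min)
        edges, step = [0.0], de_max
        while step > de_min and edges[-1] + step <= e_init:
            edges.append(edges[-1] + step)
            step *= q
        while edges[-1] + de_min <= e_init:
            edges.append(edges[-1] + de_min)
        assert np.allclose(g.edges, edges, rtol=0, atol=1e-12)
        assert np.all(np.diff(g.edges) > 0)
        assert g.edges[-1] <= e_init
        # spacing shrinks geometrically, then becomes uniform near e_s
        d = np.diff(g.edges)
        assert d[0] == pytest.approx(de_max)
        assert np.all(np.diff(d) < 1e-12)

    @given(st.floats(0.21, 0.5), st.floats(0.02, 0.1))
    def test_monotone_for_valid_params(self, de_max, de_min):
        g = build_energy_grid(100.0, de_max, de_min, 60.0)
        assert np.all(np.diff(g.edges) > 0)

    def test_invalid_params_raise(self):
        with pytest.raises(ConfigurationError):
            build_energy_grid(100.0, 0.1, 0.3, 60.0)


class TestNormalKernel:
    def test_zero_beyond_range(self, rt, grid100):
        spec = conditional_spectrum_normal(30.0, rt.csda_range(30.0) + 0.1,
                                           grid100)
        assert spec.integral == 0.0

    def test_delta_limit(self, grid100):
        spec = conditional_spectrum_normal(70.0, 1e-6, grid100)
        w_loc = grid100.widths[grid100.index_of(70.0)]
        assert abs(mean_energy(spec) - 70.0) <= w_loc

    def test_moments_match_closed_forms(self, rt, grid100):
        E0 = 100.0
        dt = rt.csda_range(E0) - rt.csda_range(95.0)
        spec = conditional_spectrum_normal(E0, dt, grid100)
        b2 = beta_squared(E0)
        var_ref = float(xi(E0)) * dt * float(delta_e_max(E0)) * (1 - b2 / 2)
        e_ref = rt.energy_after(E0, dt)
        mass = spec.phi * grid100.widths
        mu = (mass * grid100.mids).sum()
        var = (mass * (grid100.mids - mu) ** 2).sum()
        assert spec.integral == pytest.approx(1.0, abs=1e-9)
        assert mu == pytest.approx(e_ref, abs=0.5 * grid100.de_min)
        assert var == pytest.approx(var_ref, rel=0.15)  # binning error


class TestPropagation:
    def test_identity_for_tiny_step(self, grid100):
        s0 = delta_spectrum(grid100, 100.0)
        s1 = propagate_spectrum(s0, 1e-7)
        assert abs(mean_energy(s1) - mean_energy(s0)) < grid100.de_min

    def test_particle_conservation(self, rt, grid100):
        s = delta_spectrum(grid100, 100.0)
        for _ in range(5):
            s = propagate_spectrum(s, 0.5, range_table=rt)
        assert s.integral == pytest.approx(1.0, abs=1e-6)

    def test_mean_energy_decreases(self, rt, grid100):
        s = delta_spectrum(grid100, 100.0)
        means = [mean_energy(s)]
        for _ in range(8):
            s = propagate_spectrum(s, 0.6, range_table=rt)
            means.append(mean_energy(s))
        assert np.all(np.diff(means) < 0)

    def test_variance_grows_with_depth(self, rt, grid100):
        s = delta_spectrum(grid100, 100.0)
        var = []
        for _ in range(8):
            s = propagate_spectrum(s, 0.6, range_table=rt)
            mass = s.phi * grid100.widths
            mu = (mass * grid100.mids).sum() / mass.sum()
            var.append((mass * (grid100.mids - mu) ** 2).sum() / mass.sum())
        assert np.all(np.diff(var) > 0)

    def test_two_half_steps_match_one_full_step(self, rt, grid100):
        s0 = delta_spectrum(grid100, 100.0)
        one = propagate_spectrum(s0, 1.0, range_table=rt)
        half = propagate_spectrum(
            propagate_spectrum(s0, 0.5, range_table=rt), 0.5, range_table=rt)
        for s in (one, half):
            s.mass = s.phi * grid100.widths
        mu1 = (one.mass * grid100.mids).sum()
        mu2 = (half.mass * grid100.mids).sum()
        v1 = (one.mass * (grid100.mids - mu1) ** 2).sum()
        v2 = (half.mass * (grid100.mids - mu2) ** 2).sum()
        assert mu2 == pytest.approx(mu1, rel=0.001)
        assert v2 == pytest.approx(v1, rel=0.01)

    def test_composed_width_reduces_to_thin_step(self, rt):
        b2 = beta_squared(100.0)
        local = np.sqrt(float(xi(100.0)) * 0.01 * float(delta_e_max(100.0))
                        * (1 - b2 / 2))
        comp = float(composed_sigma(100.0, rt.energy_after(100.0, 0.01)))
        assert comp == pytest.approx(local, rel=0.02)


class TestMeanEnergy:
    def test_single_bin(self, grid100):
        s = delta_spectrum(grid100, 100.0)
        i = grid100.index_of(100.0 - 1e-9)
        assert mean_energy(s) == pytest.approx(grid100.mids[i])

    def test_symmetric_two_bins(self, grid100):
        phi = np.zeros(grid100.n_bins)
        i1, i2 = grid100.index_of(90.0), grid100.index_of(110.0 - 20.0)
        # two equal masses symmetric about their midpoint
        phi[i1] = 1.0 / grid100.widths[i1]
        phi[i2] = 1.0 / grid100.widths[i2]
        s = Spectrum(z=0.0, grid=grid100, phi=phi)
        assert mean_energy(s) == pytest.approx(
            0.5 * (grid100.mids[i1] + grid100.mids[i2]))

    def test_empty_raises(self, grid100):
        with pytest.raises(EmptySpectrumError):
            mean_energy(Spectrum(z=0.0, grid=grid100))


class TestInterpolation:
    @pytest.fixture(scope="class")
    def pair(self, rt, grid100):
        a = delta_spectrum(grid100, 100.0)
        for _ in range(6):
            a = propagate_spectrum(a, 0.7, range_table=rt)
        a.z = 4.2
        b = propagate_spectrum(a, 0.7, range_table=rt)
        b.z = 4.9
        return a, b

    def test_endpoints_identity(self, pair, rt):
        a, b = pair
        assert np.allclose(interpolate_spectrum(a.z, a, b, rt).phi, a.phi)
        assert np.allclose(interpolate_spectrum(b.z, a, b, rt).phi, b.phi)

    def test_mid_depth_mean_energy(self, pair, rt):
        a, b = pair
        z = 0.5 * (a.z + b.z)
        mid = interpolate_spectrum(z, a, b, rt)
        k_expect = 0.5 * (mean_energy(a) + mean_energy(b))
        assert mean_energy(mid) == pytest.approx(k_expect, abs=0.1)

    def test_out_of_bracket_raises(self, pair, rt):
        a, b = pair
        with pytest.raises(ValueError):
            interpolate_spectrum(a.z - 1.0, a, b, rt)
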