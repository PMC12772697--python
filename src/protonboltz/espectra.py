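"""Fluence energy spectra and their step-wise propagation in depth.

Spectra are histograms (fluence density per MeV per incident proton) on a
nonuniform energy grid that is fine (``de_min``) above the switching energy
``e_s`` -- where spectra of a monoenergetic beam are still narrow -- and
relaxes geometrically to ``de_max`` toward low energies.  Propagation over
one depth step applies the law of total expectation: the new spectrum is
the source spectrum convolved with the single-step conditional energy-loss
kernel (Gaussian by default, Vavilov on request).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .constants import beta_squared
from .materials import (
    ConfigurationError,
    Material,
    RangeTable,
    delta_e_max,
    load_range_table,
    water,
    xi,
)


class EmptySpectrumError(ValueError):
    """Operation undefined for a spectrum with zero integral fluence."""


_AUX_CACHE: dict = {}


def _straggling_w(material: Material, rt: RangeTable):
    """Cumulative thick-target straggling integral W(E).

    The variance of the energy spectrum after slowing from E to E_f is
    ``S(E_f)^2 (W(E) - W(E_f))`` with ``W(E) = int xi*dE_max*(1-beta^2/2)
    / S^3 de`` -- the per-step Gaussian widths composed through the
    linearized CSDA map (each step's width is carried to the final energy
    with the Jacobian S(E_f)/S(e)).
    """
    key = ("W", material.name, id(rt))
    if key not in _AUX_CACHE:
        e = np.geomspace(rt.energies[0], rt.energies[-1], 2000)
        s = rt.stopping_power(e)
        b2 = beta_squared(e)
        integrand = xi(e, material) * delta_e_max(e) * (1.0 - b2 / 2.0) / s**3
        w = np.concatenate([[0.0], np.cumsum(
            0.5 * (integrand[1:] + integrand[:-1]) * np.diff(e))])
        from scipy.interpolate import PchipInterpolator
        _AUX_CACHE[key] = (PchipInterpolator(e, w, extrapolate=False), e[0])
    itp, e_min = _AUX_CACHE[key]
    def w_of(E):
        return itp(np.clip(E, e_min, None))
    return w_of


def _attenuation_g(material: Material, rt: RangeTable, tables):
    """Cumulative nuclear attenuation integral G(E) = int sigma_N / S de.

    The survival probability of a proton slowing from E to E_f in the CSDA
    is ``exp(-(G(E) - G(E_f)))``.
    """
    key = ("G", material.name, id(rt), id(tables))
    if key not in _AUX_CACHE:
        e = np.geomspace(rt.energies[0], rt.energies[-1], 2000)
        s = rt.stopping_power(e)
        sig = tables.sigma_total(e)
        g = np.concatenate([[0.0], np.cumsum(
            0.5 * (sig[1:] / s[1:] + sig[:-1] / s[:-1]) * np.diff(e))])
        from scipy.interpolate import PchipInterpolator
        _AUX_CACHE[key] = (PchipInterpolator(e, g, extrapolate=False), e[0])
    itp, e_min = _AUX_CACHE[key]
    def g_of(E):
        return itp(np.clip(E, e_min, None))
    return g_of


def composed_sigma(e_src, e_fin, material: Material | None = None,
                   range_table: RangeTable | None = None):
    """Straggling width [MeV] accumulated while slowing from e_src to e_fin."""
    mat = material or water()
    rt = range_table or load_range_table()
    w = _straggling_w(mat, rt)
    var = rt.stopping_power(np.maximum(e_fin, 1e-6)) ** 2 \
        * np.maximum(w(e_src) - w(np.maximum(e_fin, 1e-6)), 0.0)
    return np.sqrt(np.maximum(var, 0.0))


@dataclass(frozen=True)
class EnergyGrid:
    """Bin edges E_1 = 0 < E_2 < ... with geometric-then-uniform spacing."""

    edges: np.ndarray
    de_max: float
    de_min: float
    e_s: float
    e_init: float

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def mids(self) -> np.ndarray:
        return 0.5 * (self.edges[1:] + self.edges[:-1])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def index_of(self, E: float) -> int:
        i = int(np.searchsorted(self.edges, E, side="right") - 1)
        return min(max(i, 0), self.n_bins - 1)


def build_energy_grid(e_init: float, de_max: float, de_min: float,
                      e_s: float) -> EnergyGrid:
    """Construct the energy grid from its four defining parameters.

    Spacing starts at ``de_max`` just above E = 0 and shrinks geometrically
    by ``q = (e_s - de_max)/(e_s - de_min)`` per bin; once it reaches
    ``de_min`` (near ``e_s``) the grid continues uniformly up to ``e_init``.
    """
    if not (0 < de_min < de_max < e_s < e_init):
        raise ConfigurationError(
            "require 0 < de_min < de_max < e_s < e_init, got "
            f"{de_min}, {de_max}, {e_s}, {e_init}"
        )
    q = (e_s - de_max) / (e_s - de_min)
    edges = [0.0]
    step = de_max
    while step > de_min and edges[-1] + step <= e_init:
        edges.append(edges[-1] + step)
        step *= q
    while edges[-1] + de_min <= e_init:
        edges.append(edges[-1] + de_min)
    return EnergyGrid(edges=np.asarray(edges), de_max=de_max, de_min=de_min,
                      e_s=e_s, e_init=e_init)


@dataclass
class Spectrum:
    """Fluence density per MeV (per incident proton) at one depth."""

    z: float
    grid: EnergyGrid
    phi: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.phi is None:
            self.phi = np.zeros(self.grid.n_bins)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.size != self.grid.n_bins:
            raise ValueError("phi length does not match grid")

    @property
    def integral(self) -> float:
        return float(np.sum(self.phi * self.grid.widths))

    @property
    def mean_energy(self) -> float:
        return mean_energy(self)

    def copy(self, z: float | None = None) -> "Spectrum":
        return Spectrum(z=self.z if z is None else z, grid=self.grid,
                        phi=self.phi.copy())


def delta_spectrum(grid: EnergyGrid, E: float, z: float = 0.0) -> Spectrum:
    """All fluence concentrated in the bin containing ``E``."""
    phi = np.zeros(grid.n_bins)
    i = grid.index_of(min(E, grid.edges[-1] - 1e-12))
    phi[i] = 1.0 / grid.widths[i]
    return Spectrum(z=z, grid=grid, phi=phi)


def mean_energy(spec: Spectrum) -> float:
    """Fluence-weighted mean energy K-bar of the spectrum [MeV]."""
    mass = spec.phi * spec.grid.widths
    total = mass.sum()
    if total <= 0:
        raise EmptySpectrumError("mean energy of an empty spectrum")
    return float((mass * spec.grid.mids).sum() / total)


def conditional_spectrum_normal(E_prime: float, dt: float, grid: EnergyGrid,
                                material: Material | None = None,
                                range_table: RangeTable | None = None) -> Spectrum:
    """Gaussian single-step kernel binned on ``grid``.

    Center is the CSDA mean ``R^-1(R(E') - dt)``; the variance is
    ``xi*dt*(dE)_max*(1 - beta^2/2)``.  The tail below E = 0 is cut off and
    the kernel renormalized; a step exceeding the CSDA range returns the
    zero spectrum.
    """
    mat = material or water()
    rt = range_table or load_range_table()
    phi = np.zeros(grid.n_bins)
    if dt >= rt.csda_range(E_prime):
        return Spectrum(z=dt, grid=grid, phi=phi)
    e_bar = rt.energy_after(E_prime, dt)
    b2 = float(beta_squared(E_prime))
    var = float(xi(E_prime, mat)) * dt * float(delta_e_max(E_prime)) * (1.0 - b2 / 2.0)
    sig = np.sqrt(var)
    if sig < 1e-9:
        return delta_spectrum(grid, e_bar, z=dt)
    cdf = ndtr((grid.edges - e_bar) / sig)
    mass = np.diff(cdf)
    mass[grid.edges[1:] <= 0] = 0.0
    total = mass.sum()
    if total <= 0:
        return Spectrum(z=dt, grid=grid, phi=phi)
    phi = mass / total / grid.widths
    return Spectrum(z=dt, grid=grid, phi=phi)


def propagate_spectrum(spec: Spectrum, dt: float, kernel: str = "normal",
                       material: Material | None = None,
                       range_table: RangeTable | None = None,
                       nuclear_tables=None) -> Spectrum:
    """Total-expectation propagation over a slab of thickness ``dt``.

    ``kernel`` is ``"normal"`` or ``"vavilov"``.  The Gaussian path composes
    the per-step widths analytically (thick-target straggling integral), so
    ``dt`` may span many transport steps without accumulating grid noise.
    Protons whose CSDA range is shorter than ``dt`` stop inside the slab and
    are dropped from the returned spectrum (their terminal deposition is
    bookkept by the driver).  When ``nuclear_tables`` is given, each
    contribution is attenuated by the exact CSDA survival factor
    ``exp(-int sigma_N dt)`` along its slowing-down path.
    """
    mat = material or water()
    rt = range_table or load_range_table()
    grid = spec.grid
    mids, widths, edges = grid.mids, grid.widths, grid.edges
    mass_src = spec.phi * widths
    total = mass_src.sum()
    out = np.zeros(grid.n_bins)
    if total <= 0:
        return Spectrum(z=spec.z + dt, grid=grid, phi=out)
    active = mass_src > 1e-16 * total
    surviving = active & (rt.csda_range(edges[1:]) > dt)
    if not np.any(surviving):
        return Spectrum(z=spec.z + dt, grid=grid, phi=out)

    if kernel == "vavilov":
        from .vavilov import StepTooLargeError, conditional_spectrum_vavilov
        for j in np.where(surviving)[0]:
            try:
                ker = conditional_spectrum_vavilov(mids[j], dt, grid, mat, rt)
            except StepTooLargeError:
                # the thin-slab condition fails for slow protons in a
                # clamped step; the Gaussian kernel takes over there
                ker = conditional_spectrum_normal(mids[j], dt, grid, mat, rt)
            out += mass_src[j] * ker.phi
        return Spectrum(z=spec.z + dt, grid=grid, phi=out)

    src = np.where(surviving)[0]
    # uniform-within-bin source semantics: the surviving sub-interval of each
    # bin maps through the CSDA to [Ebar(lo), Ebar(hi)]; where that mapped
    # width exceeds the physical kernel width (strongly nonlinear map near
    # the track end) the interval is subdivided so the piecewise-Gaussian
    # representation tracks the exact mapped density
    e_thr = rt.inverse_range(dt)
    lo = np.maximum(edges[src], e_thr)
    hi = edges[src + 1]
    frac = (hi - lo) / widths[src]
    mid0 = 0.5 * (lo + hi)
    w_strag = _straggling_w(mat, rt)
    sig0 = composed_sigma(mid0, rt.energy_after(mid0, dt), mat, rt)
    spread = rt.energy_after(hi, dt) - rt.energy_after(lo, dt)
    n_sub = np.clip(np.ceil(spread / np.maximum(sig0, 1e-12)).astype(int), 1, 24)
    # expand to sub-intervals (uniform mass split within each source bin)
    reps = np.repeat(np.arange(src.size), n_sub)
    offs = np.concatenate([np.arange(k) for k in n_sub])
    sub_w = ((hi - lo) / n_sub)[reps]
    sub_lo = lo[reps] + offs * sub_w
    sub_hi = sub_lo + sub_w
    # two-point Gauss nodes inside each sub-interval give the mapped mean
    # and spread exactly for a locally linear map (and much better than the
    # endpoint midpoint where the map curves near the track end)
    src_mid = 0.5 * (sub_lo + sub_hi)
    h = 0.5 * (sub_hi - sub_lo) / np.sqrt(3.0)
    e1 = rt.energy_after(src_mid - h, dt)
    e2 = rt.energy_after(src_mid + h, dt)
    e_bar = 0.5 * (e1 + e2)
    e_safe = np.maximum(e_bar, 1e-4)
    var = (rt.stopping_power(e_safe) ** 2
           * np.maximum(w_strag(src_mid) - w_strag(e_safe), 0.0)
           + (e2 - e1) ** 2 / 4.0)
    # Sheppard-type deconvolution: the final re-binning adds about
    # w_out^2/12 of variance at the measurement grid; pre-subtract it
    w_out = widths[np.clip(np.searchsorted(edges, e_bar, side="right") - 1,
                           0, widths.size - 1)]
    var = np.maximum(var - w_out**2 / 12.0, 0.05 * var)
    sig = np.sqrt(np.maximum(var, 1e-24))
    sub_mass = (mass_src[src] * frac / n_sub)[reps]
    if nuclear_tables is not None:
        g = _attenuation_g(mat, rt, nuclear_tables)
        sub_mass = sub_mass * np.exp(-(np.maximum(
            g(src_mid) - g(e_safe), 0.0)))
    lo = max(0.0, float(np.min(e_bar - 10.0 * sig)))
    hi = float(np.max(e_bar + 10.0 * sig))
    c0 = max(int(np.searchsorted(edges, lo)) - 1, 0)
    c1 = min(int(np.searchsorted(edges, hi)) + 1, edges.size - 1)
    sub_edges = edges[c0:c1 + 1]
    cdf = ndtr((sub_edges[None, :] - e_bar[:, None]) / sig[:, None])
    mass_k = np.diff(cdf, axis=1)
    mass_k[:, sub_edges[1:] <= 0] = 0.0
    norm = mass_k.sum(axis=1)
    ok = norm > 0
    contrib = (sub_mass[ok] / norm[ok])[:, None] * mass_k[ok]
    out[c0:c1] = contrib.sum(axis=0)
    return Spectrum(z=spec.z + dt, grid=grid, phi=out / widths)


def interpolate_spectrum(z: float, spec_m: Spectrum, spec_m1: Spectrum,
                         range_table: RangeTable | None = None) -> Spectrum:
    """Energy-shifted interpolation between two stored spectra.

    The mean energy at ``z`` is obtained by CSDA evolution from the stored
    mean at the lower depth; the two shifted copies are blended with the
    mean-energy weight ``w = (K_m - K)/(K_m - K_m1)``.
    """
    if not (spec_m.z <= z <= spec_m1.z):
        raise ValueError(f"depth {z} outside bracket [{spec_m.z}, {spec_m1.z}]")
    if z == spec_m.z:
        return spec_m.copy()
    if z == spec_m1.z:
        return spec_m1.copy()
    rt = range_table or load_range_table()
    grid = spec_m.grid
    try:
        k_m = mean_energy(spec_m)
        k_m1 = mean_energy(spec_m1)
    except EmptySpectrumError:
        return Spectrum(z=z, grid=grid)
    u = (z - spec_m.z) / (spec_m1.z - spec_m.z)
    # linear-in-depth mean energy: second-order accurate over a fractional
    # energy-loss step and, unlike CSDA evolution of the stored mean, free
    # of survivor bias in the range-out region
    k_here = (1.0 - u) * k_m + u * k_m1
    if k_m - k_m1 > 1e-9:
        w = float(np.clip((k_m - k_here) / (k_m - k_m1), 0.0, 1.0))
    else:
        w = u
    dk_m = k_m - k_here
    dk_m1 = k_here - k_m1
    mids = grid.mids
    shifted_m = np.interp(mids + dk_m, mids, spec_m.phi, left=0.0, right=0.0)
    shifted_m1 = np.interp(mids - dk_m1, mids, spec_m1.phi, left=0.0, right=0.0)
    # w vanishes at z_m, so it weights the far (shifted m+1) spectrum
    phi = (1.0 - w) * shifted_m + w * shifted_m1
    # the shifts redistribute mass across nonuniform bins; restore the
    # linearly interpolated integral for particle-number consistency
    target = (1.0 - w) * spec_m.integral + w * spec_m1.integral
    got = float(np.sum(phi * grid.widths))
    if got > 0:
        phi *= target / got
    return Spectrum(z=z, grid=grid, phi=phi)
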