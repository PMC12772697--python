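"""Vavilov energy-loss straggling distribution for a single transport step.

The Vavilov distribution describes the fluctuation of the total energy loss
Q of a charged particle crossing a slab thin enough that Q is much smaller
than the kinetic energy.  It interpolates between the Landau limit (very
thin slabs, ``k << 1``) and a Gaussian (thick slabs, ``k >> 1``) where the
straggling parameter ``k = xi*t/(dE)_max`` counts, roughly, the number of
near-maximal delta-ray collisions per step.

The density is evaluated by direct quadrature of the oscillatory inversion
integral; the exponential envelope ``exp(k*f1(y))`` decays like
``exp(-pi*k*y/2)`` at large ``y``, which gives explicit truncation control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sici

from .constants import EULER_GAMMA, beta_squared
from .materials import Material, RangeTable, delta_e_max, load_range_table, water, xi


class StepTooLargeError(ValueError):
    """The mean loss over the step violates the thin-slab assumption."""


def ci_si(y):
    """Cosine and sine integrals Ci(y), Si(y) (wrapper around scipy)."""
    si, ci = sici(y)
    return ci, si


@dataclass(frozen=True)
class VavilovParams:
    """Parameters of the straggling distribution for one step."""

    E0: float          # kinetic energy at step start [MeV]
    t: float           # step length [cm]
    k: float           # straggling parameter xi*t/(dE)_max
    beta2: float       # (v/c)^2
    de_max: float      # maximum single-collision energy transfer [MeV]
    xi_t: float        # xi(E0) * t [MeV]
    q_bar: float       # mean energy loss over t [MeV]


def vavilov_params(
    E0: float,
    t: float,
    material: Material | None = None,
    range_table: RangeTable | None = None,
) -> VavilovParams:
    mat = material or water()
    rt = range_table or load_range_table()
    b2 = float(beta_squared(E0))
    dem = float(delta_e_max(E0))
    xt = float(xi(E0, mat)) * t
    q_bar = E0 - rt.energy_after(E0, t)
    return VavilovParams(E0=E0, t=t, k=xt / dem, beta2=b2, de_max=dem,
                         xi_t=xt, q_bar=q_bar)


def _f1_f2(y, beta2):
    ci, si = ci_si(y)
    lg = np.log(y) - ci
    f1 = beta2 * lg - y * si - np.cos(y)
    f2 = y * lg + beta2 * si + np.sin(y)
    return f1, f2


def _y_max(k: float, beta2: float, tol_log: float = 27.6) -> float:
    # envelope exp(k*f1) ~ exp(k*(beta2*ln y - pi*y/2)); solve for decay < 1e-12
    y = 10.0
    for _ in range(4):
        y = (tol_log / k + 1.0 + beta2 * np.log(max(y, 2.0))) / (np.pi / 2.0)
    return max(y, 8.0 / np.sqrt(max(k, 1e-12)))


def vavilov_pdf(Q, E0: float, t: float,
                material: Material | None = None,
                range_table: RangeTable | None = None,
                params: VavilovParams | None = None):
    """Probability density (per MeV) of losing energy ``Q`` over step ``t``.

    ``Q = E0 - E(t)``.  Raises :class:`StepTooLargeError` when the mean loss
    exceeds 20% of ``E0`` (thin-slab assumption).
    """
    p = params or vavilov_params(E0, t, material, range_table)
    if p.q_bar > 0.2 * p.E0:
        raise StepTooLargeError(
            f"mean loss {p.q_bar:.2f} MeV exceeds 20% of E0={p.E0:.1f} MeV"
        )
    Q = np.atleast_1d(np.asarray(Q, dtype=float))
    lam1 = (Q - p.q_bar) / p.de_max - p.k * (1.0 + p.beta2 - EULER_GAMMA)

    ymax = _y_max(p.k, p.beta2)
    # resolve the fastest oscillation cos(lam1*y + k*f2)
    freq = np.max(np.abs(lam1)) + p.k * (1.0 + p.beta2 - EULER_GAMMA) + 1.0
    n = int(min(max(4000, 25 * freq * ymax / (2 * np.pi)), 2_000_000))
    n += (n % 2)  # Simpson needs even interval count
    y = np.linspace(1e-9, ymax, n + 1)
    f1, f2 = _f1_f2(y, p.beta2)
    env = np.exp(p.k * f1)
    phase0 = p.k * f2
    w = np.ones(n + 1)
    w[1:-1:2], w[2:-1:2] = 4.0, 2.0
    w *= (y[1] - y[0]) / 3.0

    out = np.empty_like(Q)
    chunk = max(1, int(4e6 // (n + 1)))
    for i0 in range(0, Q.size, chunk):
        lam = lam1[i0:i0 + chunk, None]
        out[i0:i0 + chunk] = (env * np.cos(lam * y + phase0) * w).sum(axis=1)
    pref = np.exp(p.k * (1.0 + EULER_GAMMA * p.beta2)) / (np.pi * p.de_max)
    return np.clip(pref * out, 0.0, None)


def gaussian_limit_sigma2(params: VavilovParams) -> float:
    """Variance of the large-k (Gaussian) limit: xi*t*(dE)_max*(1-beta^2/2)."""
    return params.xi_t * params.de_max * (1.0 - params.beta2 / 2.0)


def conditional_spectrum_vavilov(E_prime: float, dt: float, grid,
                                 material: Material | None = None,
                                 range_table: RangeTable | None = None):
    """Single-step conditional spectrum Phi(E|E') binned on ``grid``.

    Returns the fluence density histogram (per MeV) of protons that started
    the step with energy ``E_prime``; identically zero when the step exceeds
    the CSDA range (the proton stops inside the step).
    """
    from .espectra import Spectrum  # local import to avoid a cycle

    rt = range_table or load_range_table()
    phi = np.zeros(grid.n_bins)
    if dt >= rt.csda_range(E_prime):
        return Spectrum(z=dt, grid=grid, phi=phi)
    p = vavilov_params(E_prime, dt, material, rt)
    sig = np.sqrt(gaussian_limit_sigma2(p))
    # energy window: generous Gaussian core plus the Landau-type low-E tail
    e_lo = max(0.0, E_prime - p.q_bar - 30.0 * sig - 30.0 * p.xi_t)
    e_hi = min(E_prime, grid.edges[-1])
    sel = (grid.edges[1:] > e_lo) & (grid.edges[:-1] < e_hi)
    idx = np.where(sel)[0]
    if idx.size == 0:
        return Spectrum(z=dt, grid=grid, phi=phi)
    # 3-point Gauss-Legendre inside each bin, clipped to [0, E']
    lo = np.maximum(grid.edges[:-1][idx], 0.0)
    hi = np.minimum(grid.edges[1:][idx], E_prime)
    gl_x = np.array([-0.7745966692414834, 0.0, 0.7745966692414834])
    gl_w = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])
    mid, half = 0.5 * (hi + lo), 0.5 * (hi - lo)
    E_nodes = mid[:, None] + half[:, None] * gl_x[None, :]
    dens = vavilov_pdf(E_prime - E_nodes.ravel(), E_prime, dt, params=p,
                       range_table=rt).reshape(E_nodes.shape)
    bin_mass = (dens * gl_w[None, :]).sum(axis=1) * half
    total = bin_mass.sum()
    if total > 0:
        phi[idx] = bin_mass / total / grid.widths[idx]
    return Spectrum(z=dt, grid=grid, phi=phi)
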