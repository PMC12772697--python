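"""Moliere multiple-Coulomb-scattering kernel and angular-distribution transport.

A single depth step produces the classic Moliere angular distribution: a
Gaussian core of width ``chi_c*sqrt(B)`` plus the single-scattering tail,
expressed as the series ``sum_n B^-n f^(n)(theta/(chi_c*sqrt(B)))`` truncated
at n = 2.  The step kernel is convolved iteratively with the current angular
distribution on the sphere, with Gauss-Legendre quadrature over the polar
angle and Gauss-Chebyshev quadrature over the azimuth.

Screening angles follow the Fano-corrected prescription for compounds: each
element contributes a screened single-atom angle (Thomas-Fermi with a
Hartree-Fock factor) and an inelastic-scattering correction ``F_j/Z_j``; the
compound average is weighted by the element's share of ``chi_c^2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import j0, roots_legendre

from .constants import (
    ALPHA_FS,
    C_TF,
    ELECTRON_REST_MEV,
    EULER_GAMMA,
    N_AVOGADRO,
    PROTON_REST_MEV,
    RE_CM,
    beta_squared,
)
from .materials import Material, water


class ThinStepError(ValueError):
    """Too few scattering events in the step for Moliere theory."""


# Fano inelastic-scattering constants u_j for the elements of water
_FANO_U = {1: 3.6, 8: 5.8}

THETA_MIN_DEG = 0.01
THETA_MAX_DEG = 10.0
N_THETA = 50


def build_theta_grid(n: int = N_THETA, theta_min_deg: float = THETA_MIN_DEG,
                     theta_max_deg: float = THETA_MAX_DEG) -> np.ndarray:
    """Log-uniform polar-angle grid [rad]."""
    return np.deg2rad(np.geomspace(theta_min_deg, theta_max_deg, n))


# ---------------------------------------------------------------------------
# the universal functions f^(n)

_F_TAB_THETA_MAX = 20.0


@lru_cache(maxsize=1)
def _f_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pretabulated f^(0), f^(1), f^(2) on a fixed reduced-angle grid."""
    thetas = np.concatenate([[0.0], np.geomspace(1e-3, _F_TAB_THETA_MAX, 1200)])
    u = np.linspace(1e-12, 20.0, 8001)
    du = u[1] - u[0]
    w = np.ones(u.size)
    w[1:-1:2], w[2:-1:2] = 4.0, 2.0
    w *= du / 3.0
    base = u * np.exp(-u * u / 4.0) * w
    lnterm = (u * u / 4.0) * np.log(u * u / 4.0)
    rows = []
    for n, fac in ((0, 1.0), (1, 1.0), (2, 0.5)):
        g = base * lnterm**n * fac
        # J0(theta*u) evaluated as an outer product, integrated over u
        rows.append(j0(np.outer(thetas, u)) @ g)
    return thetas, rows[0], rows[1], rows[2]


def f_n_table(n: int, thetas=None):
    """f^(n) on the reduced-angle grid (or interpolated onto ``thetas``)."""
    if n not in (0, 1, 2):
        raise ValueError("series truncated at n = 2")
    tab_t, f0, f1, f2 = _f_tables()
    f = (f0, f1, f2)[n]
    if thetas is None:
        return tab_t.copy(), f.copy()
    return _eval_f(n, np.asarray(thetas, dtype=float))


def _eval_f(n: int, th: np.ndarray) -> np.ndarray:
    tab_t, f0, f1, f2 = _f_tables()
    f = (f0, f1, f2)[n]
    out = np.interp(th, tab_t, f, right=0.0)
    if n == 1:  # Rutherford single-scattering tail beyond the table
        big = th > tab_t[-1]
        if np.any(big):
            out[big] = 2.0 / th[big] ** 4
    return out


# ---------------------------------------------------------------------------
# Moliere parameters

@dataclass(frozen=True)
class MoliereParams:
    E: float            # kinetic energy at step start [MeV]
    dt: float           # step length [cm]
    chi_c2: float       # characteristic angle^2 [rad^2]
    chi_a2: float       # screening angle^2 [rad^2]
    b: float
    B: float
    beta2: float
    tau: float

    @property
    def theta_unit(self) -> float:
        """The reduced-angle scale chi_c * sqrt(B) [rad]."""
        return np.sqrt(self.chi_c2 * self.B)


def solve_B(b: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve B - ln(B) = b on the branch B > 1 by Newton iteration."""
    if b <= 1.0:
        raise ThinStepError(f"b = {b:.3f} <= 1 has no solution with B > 1")
    B = b + np.log(b) + 1.0
    for _ in range(max_iter):
        f = B - np.log(B) - b
        B_new = B - f / (1.0 - 1.0 / B)
        if B_new <= 1.0:
            B_new = 0.5 * (B + 1.0)
        if abs(B_new - B) < tol:
            return B_new
        B = B_new
    return B


def moliere_params(E: float, dt: float,
                   material: Material | None = None) -> MoliereParams:
    """Compute the single-step Moliere parameters for ``material``.

    Raises :class:`ThinStepError` when the step holds too few elastic
    collisions (b <= 1.2) for the multiple-scattering expansion.
    """
    if dt <= 0 or E <= 0:
        raise ValueError("E and dt must be positive")
    mat = material or water()
    b2 = float(beta_squared(E))
    tau = E / PROTON_REST_MEV
    kin = ((tau + 1.0) / (tau * (tau + 2.0))) ** 2
    m_ratio2 = (ELECTRON_REST_MEV / PROTON_REST_MEV) ** 2

    pref = 4.0 * np.pi * N_AVOGADRO * RE_CM**2 * m_ratio2 * kin * mat.rho * dt
    chi_c2_j, ln_chi_a2_j = [], []
    for el in mat.elements:
        # Z^2 nuclear scattering; scattering off atomic electrons enters
        # through the separate inelastic (Fano) term F_j below
        chi_c2_j.append(pref * el.w * el.Z**2 / el.A)
        g_s = ((ALPHA_FS * el.Z ** (1.0 / 3.0)
                * np.sqrt(m_ratio2) / C_TF) ** 2
               * (1.13 + 3.76 * (ALPHA_FS * el.Z) ** 2 / b2 * el.k_HF)
               / (tau * (tau + 2.0)))
        f_j = 0.0
        u_j = _FANO_U.get(el.Z)
        if u_j is not None:
            f_j = np.log(1130.0 * el.Z ** (-4.0 / 3.0) * b2 / (1.0 - b2)) + u_j - b2
        ln_chi_a2_j.append(np.log(g_s) - f_j / el.Z)
    chi_c2_j = np.asarray(chi_c2_j)
    chi_c2 = float(chi_c2_j.sum())
    ln_chi_a2 = float((chi_c2_j * np.asarray(ln_chi_a2_j)).sum() / chi_c2)
    chi_a2 = float(np.exp(ln_chi_a2))
    b = np.log(chi_c2 / chi_a2) + 1.0 - 2.0 * EULER_GAMMA
    if b <= 1.2:
        raise ThinStepError(
            f"step dt = {dt:.4g} cm too thin at E = {E:.3g} MeV (b = {b:.2f});"
            " increase the step size"
        )
    B = solve_B(b)
    return MoliereParams(E=E, dt=dt, chi_c2=chi_c2, chi_a2=chi_a2, b=b, B=B,
                         beta2=b2, tau=tau)


def kernel_second_moment(params: MoliereParams,
                         theta_max: float | None = None) -> float:
    """Mean-square deflection <theta^2> [rad^2] of the single-step kernel.

    The Moliere mean-square angle diverges logarithmically, so it is
    evaluated with the same angular cutoff as the transport grid.
    """
    t_max = np.deg2rad(THETA_MAX_DEG) if theta_max is None else theta_max
    th = np.concatenate([[0.0], np.geomspace(1e-5, t_max, 600)])
    pdf = moliere_pdf(th, params)
    norm = 2.0 * np.pi * np.trapezoid(pdf * th, th)
    if norm <= 0:
        return 0.0
    return float(2.0 * np.pi * np.trapezoid(pdf * th**3, th) / norm)


def kernel_char_fn(params: MoliereParams, q: np.ndarray,
                   theta_max: float | None = None) -> np.ndarray:
    """Hankel transform (2-D characteristic function) of the step kernel.

    ``A(q) = 2*pi*int pdf(theta) J0(q*theta) theta dtheta``, normalized to
    ``A(0) = 1``, with the transport grid's angular cutoff.
    """
    t_max = np.deg2rad(THETA_MAX_DEG) if theta_max is None else theta_max
    q = np.asarray(q, dtype=float)
    th = np.linspace(0.0, t_max, 1200)
    pdf = moliere_pdf(np.maximum(th, 1e-9), params)
    w = pdf * th
    norm = np.trapezoid(w, th)
    if norm <= 0:
        return np.ones_like(q)
    out = np.trapezoid(w[None, :] * j0(np.outer(q, th)), th, axis=1) / norm
    return out


def moliere_pdf(theta, params: MoliereParams):
    """Fluence density per steradian of the single-step kernel."""
    th = np.atleast_1d(np.asarray(theta, dtype=float)) / params.theta_unit
    series = _eval_f(0, th) + _eval_f(1, th) / params.B + _eval_f(2, th) / params.B**2
    out = series / (2.0 * np.pi * params.chi_c2 * params.B)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# angular distributions and their iterative convolution

@dataclass
class AngularDist:
    """Azimuthally symmetric fluence density per steradian on a theta grid."""

    z: float
    theta: np.ndarray
    phi: np.ndarray
    is_delta: bool = False   # exact forward delta (source at z = 0)

    def solid_angle_integral(self) -> float:
        if self.is_delta:
            return 1.0
        return float(2.0 * np.pi * np.trapezoid(self.phi * self.theta, self.theta))

    @property
    def theta_bar(self) -> float:
        """Fluence-weighted mean polar angle [rad]."""
        if self.is_delta:
            return 0.0
        wgt = self.phi * self.theta
        tot = np.trapezoid(wgt, self.theta)
        if tot <= 0:
            return 0.0
        return float(np.trapezoid(wgt * self.theta, self.theta) / tot)

    def normalized(self) -> "AngularDist":
        tot = self.solid_angle_integral()
        phi = self.phi / tot if tot > 0 else self.phi
        return AngularDist(z=self.z, theta=self.theta, phi=phi,
                           is_delta=self.is_delta)


def delta_angular(theta_grid: np.ndarray, z: float = 0.0) -> AngularDist:
    return AngularDist(z=z, theta=theta_grid, phi=np.zeros_like(theta_grid),
                       is_delta=True)


@lru_cache(maxsize=8)
def _quad_nodes(n_leg: int, n_cheb: int):
    x, w = roots_legendre(n_leg)
    jj = np.arange(1, n_cheb + 1)
    y = np.cos((2 * jj - 1) * np.pi / (2 * n_cheb))
    w_cheb = np.pi / n_cheb
    return x, w, y, w_cheb


def _kernel_factory(source: "AngularDist | MoliereParams"):
    if isinstance(source, MoliereParams):
        return lambda th: moliere_pdf(th, source)
    grid, vals = source.theta, source.phi
    return lambda th: np.interp(th, grid, vals, left=vals[0], right=0.0)


def propagate_angular(dist: AngularDist, kernel: "AngularDist | MoliereParams",
                      n_legendre: int = 64, n_chebyshev: int = 64,
                      renormalize: bool = True) -> AngularDist:
    """One step of the spherical convolution of ``dist`` with ``kernel``.

    The kernel may be given as precomputed Moliere parameters (evaluated
    exactly) or as another tabulated angular distribution.  A forward-delta
    input returns the kernel itself binned on the grid.
    """
    theta = dist.theta
    ker = _kernel_factory(kernel)
    if dist.is_delta:
        phi = ker(theta)
        out = AngularDist(z=dist.z, theta=theta, phi=phi)
        return out.normalized() if renormalize else out

    x, w_leg, y, w_cheb = _quad_nodes(n_legendre, n_chebyshev)
    t_max = theta[-1]
    tp = 0.5 * t_max * (x + 1.0)          # theta' nodes on [0, theta_max]
    w_tp = 0.5 * t_max * w_leg
    phi_tp = np.interp(tp, theta, dist.phi, left=dist.phi[0], right=0.0)

    cos_big = (np.sin(theta)[:, None, None] * np.sin(tp)[None, :, None]
               * y[None, None, :]
               + np.cos(theta)[:, None, None] * np.cos(tp)[None, :, None])
    big_theta = np.arccos(np.clip(cos_big, -1.0, 1.0))
    k_vals = ker(big_theta.ravel()).reshape(big_theta.shape)
    azim = 2.0 * w_cheb * k_vals.sum(axis=2)          # integral over phi'
    phi_out = azim @ (w_tp * tp * phi_tp)
    out = AngularDist(z=dist.z, theta=theta, phi=phi_out)
    return out.normalized() if renormalize else out
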