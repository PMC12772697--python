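"""Nuclear attenuation of primaries and single-generation secondary protons.

Primaries are removed with the total macroscopic nuclear cross section after
each Coulomb step.  The secondary-proton fluence produced by elastic
scattering on hydrogen (two outgoing protons, isotropic in the CM frame),
elastic scattering on heavier nuclei (one forward-peaked proton, Ranft-type
differential cross section with relativistic two-body kinematics), and --
optionally -- nonelastic reactions, is tallied on a coarse depth grid with a
surface-crossing estimator: each scattered proton contributes ``1/mu_lab``
to the spectrum at a tally plane it can still reach, attenuated by
``exp(-sigma_N * path)`` and slowed along the path in the CSDA.

Secondaries do not spawn further generations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import roots_legendre, roots_laguerre

from .constants import AMU_MEV, PROTON_REST_MEV
from .materials import (
    ConfigurationError,
    NuclearTables,
    RangeTable,
    load_nuclear_tables,
    load_range_table,
)
from .espectra import EnergyGrid, Spectrum

A_OXYGEN = 15.999


@dataclass(frozen=True)
class NuclearStepGrid:
    """Coarse depth grid for nuclear-interaction tallies."""

    depths: np.ndarray      # zeta_1 ... zeta_n [cm]
    dtau_max: float
    dtau_min: float

    @property
    def steps(self) -> np.ndarray:
        return np.diff(self.depths)


def build_nuclear_grid(e_init: float, dtau_max: float, dtau_min: float,
                       range_table: RangeTable | None = None,
                       z_max: float | None = None) -> NuclearStepGrid:
    """Depth grid covering the track, steps shrinking toward the track end."""
    if not (0 < dtau_min <= dtau_max):
        raise ConfigurationError("need 0 < dtau_min <= dtau_max")
    rt = range_table or load_range_table()
    end = z_max if z_max is not None else rt.csda_range(e_init)
    depths = [0.0]
    while depths[-1] < end - 1e-9:
        remaining = end - depths[-1]
        step = min(dtau_max, max(dtau_min, 0.5 * remaining))
        step = min(step, remaining) if remaining > dtau_min else dtau_min
        depths.append(depths[-1] + step)
    return NuclearStepGrid(depths=np.asarray(depths), dtau_max=dtau_max,
                           dtau_min=dtau_min)


def attenuate(spec: Spectrum, dt: float,
              tables: NuclearTables | None = None) -> Spectrum:
    """Remove primaries undergoing any nuclear reaction over step ``dt``."""
    nt = tables or load_nuclear_tables()
    sig = nt.sigma_total(spec.grid.mids)
    return Spectrum(z=spec.z, grid=spec.grid,
                    phi=spec.phi * np.exp(-sig * dt))


# ---------------------------------------------------------------------------
# p -> H elastic kinematics (nonrelativistic equal-mass two-body)

def ph_kinematics(mu_cm, E):
    """Lab direction cosines and kinetic energies of the two outgoing protons.

    ``mu_lab_1 = sqrt((1+mu_cm)/2)``, ``mu_lab_2 = sqrt((1-mu_cm)/2)``,
    ``eps_i = mu_lab_i^2 * E``; energies sum to ``E`` exactly.
    """
    mu_cm = np.asarray(mu_cm, dtype=float)
    mu1 = np.sqrt((1.0 + mu_cm) / 2.0)
    mu2 = np.sqrt((1.0 - mu_cm) / 2.0)
    return (mu1, mu1**2 * E), (mu2, mu2**2 * E)


# ---------------------------------------------------------------------------
# p -> A elastic: Ranft differential cross section + relativistic kinematics

def _momentum_transfer_scale(E, A: float = A_OXYGEN):
    """CM momentum squared [GeV^2/c^2]: s = 2*p_cm^2*(1 - mu_cm)."""
    m1 = PROTON_REST_MEV / 1000.0
    m2 = A * AMU_MEV / 1000.0
    E = np.asarray(E, dtype=float) / 1000.0
    p_lab = np.sqrt((m1 + E) ** 2 - m1**2)
    e_tot = m1 + E + m2
    p_cm = p_lab * m2 / np.sqrt(e_tot**2 - p_lab**2)
    return p_cm**2


def pA_elastic_dcs(E, mu_cm, A: float = A_OXYGEN):
    """Relative differential cross section for elastic p-A scattering (A < 62).

    ``A^1.63 exp(-14.5 s A^0.66) + 1.4 A^0.33 exp(-10 s)`` with the invariant
    momentum transfer ``s`` in (GeV/c)^2.
    """
    if A >= 62:
        raise ValueError("parameterization valid for A < 62")
    s = 2.0 * _momentum_transfer_scale(E, A) * (1.0 - np.asarray(mu_cm, float))
    return (A**1.63 * np.exp(-14.5 * s * A**0.66)
            + 1.4 * A**0.33 * np.exp(-10.0 * s))


def pA_elastic_kinematics(mu_cm, E, A: float = A_OXYGEN):
    """Lab direction cosine and kinetic energy of the elastically scattered proton.

    CM momentum is rotated by ``mu_cm`` and boosted back to the lab frame.
    """
    m1 = PROTON_REST_MEV
    m2 = A * AMU_MEV
    mu_cm = np.asarray(mu_cm, dtype=float)
    E = np.asarray(E, dtype=float)
    p_lab = np.sqrt((m1 + E) ** 2 - m1**2)
    e_tot = m1 + E + m2
    p_cm = p_lab * m2 / np.sqrt(e_tot**2 - p_lab**2)
    beta = p_lab / e_tot                       # boost along z
    gamma = e_tot / np.sqrt(e_tot**2 - p_lab**2)
    p_cm_x = p_cm * np.sqrt(np.clip(1.0 - mu_cm**2, 0.0, None))
    p_cm_z = p_cm * mu_cm
    e_cm = np.sqrt(m1**2 + p_cm**2)
    # inverse boost (CM -> lab): beta_vec . p'_cm = -beta * p_cm_z in the CM
    # convention of a target at rest; equivalently use +beta with E' transform
    e_lab = gamma * (e_cm + beta * p_cm_z)
    p_lab_z = p_cm_z + gamma * beta * (gamma / (gamma + 1.0) * beta * p_cm_z + e_cm)
    p_lab_x = p_cm_x
    eps = e_lab - m1
    mu_lab = p_lab_z / np.sqrt(p_lab_x**2 + p_lab_z**2)
    return mu_lab, eps


def pA_recoil_fraction(E, A: float = A_OXYGEN, n_laguerre: int = 32):
    """Mean fraction of E transferred to the recoil nucleus in p-A elastic."""
    E = np.atleast_1d(np.asarray(E, dtype=float))
    y, w = roots_laguerre(n_laguerre)
    out = np.empty_like(E)
    for i, e in enumerate(E):
        lam = max(14.5 * A**0.66 * 2.0 * float(_momentum_transfer_scale(e, A)), 1e-6)
        x = y / lam                         # x = 1 - mu_cm
        keep = x <= 2.0
        dcs = pA_elastic_dcs(e, 1.0 - x[keep], A)
        wk = w[keep] * np.exp(y[keep]) * dcs
        _, eps = pA_elastic_kinematics(1.0 - x[keep], e, A)
        out[i] = float(np.sum(wk * (e - eps)) / (np.sum(wk) * e))
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# surface-tally secondary spectra

def _tally_add(phi: np.ndarray, grid: EnergyGrid, eps: np.ndarray,
               weight: np.ndarray) -> None:
    """Histogram ``weight`` at energies ``eps`` into density ``phi``."""
    idx = np.searchsorted(grid.edges, eps, side="right") - 1
    ok = (idx >= 0) & (idx < grid.n_bins) & (weight > 0)
    np.add.at(phi, idx[ok], weight[ok] / grid.widths[idx[ok]])


def _transport_factor(eps, length, rt: RangeTable, nt: NuclearTables):
    """(eps_at_plane, attenuation) for a proton travelling ``length`` cm.

    Zero attenuation when the path is negative or exceeds the CSDA range.
    """
    eps = np.asarray(eps, dtype=float)
    length = np.broadcast_to(np.asarray(length, dtype=float), eps.shape)
    reach = rt.csda_range(np.maximum(eps, 0.0))
    ok = (length >= 0.0) & (length <= reach) & (eps > 0.0)
    eps_star = np.zeros_like(eps)
    att = np.zeros_like(eps)
    if np.any(ok):
        eps_star[ok] = rt.energy_after(eps[ok], length[ok])
        att[ok] = np.exp(-nt.sigma_total(np.maximum(eps_star[ok], 1e-3))
                         * length[ok])
    return eps_star, att


def ph_elastic_contribution(zeta: float, intervals, grid: EnergyGrid,
                            range_table: RangeTable | None = None,
                            tables: NuclearTables | None = None,
                            n_mu: int = 16) -> Spectrum:
    """Secondary-proton spectrum at depth ``zeta`` from p-H elastic collisions.

    ``intervals`` is an iterable of ``(t_mid, length, Spectrum)`` source
    slabs at depths below ``zeta``; scattering is isotropic in the CM frame
    (density 1/2 in ``mu_cm``), and each of the two outgoing protons is
    tallied with the surface-crossing weight ``1/mu_lab``.
    """
    rt = range_table or load_range_table()
    nt = tables or load_nuclear_tables()
    mu_nodes, mu_w = roots_legendre(n_mu)
    phi = np.zeros(grid.n_bins)
    mids, widths = grid.mids, grid.widths
    for t_mid, length, spec in intervals:
        if length <= 0 or t_mid >= zeta:
            continue
        mass = spec.phi * widths
        act = mass > 1e-15 * max(mass.sum(), 1e-300)
        if not np.any(act):
            continue
        e_src = mids[act]
        sig_h = nt.nuclear_xs(e_src)[0]
        base = mass[act] * sig_h * length            # (nE,)
        for mu_lab, eps in ph_kinematics(mu_nodes, e_src[:, None]):
            # mu_lab, eps: (nE, n_mu); path to the tally plane
            safe_mu = np.maximum(mu_lab, 1e-12)
            path = (zeta - t_mid) / safe_mu
            eps_star, att = _transport_factor(eps, path, rt, nt)
            wgt = base[:, None] * (mu_w[None, :] / 2.0) * att / safe_mu
            _tally_add(phi, grid, eps_star.ravel(), wgt.ravel())
    return Spectrum(z=zeta, grid=grid, phi=phi)


def pA_elastic_contribution(zeta: float, intervals, grid: EnergyGrid,
                            range_table: RangeTable | None = None,
                            tables: NuclearTables | None = None,
                            A: float = A_OXYGEN,
                            n_laguerre: int = 32) -> Spectrum:
    """Secondary spectrum at ``zeta`` from elastic p-A scattering.

    The normalized differential cross section is sampled with Gauss-Laguerre
    nodes in ``1 - mu_cm`` (the forward peak is nearly exponential there).
    """
    rt = range_table or load_range_table()
    nt = tables or load_nuclear_tables()
    y, w = roots_laguerre(n_laguerre)
    phi = np.zeros(grid.n_bins)
    mids, widths = grid.mids, grid.widths
    for t_mid, length, spec in intervals:
        if length <= 0 or t_mid >= zeta:
            continue
        mass = spec.phi * widths
        act = mass > 1e-15 * max(mass.sum(), 1e-300)
        if not np.any(act):
            continue
        e_src = mids[act]
        sig_a = nt.nuclear_xs(e_src)[1]
        lam = 14.5 * A**0.66 * 2.0 * _momentum_transfer_scale(e_src)  # (nE,)
        x = y[None, :] / np.maximum(lam[:, None], 1e-9)   # 1 - mu_cm, (nE, nq)
        mu_cm = 1.0 - x
        dcs = pA_elastic_dcs(e_src[:, None], mu_cm, A)
        wk = w[None, :] * np.exp(y)[None, :] * dcs
        wk[mu_cm < -1.0] = 0.0
        wk /= np.maximum(wk.sum(axis=1, keepdims=True), 1e-300)  # normalized density
        mu_lab, eps = pA_elastic_kinematics(mu_cm, e_src[:, None], A)
        safe_mu = np.maximum(mu_lab, 1e-12)
        path = (zeta - t_mid) / safe_mu
        eps_star, att = _transport_factor(eps, path, rt, nt)
        wgt = (mass[act] * sig_a * length)[:, None] * wk * att / safe_mu
        _tally_add(phi, grid, eps_star.ravel(), wgt.ravel())
    return Spectrum(z=zeta, grid=grid, phi=phi)


def pA_inelastic_contribution(zeta: float, intervals, grid: EnergyGrid,
                              range_table: RangeTable | None = None,
                              tables: NuclearTables | None = None,
                              n_mu: int = 16, n_eps: int = 24) -> Spectrum:
    """Secondary spectrum at ``zeta`` from nonelastic p-A reactions.

    Requires a single-differential emission table on ``tables``; emission is
    isotropic.  Disabled by default at the driver level.
    """
    rt = range_table or load_range_table()
    nt = tables or load_nuclear_tables()
    if nt.differential_in is None:
        raise ConfigurationError(
            "nonelastic channel enabled without a differential emission table")
    tab = np.asarray(nt.differential_in, dtype=float)
    e_knots = np.unique(tab[:, 0])
    mu_nodes, mu_w = roots_legendre(n_mu)
    fwd = mu_nodes > 0
    phi = np.zeros(grid.n_bins)
    mids, widths = grid.mids, grid.widths
    for t_mid, length, spec in intervals:
        if length <= 0 or t_mid >= zeta:
            continue
        mass = spec.phi * widths
        act = mass > 1e-15 * max(mass.sum(), 1e-300)
        for j in np.where(act)[0]:
            e0 = mids[j]
            sig_in = nt.nuclear_xs(e0)[2]
            if sig_in <= 0:
                continue
            # emission-energy density at e0 from the nearest table knot
            k = e_knots[np.argmin(np.abs(e_knots - e0))]
            rows = tab[tab[:, 0] == k]
            eps_grid = np.linspace(0.0, e0, n_eps + 1)[1:]
            dens = np.interp(eps_grid, rows[:, 1], rows[:, 2], left=0.0, right=0.0)
            tot = np.trapezoid(dens, eps_grid)
            if tot <= 0:
                continue
            dens /= tot
            d_eps = eps_grid[1] - eps_grid[0]
            eps = eps_grid[:, None] * np.ones_like(mu_nodes[fwd])[None, :]
            path = (zeta - t_mid) / mu_nodes[fwd][None, :]
            eps_star, att = _transport_factor(eps, path, rt, nt)
            wgt = (mass[j] * sig_in * length * d_eps
                   * dens[:, None] * (mu_w[fwd][None, :] / 2.0)
                   * att / mu_nodes[fwd][None, :])
            _tally_add(phi, grid, eps_star.ravel(), wgt.ravel())
    return Spectrum(z=zeta, grid=grid, phi=phi)
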