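"""Condensed-history Monte Carlo oracle sharing the solver's physics kernels.

Used only for validation: histories sample the same per-step Gaussian
energy-loss kernels, the same tabulated Moliere deflection kernels on the
same step plan, and the same nuclear removal probabilities as the
deterministic solver.  Because physics inputs are shared, any discrepancy
between the oracle's tallies and the solver's distributions isolates
transport-math errors rather than data differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import angular as ang_mod
from .constants import beta_squared
from .driver import StepPlan, build_step_plan
from .espectra import EnergyGrid
from .materials import (
    Material,
    NuclearTables,
    RangeTable,
    delta_e_max,
    load_nuclear_tables,
    load_range_table,
    water,
    xi,
)


@dataclass
class Tallies:
    """Per-depth histograms with standard errors, plus a depth-dose tally."""

    depths: np.ndarray
    energy_grid: EnergyGrid
    theta_grid: np.ndarray
    spectra: dict = field(default_factory=dict)        # z-index -> (phi, err)
    angular: dict = field(default_factory=dict)        # z-index -> (phi, err)
    radial: dict = field(default_factory=dict)         # z-index -> (r_edges, phi, err)
    depth_dose: np.ndarray | None = None               # MeV per cm per history
    n_histories: int = 0
    alive_fraction: dict = field(default_factory=dict)


def _sample_moliere(params, n, rng):
    """Inverse-CDF sampling of the polar deflection from the step kernel."""
    th = np.concatenate([[0.0], np.geomspace(1e-5, 0.35, 600)])
    pdf = ang_mod.moliere_pdf(th, params)
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (pdf[1:] * th[1:] + pdf[:-1] * th[:-1]) * np.diff(th))])
    cdf *= 2.0 * np.pi
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, th)


def simulate(n_histories: int, e_init: float, seed: int,
             plan: StepPlan | None = None,
             energy_grid: EnergyGrid | None = None,
             tally_depth_indices=None,
             nuclear: bool = False,
             straggling: bool = True,
             scattering: bool = True,
             f: float = 0.05, dt_min: float | None = None,
             source_bin_uniform: bool = False,
             material: Material | None = None,
             range_table: RangeTable | None = None,
             nuclear_tables: NuclearTables | None = None) -> Tallies:
    """Transport ``n_histories`` protons and tally plane crossings.

    Tallies are collected at the plan depths listed in
    ``tally_depth_indices`` (default: every tenth node).  Identical seeds
    give identical tallies.
    """
    rng = np.random.default_rng(seed)
    mat = material or water()
    rt = range_table or load_range_table()
    nt = nuclear_tables or load_nuclear_tables()
    plan = plan or build_step_plan(e_init, f, dt_min, rt)
    if energy_grid is None:
        from .driver import default_params
        from .espectra import build_energy_grid
        p = default_params(e_init)
        energy_grid = build_energy_grid(e_init, p["de_max"], p["de_min"], p["e_s"])
    if tally_depth_indices is None:
        tally_depth_indices = list(range(0, plan.n_steps + 1, 10))
    tally_set = set(int(i) for i in tally_depth_indices)

    n = int(n_histories)
    if source_bin_uniform:
        # share the solver's source representation: uniform over the grid
        # bin containing the initial energy
        i0 = energy_grid.index_of(min(e_init, energy_grid.edges[-1] - 1e-12))
        E = rng.uniform(energy_grid.edges[i0], energy_grid.edges[i0 + 1], n)
    else:
        E = np.full(n, e_init)
    ux = np.zeros(n)
    uy = np.zeros(n)
    uz = np.ones(n)
    x = np.zeros(n)
    y = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    theta_grid = ang_mod.build_theta_grid()
    tal = Tallies(depths=plan.depths, energy_grid=energy_grid,
                  theta_grid=theta_grid, n_histories=n)
    dose = np.zeros(plan.n_steps)

    def record(idx):
        a = alive
        if not np.any(a):
            return
        eg = energy_grid
        counts, _ = np.histogram(E[a], bins=eg.edges)
        phi = counts / n / eg.widths
        err = np.sqrt(counts) / n / eg.widths
        tal.spectra[idx] = (phi, err)
        th = np.arccos(np.clip(uz[a], -1.0, 1.0))
        t_edges = np.concatenate([[0.0], np.sqrt(theta_grid[:-1] * theta_grid[1:]),
                                  [theta_grid[-1]]])
        counts_t, _ = np.histogram(th, bins=t_edges)
        d_omega = 2.0 * np.pi * (np.cos(t_edges[:-1]) - np.cos(t_edges[1:]))
        n_a = a.sum()
        tal.angular[idx] = (counts_t / n_a / d_omega,
                            np.sqrt(counts_t) / n_a / d_omega)
        r = np.sqrt(x[a] ** 2 + y[a] ** 2)
        r_edges = np.linspace(0.0, max(float(r.max()), 1e-6) * 1.05, 41)
        counts_r, _ = np.histogram(r, bins=r_edges)
        area = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)
        tal.radial[idx] = (r_edges, counts_r / n_a / area,
                           np.sqrt(counts_r) / n_a / area)
        tal.alive_fraction[idx] = n_a / n

    if 0 in tally_set:
        record(0)
    for i in range(plan.n_steps):
        if not np.any(alive):
            break
        dt = plan.steps[i]
        a = np.where(alive)[0]
        e_a = E[a]
        # ranged-out protons deposit their remaining energy in this slab
        reach = rt.csda_range(e_a)
        stops = reach <= dt
        if np.any(stops):
            dose[i] += float(e_a[stops].sum()) / n
            alive[a[stops]] = False
            a = a[~stops]
            e_a = e_a[~stops]
        if a.size == 0:
            continue
        e_bar = rt.energy_after(e_a, dt)
        if straggling:
            b2 = beta_squared(e_a)
            var = xi(e_a, mat) * dt * delta_e_max(e_a) * (1.0 - b2 / 2.0)
            e_new = e_bar + rng.standard_normal(a.size) * np.sqrt(var)
        else:
            e_new = e_bar.copy()
        low = e_new <= 0.0
        if np.any(low):
            # truncated-at-zero kernel, renormalized as in the solver:
            # resample the clipped tail inside the physical domain
            for _ in range(10):
                idx = np.where(low)[0]
                if idx.size == 0:
                    break
                e_new[idx] = (e_bar[idx] + rng.standard_normal(idx.size)
                              * np.sqrt(var[idx] if straggling else 0.0))
                low = e_new <= 0.0
            e_new[low] = 1e-6
        dose[i] += float((e_a - e_new).sum()) / n
        E[a] = e_new

        if nuclear:
            p_rm = 1.0 - np.exp(-nt.sigma_total(np.maximum(E[a], 1e-3)) * dt)
            rm = rng.random(a.size) < p_rm
            alive[a[rm]] = False
            a = a[~rm]

        # lateral update with the pre-step direction (t = z approximation)
        tan_pre = np.sqrt(np.clip(1.0 - uz[a] ** 2, 0.0, None)) / np.maximum(uz[a], 1e-9)
        with np.errstate(invalid="ignore"):
            norm_xy = np.sqrt(ux[a] ** 2 + uy[a] ** 2)
        cx = np.where(norm_xy > 0, ux[a] / np.maximum(norm_xy, 1e-300), 0.0)
        cy = np.where(norm_xy > 0, uy[a] / np.maximum(norm_xy, 1e-300), 0.0)
        if scattering and plan.energies[i] > 1.0:
            try:
                params = ang_mod.moliere_params(plan.energies[i], dt, mat)
                omega = _sample_moliere(params, a.size, rng)
            except ang_mod.ThinStepError:
                omega = np.zeros(a.size)
            psi = rng.uniform(0.0, 2.0 * np.pi, a.size)
            # rotate (ux, uy, uz) by omega about a random azimuth
            so, co = np.sin(omega), np.cos(omega)
            sp, cp = np.sin(psi), np.cos(psi)
            u, v, w = ux[a], uy[a], uz[a]
            sint = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
            pole = sint < 1e-10
            safe = np.where(pole, 1.0, sint)
            ux[a] = np.where(pole, so * cp,
                             u * co + so * (u * w * cp - v * sp) / safe)
            uy[a] = np.where(pole, so * sp,
                             v * co + so * (v * w * cp + u * sp) / safe)
            uz[a] = np.where(pole, np.sign(w) * co, w * co - sint * so * cp)
        tan_post = np.sqrt(np.clip(1.0 - uz[a] ** 2, 0.0, None)) / np.maximum(uz[a], 1e-9)
        norm_xy2 = np.sqrt(ux[a] ** 2 + uy[a] ** 2)
        cx2 = np.where(norm_xy2 > 0, ux[a] / np.maximum(norm_xy2, 1e-300), 0.0)
        cy2 = np.where(norm_xy2 > 0, uy[a] / np.maximum(norm_xy2, 1e-300), 0.0)
        x[a] += 0.5 * dt * (tan_pre * cx + tan_post * cx2)
        y[a] += 0.5 * dt * (tan_pre * cy + tan_post * cy2)

        if (i + 1) in tally_set:
            record(i + 1)
    tal.depth_dose = dose / np.maximum(plan.steps, 1e-300)
    return tal
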