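"""Run orchestration: step planning, transport pipeline, dose/LET assembly.

The pipeline mirrors the structure of the solver: (1) plan depth steps so a
proton loses the fraction ``f`` of its energy per step (clamped at a minimal
step near the track end); (2) propagate the energy spectrum and the angular
distribution step by step, applying nuclear attenuation; (3) tally secondary
protons from the nuclear channels on a coarser depth grid; (4) post-process
fluence into depth dose, 3-D Gaussian-beam dose and LET profiles.

All solver paths are deterministic: identical configurations produce
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import angular as ang_mod
from . import lateral as lat_mod
from . import nuclear as nuc_mod
from .constants import MEV_PER_G_TO_GY
from .espectra import (
    EnergyGrid,
    Spectrum,
    build_energy_grid,
    delta_spectrum,
    interpolate_spectrum,
    propagate_spectrum,
)
from .materials import (
    ConfigurationError,
    Material,
    NuclearTables,
    RangeTable,
    load_nuclear_tables,
    load_range_table,
    water,
)
from .scoring import DoseMap, dose_from_spectra, let_averages

# Parameter schedules: linear in the initial energy between the calibrated
# 40 and 220 MeV endpoints, clamped outside.
_SCHEDULE = {
    "dt_min":   (0.005, 0.2),    # cm
    "dtau_max": (0.1, 2.4),      # cm
    "dtau_min": (0.1, 0.8),      # cm
    "de_max":   (0.3, 0.5),      # MeV
    "de_min":   (0.02, 0.1),     # MeV
    "e_s":      (31.0, 175.0),   # MeV
}


def default_params(e_init: float) -> dict:
    """Energy-dependent defaults for step and grid parameters."""
    x = np.clip((e_init - 40.0) / (220.0 - 40.0), 0.0, 1.0)
    out = {k: lo + (hi - lo) * float(x) for k, (lo, hi) in _SCHEDULE.items()}
    out["e_s"] = min(out["e_s"], 0.8 * e_init)
    out["rmax"] = 3.0 if e_init >= 200.0 else 2.0
    return out


@dataclass(frozen=True)
class StepPlan:
    """Coulomb depth grid with fractional-energy-loss steps."""

    depths: np.ndarray       # z_0 = 0 ... z_n [cm]
    energies: np.ndarray     # CSDA energy at each depth [MeV]
    f: float
    dt_min: float

    @property
    def steps(self) -> np.ndarray:
        return np.diff(self.depths)

    @property
    def n_steps(self) -> int:
        return self.depths.size - 1


def build_step_plan(e_init: float, f: float = 0.05, dt_min: float | None = None,
                    range_table: RangeTable | None = None,
                    z_max: float | None = None) -> StepPlan:
    """Depth steps ``dt_i = R(E_i) - R((1-f) E_i)``, clamped at ``dt_min``.

    The plan extends past the CSDA range by a straggling margin so the
    distal falloff is fully covered; terminal steps are uniform ``dt_min``.
    """
    if not (0.0 < f < 1.0):
        raise ConfigurationError("f must lie in (0, 1)")
    rt = range_table or load_range_table()
    dt_min = default_params(e_init)["dt_min"] if dt_min is None else dt_min
    r_full = rt.csda_range(e_init)
    if z_max is None:
        z_max = r_full + max(0.055 * r_full, 0.1)
    depths, energies = [0.0], [e_init]
    E = e_init
    while depths[-1] < z_max - 1e-12:
        dt = rt.csda_range(E) - rt.csda_range((1.0 - f) * E) if E > 0 else dt_min
        dt = max(dt, dt_min)
        depths.append(min(depths[-1] + dt, z_max))
        E = rt.inverse_range(max(r_full - depths[-1], 0.0))
        energies.append(E)
    return StepPlan(depths=np.asarray(depths), energies=np.asarray(energies),
                    f=f, dt_min=dt_min)


@dataclass
class RunConfig:
    """Configuration of one solver run."""

    e_init: float
    source: str = "delta"            # "delta" | "gaussian"
    sigma: float = 0.5               # cm, Gaussian source width
    norm_dose: float = 2.0           # Gy at the entrance (central axis)
    f: float = 0.05
    dt_min: float | None = None
    de_max: float | None = None
    de_min: float | None = None
    e_s: float | None = None
    dtau_max: float | None = None
    dtau_min: float | None = None
    rmax: float | None = None
    kernel: str = "vavilov-first"    # | "vavilov-all" | "normal-only"
    nuclear: str = "elastic-only"    # | "off" | "all"
    # fraction of the energy removed by non-transported nonelastic reactions
    # that is deposited locally: charged fragments, recoils and the emitted
    # proton component stay, neutrons and gammas escape the phantom
    local_deposit_fraction: float = 0.65
    material: Material | None = None
    range_table: RangeTable | None = None
    nuclear_tables: NuclearTables | None = None

    def __post_init__(self):
        if not (1.0 <= self.e_init <= 300.0):
            raise ConfigurationError("e_init outside the supported table range")
        if self.source not in ("delta", "gaussian"):
            raise ConfigurationError(f"unknown source {self.source!r}")
        if self.source == "gaussian" and self.sigma <= 0:
            raise ConfigurationError("gaussian source needs sigma > 0")
        if self.kernel not in ("vavilov-first", "vavilov-all", "normal-only"):
            raise ConfigurationError(f"unknown kernel mode {self.kernel!r}")
        if self.nuclear not in ("off", "elastic-only", "all"):
            raise ConfigurationError(f"unknown nuclear mode {self.nuclear!r}")

    def resolved(self) -> dict:
        d = default_params(self.e_init)
        for k in ("dt_min", "de_max", "de_min", "e_s", "dtau_max", "dtau_min",
                  "rmax"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


@dataclass
class TransportResult:
    """Per-depth fluence data produced by one transport run."""

    config: RunConfig
    plan: StepPlan
    grid: EnergyGrid
    spectra: list                    # primary Spectrum at each plan depth
    theta_bar: np.ndarray            # mean polar angle per depth [rad]
    rho_bar: np.ndarray              # mean lateral displacement [cm]
    angular: list                    # AngularDist per depth
    nuclear_grid: nuc_mod.NuclearStepGrid | None
    secondary: list                  # secondary Spectrum at nuclear nodes
    local_rate: np.ndarray           # step energy balance plus local nuclear
                                     # deposits, per cm of depth [MeV/cm]
    anchors: list = field(default_factory=list)   # (z, Spectrum) composition anchors
    diagnostics: dict = field(default_factory=dict)

    # -- fluence access ------------------------------------------------
    def primary_at(self, z: float, exact: bool = True) -> Spectrum:
        """Primary spectrum at an arbitrary depth.

        With ``exact=True`` (default) the spectrum is recomputed from the
        nearest stored composition anchor, which is as accurate as the
        transport itself; otherwise the energy-shifted interpolation
        between the neighbouring stored spectra is used.
        """
        zs = self.plan.depths
        if not (zs[0] <= z <= zs[-1]):
            raise ValueError(f"depth {z} outside the plan")
        i = int(np.searchsorted(zs, z, side="right")) - 1
        i = min(i, zs.size - 2)
        if z == zs[i]:
            return self.spectra[i].copy()
        if exact and self.anchors:
            za, spec_a = None, None
            for zj, sj in self.anchors:
                if zj <= z:
                    za, spec_a = zj, sj
                else:
                    break
            if za is not None:
                nt_arg = (None if self.config.nuclear == "off"
                          else (self.config.nuclear_tables
                                or load_nuclear_tables()))
                out = propagate_spectrum(
                    spec_a, z - za, "normal", self.config.material,
                    self.config.range_table, nuclear_tables=nt_arg)
                out.z = z
                return out
        return interpolate_spectrum(z, self.spectra[i], self.spectra[i + 1],
                                    self.config.range_table)

    def secondary_at(self, z: float) -> Spectrum:
        if not self.secondary:
            return Spectrum(z=z, grid=self.grid)
        zs = self.nuclear_grid.depths
        zc = float(np.clip(z, zs[0], zs[-1]))
        i = min(int(np.searchsorted(zs, zc, side="right")) - 1, zs.size - 2)
        lo, hi = self.secondary[i], self.secondary[i + 1]
        if lo.integral > 1e-12 and hi.integral > 1e-12:
            # energy-shifted interpolation preserves the Bragg structure of
            # the quasi-primary (forward elastic) component
            spec = interpolate_spectrum(zc, lo, hi, self.config.range_table)
            return Spectrum(z=z, grid=self.grid, phi=spec.phi)
        w = (zc - zs[i]) / (zs[i + 1] - zs[i])
        phi = (1 - w) * lo.phi + w * hi.phi
        return Spectrum(z=z, grid=self.grid, phi=phi)

    def spectrum_at(self, z: float) -> Spectrum:
        prim = self.primary_at(z)
        sec = self.secondary_at(z)
        return Spectrum(z=z, grid=self.grid, phi=prim.phi + sec.phi)


def _transport(config: RunConfig) -> TransportResult:
    mat = config.material or water()
    rt = config.range_table or load_range_table()
    nt = config.nuclear_tables or load_nuclear_tables()
    p = config.resolved()

    plan = build_step_plan(config.e_init, config.f, p["dt_min"], rt)
    grid = build_energy_grid(config.e_init, p["de_max"], p["de_min"], p["e_s"])
    theta_grid = ang_mod.build_theta_grid()

    spectra = [delta_spectrum(grid, config.e_init)]
    ang = ang_mod.delta_angular(theta_grid)
    angular = [ang]
    theta_bar = [0.0]
    rho_bar = [0.0]
    fe_P = fe_C = fe_T = 0.0   # Fermi-Eyges per-axis moments
    local_rate = np.zeros(plan.n_steps)
    removed_energy = {"el_H": 0.0, "el_A": 0.0, "in_A": 0.0}
    stopped_energy = 0.0

    mids, widths = grid.mids, grid.widths
    sig_h, sig_a, sig_i, sig_tot = nt.nuclear_xs(np.maximum(mids, 1e-3))
    recoil_frac = nuc_mod.pA_recoil_fraction(np.maximum(mids, 1.0))

    from .espectra import composed_sigma
    nt_arg = nt if config.nuclear != "off" else None
    anchor, z_anchor = spectra[0], 0.0
    kbar_anchor = config.e_init
    anchors = [(0.0, spectra[0])]
    for i in range(plan.n_steps):
        dt = plan.steps[i]
        z_next = plan.depths[i + 1]
        spec = spectra[-1]
        use_vavilov = (config.kernel == "vavilov-all"
                       or (config.kernel == "vavilov-first" and i == 0))
        mass = spec.phi * widths
        stopping = mass > 0
        stopping &= rt.csda_range(mids) <= dt
        e_stop = float(np.sum(mass[stopping] * mids[stopping]))
        e_before = float(np.sum(mass * mids))
        if use_vavilov:
            new = propagate_spectrum(spec, dt, "vavilov", mat, rt)
            if nt_arg is not None:
                new = Spectrum(z=new.z, grid=grid,
                               phi=new.phi * np.exp(-sig_tot * dt))
            anchor, z_anchor = new, z_next
            anchors.append((z_next, new))
            try:
                kbar_anchor = new.mean_energy
            except Exception:
                kbar_anchor = 0.0
        else:
            # propagate from the anchor with analytically composed widths
            # and the exact CSDA attenuation integral; re-anchor once the
            # composed kernel is wide enough to re-bin without grid noise
            new = propagate_spectrum(anchor, z_next - z_anchor, "normal",
                                     mat, rt, nuclear_tables=nt_arg)
            e_b = rt.energy_after(kbar_anchor, z_next - z_anchor) \
                if kbar_anchor > 0 else 0.0
            if e_b > 0.5:
                sig_c = float(composed_sigma(kbar_anchor, e_b, mat, rt))
                w_loc = widths[grid.index_of(e_b)]
                if sig_c > 2.5 * w_loc:
                    anchor, z_anchor = new, z_next
                    anchors.append((z_next, new))
                    kbar_anchor = e_b
        # energy bookkeeping: snapshot difference minus the (first-order)
        # energy carried away by nuclear removals in this step
        e_after = float(np.sum(new.phi * widths * mids))
        dep = e_before - e_after
        if config.nuclear != "off":
            loss = -np.expm1(-sig_tot * dt)
            e_rem_tot = mass * mids * loss
            with np.errstate(invalid="ignore", divide="ignore"):
                frac_h = np.where(sig_tot > 0, sig_h / sig_tot, 0.0)
                frac_a = np.where(sig_tot > 0, sig_a / sig_tot, 0.0)
                frac_i = np.where(sig_tot > 0, sig_i / sig_tot, 0.0)
            e_h = float(np.sum(e_rem_tot * frac_h))
            e_a = float(np.sum(e_rem_tot * frac_a))
            e_i = float(np.sum(e_rem_tot * frac_i))
            removed_energy["el_H"] += e_h
            removed_energy["el_A"] += e_a
            removed_energy["in_A"] += e_i
            dep -= e_h + e_a + e_i
            # heavy recoils deposit locally; nonelastic energy per the
            # configured local fraction when the channel is not transported
            dep += float(np.sum(e_rem_tot * frac_a * recoil_frac))
            if config.nuclear != "all":
                dep += config.local_deposit_fraction * e_i
        stopped_energy += e_stop
        local_rate[i] = dep / dt
        spectra.append(new)

        # angular step, using the CSDA energy at the step start
        e_step = plan.energies[i]
        d_th = 0.0
        if e_step > 1.0:
            try:
                params = ang_mod.moliere_params(e_step, dt, mat)
                ang = ang_mod.propagate_angular(ang, params)
                d_th = 0.5 * ang_mod.kernel_second_moment(params)
            except ang_mod.ThinStepError:
                pass
        angular.append(ang)
        theta_bar.append(ang.theta_bar)
        # mean lateral displacement from Fermi-Eyges moment accumulation of
        # the same step kernels (exact for Gaussian scattering; the tangent
        # recurrence overestimates it by ignoring azimuthal decorrelation)
        fe_P = fe_P + 2.0 * fe_C * dt + fe_T * dt * dt + d_th * dt * dt / 3.0
        fe_C = fe_C + fe_T * dt + 0.5 * d_th * dt
        fe_T = fe_T + d_th
        rho_bar.append(float(np.sqrt(np.pi * fe_P / 2.0)))

    # ---- nuclear secondaries on the coarse grid ----------------------
    nuc_grid = None
    secondary: list = []
    if config.nuclear != "off":
        nuc_grid = nuc_mod.build_nuclear_grid(
            config.e_init, p["dtau_max"], p["dtau_min"], rt,
            z_max=plan.depths[-1])
        zs = nuc_grid.depths
        src_specs = []
        for zj in zs[:-1]:
            i = min(int(np.searchsorted(plan.depths, zj, side="right")) - 1,
                    plan.depths.size - 2)
            src_specs.append(interpolate_spectrum(
                float(zj), spectra[i], spectra[i + 1], rt)
                if zj != plan.depths[i] else spectra[i])
        for m, zeta in enumerate(zs):
            if m == 0:
                secondary.append(Spectrum(z=0.0, grid=grid))
                continue
            intervals = []
            for j in range(m):
                hi = min(zs[j + 1], zeta)
                if hi <= zs[j]:
                    continue
                # three-point subdivision of the line integral over the
                # collision depth within the coarse nuclear interval
                sub = np.linspace(zs[j], hi, 4)
                for lo_s, hi_s in zip(sub[:-1], sub[1:]):
                    intervals.append((0.5 * (lo_s + hi_s), hi_s - lo_s,
                                      src_specs[j]))
            phi = nuc_mod.ph_elastic_contribution(
                float(zeta), intervals, grid, rt, nt).phi.copy()
            phi += nuc_mod.pA_elastic_contribution(
                float(zeta), intervals, grid, rt, nt).phi
            if config.nuclear == "all":
                phi += nuc_mod.pA_inelastic_contribution(
                    float(zeta), intervals, grid, rt, nt).phi
            secondary.append(Spectrum(z=float(zeta), grid=grid, phi=phi))

    diagnostics = {
        "stopped_energy": stopped_energy,
        "removed_energy": removed_energy,
        "final_fluence": spectra[-1].integral,
    }
    return TransportResult(config=config, plan=plan, grid=grid,
                           spectra=spectra, theta_bar=np.asarray(theta_bar),
                           rho_bar=np.asarray(rho_bar), angular=angular,
                           nuclear_grid=nuc_grid, secondary=secondary,
                           local_rate=local_rate, anchors=anchors,
                           diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# dose assembly

def _idd_profile(res: TransportResult):
    """Planar energy deposition per incident proton [MeV cm^2/g] at plan depths."""
    mat = res.config.material or water()
    rt = res.config.range_table or load_range_table()
    d_prim = dose_from_spectra(res.spectra, mat, rt)
    zs = res.plan.depths
    if res.secondary:
        d_sec = dose_from_spectra(
            [res.secondary_at(float(z)) for z in zs], mat, rt)
    else:
        d_sec = np.zeros_like(zs)
    # close the energy balance: the step operator's exact deposit minus the
    # share the trapezoidal integral of the fluence dose already assigns
    rate = res.local_rate / mat.rho - 0.5 * (d_prim[:-1] + d_prim[1:])
    d_loc = np.zeros_like(zs)
    # local nuclear deposits build up from zero at the surface: the entrance
    # node stays primary-only and the first segment's share moves downstream
    d_loc[-1] = rate[-1]
    d_loc[1:-1] = 0.5 * (rate[:-1] + rate[1:])
    d_loc[1] += 0.5 * rate[0]
    return d_prim + d_sec + d_loc, d_prim, d_sec, d_loc


@dataclass
class DepthDoseResult:
    config: RunConfig
    transport: TransportResult
    dose: DoseMap                 # central-axis depth dose [Gy]
    let_f: np.ndarray             # track-averaged LET [MeV/cm]
    let_d: np.ndarray             # dose-averaged LET [MeV/cm]
    fluence_norm: float           # incident protons per cm^2

    def dose_at(self, z) -> np.ndarray:
        """Depth dose [Gy] at arbitrary depths via spectrum interpolation.

        The primary contribution is rebuilt from the energy-shifted
        interpolated spectrum, which resolves the Bragg-peak shape between
        stored nodes; the secondary and local terms are interpolated
        linearly (they are smooth).
        """
        mat = self.config.material or water()
        rt = self.config.range_table or load_range_table()
        res = self.transport
        z = np.atleast_1d(np.asarray(z, dtype=float))
        d_prim = dose_from_spectra(
            [res.primary_at(float(zi)) for zi in z], mat, rt)
        nodes = res.plan.depths
        d_other = (self.dose.meta["secondary_component"]
                   + self.dose.meta["local_component"])
        out = (d_prim * MEV_PER_G_TO_GY * self.fluence_norm
               + np.interp(z, nodes, d_other))
        return out


def run_depth_dose(config: RunConfig) -> DepthDoseResult:
    """Broad-beam depth dose, LET profiles and fluence spectra."""
    res = _transport(config)
    idd, d_prim, d_sec, d_loc = _idd_profile(res)
    scale = config.norm_dose / (idd[0] * MEV_PER_G_TO_GY)
    dose = DoseMap(z=res.plan.depths, dose=idd * MEV_PER_G_TO_GY * scale,
                   meta={"e_init": config.e_init,
                         "entrance_dose_Gy": config.norm_dose,
                         "fluence_per_cm2": scale,
                         "primary_component": d_prim * MEV_PER_G_TO_GY * scale,
                         "secondary_component": d_sec * MEV_PER_G_TO_GY * scale,
                         "local_component": d_loc * MEV_PER_G_TO_GY * scale})
    rt = config.range_table or load_range_table()
    let_f = np.full(res.plan.depths.size, np.nan)
    let_d = np.full(res.plan.depths.size, np.nan)
    for i, z in enumerate(res.plan.depths):
        spec = res.spectrum_at(float(z))
        if spec.integral > 1e-9:
            let_f[i], let_d[i] = let_averages(spec, rt)
    return DepthDoseResult(config=config, transport=res, dose=dose,
                           let_f=let_f, let_d=let_d, fluence_norm=scale)


@dataclass
class BeamResult:
    config: RunConfig
    transport: TransportResult
    dose: DoseMap                 # (z, r) dose [Gy]
    n_protons: float              # incident protons in the beam


_CHAR_ARG_GRID = np.geomspace(0.05, 2e4, 140)


def _step_char_fns(res: TransportResult):
    """Per-step Moliere characteristic functions and step midpoints."""
    mat = res.config.material or water()
    plan = res.plan
    chars, mids = [], []
    for i in range(plan.n_steps):
        e_step, dt = plan.energies[i], plan.steps[i]
        if e_step <= 1.0:
            continue
        try:
            params = ang_mod.moliere_params(e_step, dt, mat)
        except ang_mod.ThinStepError:
            continue
        chars.append(np.clip(ang_mod.kernel_char_fn(params, _CHAR_ARG_GRID),
                             0.0, None))
        mids.append(0.5 * (plan.depths[i] + plan.depths[i + 1]))
    return chars, np.asarray(mids)


def lateral_profile(res: TransportResult, z: float, r_out: np.ndarray,
                    sigma_beam: float = 0.0,
                    _cache: tuple | None = None) -> np.ndarray:
    """Radial fluence density (unit plane integral) at depth ``z``.

    Built from the product of per-step Moliere characteristic functions
    with their lever arms (exact within independent small-angle steps);
    ``sigma_beam > 0`` folds in a Gaussian source.
    """
    chars, mids = _cache if _cache is not None else _step_char_fns(res)
    lever = np.asarray([z - m if m < z else 0.0 for m in mids])
    width = max(sigma_beam, 0.02)
    q = np.linspace(0.0, 10.0 / width, 360)
    phi = lat_mod.fourier_radial_profile(chars, _CHAR_ARG_GRID, lever, q,
                                         r_out, sigma_beam)
    tot = 2.0 * np.pi * np.trapezoid(phi * r_out, r_out)
    if tot > 0.95:
        phi = phi / tot
    return phi


def run_gaussian_beam(config: RunConfig) -> BeamResult:
    """3-D dose of a narrow Gaussian beam (azimuthally symmetric)."""
    if config.source != "gaussian":
        raise ConfigurationError("run_gaussian_beam needs a gaussian source")
    res = _transport(config)
    p = config.resolved()
    idd, *_ = _idd_profile(res)
    r_grid = lat_mod.build_radial_grid(sigma=config.sigma, rmax=p["rmax"])
    zs = res.plan.depths
    dmap = np.empty((zs.size, r_grid.size))
    cache = _step_char_fns(res)
    for i in range(zs.size):
        phi = lateral_profile(res, float(zs[i]), r_grid, config.sigma,
                              _cache=cache)
        dmap[i] = phi * idd[i]
    entrance = dmap[0, 0]
    scale = config.norm_dose / (entrance * MEV_PER_G_TO_GY)
    dose = DoseMap(z=zs, r=r_grid, dose=dmap * MEV_PER_G_TO_GY * scale,
                   meta={"e_init": config.e_init, "sigma_cm": config.sigma,
                         "entrance_dose_Gy": config.norm_dose,
                         "n_protons": scale})
    return BeamResult(config=config, transport=res, dose=dose, n_protons=scale)


# ---------------------------------------------------------------------------
# detour factor

def detour_factor(e_init: float, f: float = 0.05, dt_min: float | None = None,
                  projection: str = "mean-angle",
                  material: Material | None = None,
                  range_table: RangeTable | None = None) -> float:
    """Projected range over CSDA range from accumulated mean deflections.

    ``projection="mean-angle"`` uses ``cos(theta_bar)`` per step;
    ``"mean-cos"`` uses the fluence-weighted mean of ``cos(theta)``, the
    exact longitudinal projection of the angular distribution.
    """
    mat = material or water()
    rt = range_table or load_range_table()
    r_full = rt.csda_range(e_init)
    plan = build_step_plan(e_init, f, dt_min, rt, z_max=r_full)
    dist = ang_mod.delta_angular(ang_mod.build_theta_grid())
    proj_prev, acc = 1.0, 0.0
    for i in range(plan.n_steps):
        E, dt = plan.energies[i], plan.steps[i]
        if E > 1.0:
            try:
                dist = ang_mod.propagate_angular(
                    dist, ang_mod.moliere_params(E, dt, mat))
            except ang_mod.ThinStepError:
                pass
        if projection == "mean-cos" and not dist.is_delta:
            w = dist.phi * dist.theta
            proj = float(np.trapezoid(w * np.cos(dist.theta), dist.theta)
                         / np.trapezoid(w, dist.theta))
        else:
            proj = float(np.cos(dist.theta_bar))
        acc += 0.5 * (proj_prev + proj) * dt
        proj_prev = proj
    return acc / r_full
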