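"""Dose, LET averages and gamma-index comparison.

Dose is a post-processing step: ``D = (1/rho) * int Phi(E) S(E) dE`` plus any
locally deposited terms the driver bookkeeps (stopped protons, nuclear
recoils).  LET here is the unrestricted electronic stopping power of water.
The gamma index is the standard global criterion with an exhaustive search
on a refined grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .espectra import EmptySpectrumError, Spectrum
from .materials import Material, RangeTable, load_range_table, water


@dataclass
class DoseMap:
    """Central-axis depth dose and optional cylindrical (z, r) dose grid."""

    z: np.ndarray                       # depths [cm]
    dose: np.ndarray                    # D(z) or D(z, r)
    r: np.ndarray | None = None         # radii [cm] when 2-D
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.r is not None:
            self.r = np.asarray(self.r, dtype=float)
            if self.dose.shape != (self.z.size, self.r.size):
                raise ValueError("dose shape must be (n_z, n_r)")
        elif self.dose.shape != self.z.shape:
            raise ValueError("dose shape must match z")

    @property
    def dmax(self) -> float:
        return float(np.max(self.dose))

    @property
    def central_axis(self) -> np.ndarray:
        return self.dose if self.r is None else self.dose[:, 0]


@dataclass(frozen=True)
class GammaReport:
    dd_percent: float
    dta_mm: float
    threshold: float            # fraction of Dmax included
    fail_rate: float            # fraction of included nodes with gamma > 1
    n_included: int
    gamma_mean: float

    def __post_init__(self):
        if not (0.0 <= self.fail_rate <= 1.0):
            raise ValueError("fail rate must lie in [0, 1]")


def effective_stopping(grid, range_table: RangeTable | None = None) -> np.ndarray:
    """Range-consistent bin-averaged stopping power, ``dE_bin / dR_bin``.

    Within a bin the local slowing-down spectrum varies like 1/S, so the
    harmonic bin mean -- which equals the bin width over the range increment
    -- integrates ``Phi*S`` exactly for that shape and keeps the deposited
    energy consistent with the range table.
    """
    rt = range_table or load_range_table()
    dr = np.diff(rt.csda_range(grid.edges))
    return grid.widths / np.maximum(dr, 1e-300)


def dose_from_spectra(spectra, material: Material | None = None,
                      range_table: RangeTable | None = None) -> np.ndarray:
    """Fluence-to-dose conversion, ``(1/rho) int Phi S dE`` per spectrum.

    Returns MeV cm^2/g per incident proton for each spectrum in ``spectra``.
    """
    mat = material or water()
    rt = range_table or load_range_table()
    out = np.empty(len(spectra))
    s_cache: dict[int, np.ndarray] = {}
    for i, spec in enumerate(spectra):
        key = id(spec.grid)
        if key not in s_cache:
            s_cache[key] = effective_stopping(spec.grid, rt)
        out[i] = np.sum(spec.phi * s_cache[key] * spec.grid.widths) / mat.rho
    return out


def let_averages(spec: Spectrum, range_table: RangeTable | None = None):
    """Track-averaged and dose-averaged LET (L_F, L_D) [MeV/cm].

    ``L_F = int(Phi L)/int(Phi)``; ``L_D = int(Phi L^2)/int(Phi L)``.
    """
    rt = range_table or load_range_table()
    mass = spec.phi * spec.grid.widths
    tot = mass.sum()
    if tot <= 0:
        raise EmptySpectrumError("LET of an empty spectrum")
    L = rt.stopping_power(np.maximum(spec.grid.mids, 1e-6))
    m1 = np.sum(mass * L)
    m2 = np.sum(mass * L**2)
    return float(m1 / tot), float(m2 / m1)


# ---------------------------------------------------------------------------
# gamma index

def _refined_axes(map_: DoseMap, factor: int):
    z = map_.z
    zf = np.interp(np.linspace(0, z.size - 1, (z.size - 1) * factor + 1),
                   np.arange(z.size), z)
    if map_.r is None:
        df = np.interp(zf, z, map_.dose)
        return zf, None, df
    r = map_.r
    rf = np.interp(np.linspace(0, r.size - 1, (r.size - 1) * factor + 1),
                   np.arange(r.size), r)
    from scipy.interpolate import RegularGridInterpolator
    itp = RegularGridInterpolator((z, r), map_.dose)
    zz, rr = np.meshgrid(zf, rf, indexing="ij")
    df = itp(np.stack([zz.ravel(), rr.ravel()], axis=1)).reshape(zz.shape)
    return zf, rf, df


def gamma_index(reference: DoseMap, evaluated: DoseMap, dd_percent: float,
                dta_mm: float, threshold: float = 0.01,
                refine: int = 5) -> GammaReport:
    """Global gamma comparison of two dose maps on overlapping grids.

    Nodes of the reference map with dose above ``threshold * Dmax`` are
    compared against the evaluated map searched exhaustively within a
    ``3 * dta`` radius on a ``refine``-times linearly refined grid.
    """
    if (reference.r is None) != (evaluated.r is None):
        raise ValueError("maps must have the same dimensionality")
    dta_cm = dta_mm / 10.0
    dmax = reference.dmax
    dd_abs = dd_percent / 100.0 * dmax
    z_e, r_e, d_e = _refined_axes(evaluated, refine)
    if (z_e[0] > reference.z[-1]) or (z_e[-1] < reference.z[0]):
        raise ValueError("dose grids do not overlap")

    gammas = []
    if reference.r is None:
        pts = [(i,) for i in range(reference.z.size)
               if reference.dose[i] >= threshold * dmax]
        for (i,) in pts:
            dz = z_e - reference.z[i]
            sel = np.abs(dz) <= 3.0 * dta_cm
            if not np.any(sel):
                sel = np.array([np.argmin(np.abs(dz))])
            g2 = ((d_e[sel] - reference.dose[i]) / dd_abs) ** 2 \
                + (dz[sel] / dta_cm) ** 2
            gammas.append(np.sqrt(np.min(g2)))
    else:
        mask = reference.dose >= threshold * dmax
        for i, j in zip(*np.nonzero(mask)):
            dz = z_e - reference.z[i]
            dr = r_e - reference.r[j]
            sz = np.abs(dz) <= 3.0 * dta_cm
            sr = np.abs(dr) <= 3.0 * dta_cm
            if not np.any(sz):
                sz = np.abs(dz) == np.min(np.abs(dz))
            if not np.any(sr):
                sr = np.abs(dr) == np.min(np.abs(dr))
            sub = d_e[np.ix_(sz, sr)]
            g2 = ((sub - reference.dose[i, j]) / dd_abs) ** 2 \
                + (dz[sz][:, None] / dta_cm) ** 2 \
                + (dr[sr][None, :] / dta_cm) ** 2
            gammas.append(np.sqrt(np.min(g2)))
    gammas = np.asarray(gammas)
    return GammaReport(dd_percent=dd_percent, dta_mm=dta_mm,
                       threshold=threshold,
                       fail_rate=float(np.mean(gammas > 1.0)),
                       n_included=gammas.size,
                       gamma_mean=float(np.mean(gammas)))
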