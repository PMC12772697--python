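"""Material data and tabulated physics for proton transport in water.

The solver works from three packaged plain-text tables bundled under
``protonboltz/data``: the electronic stopping power of liquid water (from
which the CSDA range and its inverse are derived at load time) and the
macroscopic nuclear cross sections.  Users may point the loaders at their
own files in the same format (two header lines, whitespace-separated
columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .constants import (
    ELECTRON_REST_MEV,
    K_BETHE,
    PROTON_REST_MEV,
    beta_squared,
)


class TableRangeError(ValueError):
    """Requested energy lies outside the packaged table."""


class ConfigurationError(RuntimeError):
    """A required physics table is missing or inconsistent."""


@dataclass(frozen=True)
class Element:
    symbol: str
    Z: int
    A: float          # g/mol
    w: float          # weight fraction in the material
    k_HF: float = 1.0  # Hartree-Fock correction in the screening angle


@dataclass(frozen=True)
class Material:
    """Composition and bulk properties of a (molecular) material.

    ``Z_molecule`` is the number of electrons per molecule and
    ``A_molecule`` the molar mass, so that ``Z_molecule / A_molecule``
    equals the electrons-per-gram ratio entering the straggling parameter.
    """

    name: str
    rho: float            # g/cm^3
    elements: tuple[Element, ...]
    Z_molecule: float
    A_molecule: float     # g/mol
    I_eV: float           # mean excitation energy

    def __post_init__(self):
        w_sum = sum(e.w for e in self.elements)
        if abs(w_sum - 1.0) > 1e-6:
            raise ValueError(f"weight fractions sum to {w_sum}, not 1")
        if self.rho <= 0:
            raise ValueError("density must be positive")
        if any(e.Z < 1 for e in self.elements):
            raise ValueError("atomic numbers must be >= 1")

    @property
    def z_over_a(self) -> float:
        return self.Z_molecule / self.A_molecule


def water(rho: float = 1.0) -> Material:
    """Liquid water with I = 75 eV."""
    return Material(
        name="water",
        rho=rho,
        elements=(
            Element("H", 1, 1.008, 0.111894, k_HF=1.0),
            Element("O", 8, 15.999, 0.888106, k_HF=1.0),
        ),
        Z_molecule=10.0,
        A_molecule=18.0153,
        I_eV=75.0,
    )


# ---------------------------------------------------------------------------
# stopping power / CSDA range

def _read_table(path) -> np.ndarray:
    return np.loadtxt(path, skiprows=2)


def _data_path(name: str):
    return resources.files("protonboltz") / "data" / name


@dataclass
class RangeTable:
    """S(E), R(E) and the inverse range map for a material.

    The range is obtained by integrating 1/S on a refined grid; below the
    first table node the stopping power is continued as a power law, which
    makes R(0) = 0 exact and the integral finite.
    """

    energies: np.ndarray          # MeV, ascending
    S: np.ndarray                 # MeV/cm
    R: np.ndarray = field(init=False)   # cm
    _logS: PchipInterpolator = field(init=False, repr=False)
    _R_of_E: PchipInterpolator = field(init=False, repr=False)
    _E_of_R: PchipInterpolator = field(init=False, repr=False)
    _p_low: float = field(init=False)

    def __post_init__(self):
        e, s = np.asarray(self.energies, float), np.asarray(self.S, float)
        if e.ndim != 1 or np.any(np.diff(e) <= 0) or np.any(s <= 0):
            raise ConfigurationError("stopping table must be ascending with S > 0")
        self.energies, self.S = e, s
        self._logS = PchipInterpolator(np.log(e), np.log(s), extrapolate=False)
        # low-energy power-law exponent from the first two nodes
        self._p_low = -(np.log(s[1] / s[0]) / np.log(e[1] / e[0]))
        # integrate 1/S on a x4-refined log grid
        ef = np.geomspace(e[0], e[-1], 4 * e.size)
        sf = np.exp(self._logS(np.log(ef)))
        r0 = e[0] / (s[0] * (1.0 + self._p_low))  # analytic below first node
        rf = r0 + np.concatenate(
            [[0.0], np.cumsum(0.5 * (1.0 / sf[1:] + 1.0 / sf[:-1]) * np.diff(ef))]
        )
        self._R_of_E = PchipInterpolator(np.log(ef), rf, extrapolate=False)
        self._E_of_R = PchipInterpolator(rf, ef, extrapolate=False)
        self._r_min = r0
        self._e_min = e[0]
        self.R = self.csda_range(e)

    @staticmethod
    def _as1d(x):
        arr = np.asarray(x, dtype=float)
        return np.atleast_1d(arr), arr.ndim == 0

    # -- S ------------------------------------------------------------
    def stopping_power(self, E):
        """S(E) [MeV/cm]; power-law continuation below the first node."""
        E, scalar = self._as1d(E)
        if np.any(E <= 0):
            raise TableRangeError("stopping power requires E > 0")
        if np.any(E > self.energies[-1]):
            raise TableRangeError(
                f"E beyond table maximum {self.energies[-1]:.1f} MeV"
            )
        low = E < self._e_min
        out = np.empty_like(E)
        if np.any(~low):
            out[~low] = np.exp(self._logS(np.log(E[~low])))
        if np.any(low):
            out[low] = self.S[0] * (E[low] / self._e_min) ** (-self._p_low)
        return float(out[0]) if scalar else out

    # -- R ------------------------------------------------------------
    def csda_range(self, E):
        """CSDA range R(E) [cm]; R(0) = 0."""
        E, scalar = self._as1d(E)
        if np.any(E < 0):
            raise TableRangeError("range requires E >= 0")
        out = np.zeros_like(E)
        low = E < self._e_min
        hi = ~low & (E > 0)
        if np.any(hi):
            out[hi] = self._R_of_E(np.log(E[hi]))
        if np.any(low):
            out[low] = self._r_min * (E[low] / self._e_min) ** (1.0 + self._p_low)
        return float(out[0]) if scalar else out

    def inverse_range(self, R):
        """E such that csda_range(E) = R."""
        R, scalar = self._as1d(R)
        if np.any(R < 0):
            raise TableRangeError("inverse range requires R >= 0")
        out = np.zeros_like(R)
        low = R < self._r_min
        hi = ~low
        if np.any(hi):
            out[hi] = self._E_of_R(R[hi])
        if np.any(low):
            out[low] = self._e_min * (R[low] / self._r_min) ** (1.0 / (1.0 + self._p_low))
        return float(out[0]) if scalar else out

    def energy_after(self, E, t):
        """Mean (CSDA) energy after travelling ``t`` cm; 0 when ranged out."""
        r = self.csda_range(E) - np.asarray(t, dtype=float)
        return self.inverse_range(np.maximum(r, 0.0))


@lru_cache(maxsize=4)
def load_range_table(path: str | None = None) -> RangeTable:
    src = Path(path) if path else _data_path("water_stopping.txt")
    tab = _read_table(src)
    return RangeTable(tab[:, 0], tab[:, 1])


# ---------------------------------------------------------------------------
# straggling parameters

def xi(E, material: Material | None = None):
    """Straggling scale xi(E) [MeV/cm]: 2*pi*re^2*rho*N_A*mc^2*(Z/A)/beta^2."""
    mat = material or water()
    b2 = beta_squared(np.asarray(E, dtype=float))
    return 0.5 * K_BETHE * mat.rho * mat.z_over_a / b2


def delta_e_max(E):
    """Maximum energy transfer to an electron, 2*mc^2*beta^2/(1-beta^2) [MeV]."""
    b2 = beta_squared(np.asarray(E, dtype=float))
    return 2.0 * ELECTRON_REST_MEV * b2 / (1.0 - b2)


# ---------------------------------------------------------------------------
# nuclear cross sections

@dataclass
class NuclearTables:
    """Macroscopic nuclear cross sections [1/cm] on an energy grid.

    Channels: elastic scattering on hydrogen, elastic scattering on the
    heavy constituents (oxygen in water), and nonelastic scattering on the
    heavy constituents.  ``sigma_N`` is their pointwise sum.  Optionally a
    single-differential emission table ``(E, eps, value)`` can be attached
    for the nonelastic channel.
    """

    energies: np.ndarray
    sig_el_H: np.ndarray
    sig_el_A: np.ndarray
    sig_in_A: np.ndarray
    differential_in: np.ndarray | None = None  # (n, 3) rows of (E, eps, value)

    def __post_init__(self):
        for name in ("sig_el_H", "sig_el_A", "sig_in_A"):
            arr = np.asarray(getattr(self, name), float)
            if np.any(arr < 0):
                raise ConfigurationError(f"{name} has negative entries")
            setattr(self, name, arr)
        self.energies = np.asarray(self.energies, float)
        loge = np.log(self.energies)
        self._fh = PchipInterpolator(loge, self.sig_el_H, extrapolate=False)
        self._fa = PchipInterpolator(loge, self.sig_el_A, extrapolate=False)
        self._fi = PchipInterpolator(loge, self.sig_in_A, extrapolate=False)

    @property
    def sigma_N(self) -> np.ndarray:
        return self.sig_el_H + self.sig_el_A + self.sig_in_A

    def _eval(self, f, E):
        E = np.asarray(E, dtype=float)
        ec = np.clip(E, self.energies[0], self.energies[-1])
        return np.clip(f(np.log(ec)), 0.0, None)

    def nuclear_xs(self, E):
        """(sig_el_H, sig_el_A, sig_in_A, sigma_N) at ``E`` [1/cm]."""
        h = self._eval(self._fh, E)
        a = self._eval(self._fa, E)
        i = self._eval(self._fi, E)
        return h, a, i, h + a + i

    def sigma_total(self, E):
        return self.nuclear_xs(E)[3]


@lru_cache(maxsize=4)
def load_nuclear_tables(path: str | None = None) -> NuclearTables:
    src = Path(path) if path else _data_path("water_nuclear.txt")
    try:
        tab = _read_table(src)
    except OSError as exc:  # pragma: no cover
        raise ConfigurationError(f"nuclear table not found: {src}") from exc
    return NuclearTables(tab[:, 0], tab[:, 1], tab[:, 2], tab[:, 3])
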