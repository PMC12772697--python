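"""Regenerate the packaged physics tables for liquid water.

Writes two plain-text tables under src/protonboltz/data/:

* ``water_stopping.txt`` -- electronic stopping power S(E) of liquid water
  for protons, from a Bethe-Bloch evaluation with I = 75 eV.  Shell and
  density-effect corrections are omitted; below 2 MeV the curve is
  continued with a power law fitted to the empirical low-energy slope of
  measured stopping powers (S ~ E^-0.7), which keeps the CSDA integral
  finite and accurate to the few-percent level where it matters least.

* ``water_nuclear.txt`` -- macroscopic nuclear cross sections [1/cm] for
  protons in water: p-H elastic, p-O elastic (the "heavy" channel, oxygen
  dominating), and p-O nonelastic.  The microscopic values [mb] are a
  smooth compilation of published p-p and p-16O measurements/evaluations
  (EXFOR / ICRU 63 level of accuracy); they are converted to macroscopic
  form with the molecular number densities of water.

Run from the repository root:  python scripts/make_tables.py
"""

from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

ME = 0.510998950  # MeV
MP = 938.2720882  # MeV
K = 0.307075      # MeV cm^2/mol
I_EV = 75.0
RHO = 1.0         # g/cm^3
Z_OVER_A = 0.555087  # electrons per gram * (1/N_A) for water
N_A = 6.02214076e23
# molecular composition of water
N_H = RHO * N_A * 0.111894 / 1.008       # H atoms per cm^3
N_O = RHO * N_A * 0.888106 / 15.999      # O atoms per cm^3

E_SWITCH = 2.0    # MeV; below this, power-law continuation
P_LOW = 0.7       # S ~ E^-p below E_SWITCH


def bethe(E):
    gamma = 1.0 + E / MP
    beta2 = 1.0 - 1.0 / gamma**2
    eta = ME / MP
    tmax = 2.0 * ME * beta2 * gamma**2 / (1.0 + 2.0 * gamma * eta + eta**2)
    I = I_EV * 1e-6  # MeV
    arg = 2.0 * ME * beta2 * gamma**2 * tmax / I**2
    return K * Z_OVER_A * RHO / beta2 * (0.5 * np.log(arg) - beta2)


def stopping(E):
    E = np.asarray(E, dtype=float)
    s_hi = bethe(np.maximum(E, E_SWITCH))
    s0 = bethe(E_SWITCH)
    s_lo = s0 * (np.maximum(E, 1e-12) / E_SWITCH) ** (-P_LOW)
    return np.where(E >= E_SWITCH, s_hi, s_lo)


# -- microscopic nuclear cross sections, mb -------------------------------
# p-p elastic (nuclear part; the Coulomb-dominated region below ~10 MeV is
# irrelevant for removal and kept flat).
PP_EL = [
    (1.0, 320.0), (5.0, 320.0), (10.0, 320.0), (15.0, 200.0), (20.0, 150.0),
    (30.0, 95.0), (40.0, 70.0), (50.0, 55.0), (60.0, 46.0), (80.0, 36.0),
    (100.0, 33.0), (120.0, 30.0), (140.0, 28.0), (160.0, 26.5),
    (180.0, 25.5), (200.0, 24.5), (220.0, 24.0), (250.0, 23.5), (300.0, 23.5),
]
# p-16O elastic (nuclear)
PO_EL = [
    (1.0, 700.0), (10.0, 700.0), (20.0, 550.0), (30.0, 450.0), (40.0, 400.0),
    (50.0, 350.0), (70.0, 280.0), (100.0, 210.0), (150.0, 150.0),
    (200.0, 120.0), (250.0, 110.0), (300.0, 105.0),
]
# p-16O nonelastic; threshold near 7 MeV, maximum near 22 MeV
PO_IN = [
    (1.0, 0.0), (5.0, 0.0), (7.0, 0.0), (10.0, 200.0), (12.0, 300.0),
    (15.0, 450.0), (20.0, 520.0), (25.0, 540.0), (30.0, 530.0),
    (40.0, 490.0), (50.0, 460.0), (60.0, 430.0), (80.0, 400.0),
    (100.0, 380.0), (120.0, 360.0), (150.0, 340.0), (180.0, 320.0),
    (200.0, 310.0), (250.0, 300.0), (300.0, 295.0),
]

MB_TO_CM2 = 1e-27


def main():
    out = Path(__file__).resolve().parents[1] / "src" / "protonboltz" / "data"
    out.mkdir(parents=True, exist_ok=True)

    e = np.unique(np.concatenate([
        np.geomspace(0.025, E_SWITCH, 40),
        np.geomspace(E_SWITCH, 300.0, 260),
    ]))
    s = stopping(e)
    with open(out / "water_stopping.txt", "w") as fh:
        fh.write("proton electronic stopping power, liquid water (I=75 eV)\n")
        fh.write("E[MeV] S[MeV/cm]\n")
        for ei, si in zip(e, s):
            fh.write(f"{ei:.6e} {si:.6e}\n")

    eg = np.unique(np.concatenate([
        np.geomspace(1.0, 300.0, 120),
        [x for x, _ in PP_EL + PO_EL + PO_IN],
    ]))

    def interp(table):
        x, y = np.array(table).T
        f = PchipInterpolator(np.log(x), y)
        v = f(np.log(np.clip(eg, x[0], x[-1])))
        return np.clip(v, 0.0, None)

    sig_h = interp(PP_EL) * MB_TO_CM2 * N_H
    sig_a = interp(PO_EL) * MB_TO_CM2 * N_O
    sig_i = interp(PO_IN) * MB_TO_CM2 * N_O
    with open(out / "water_nuclear.txt", "w") as fh:
        fh.write("macroscopic nuclear cross sections, protons in liquid water\n")
        fh.write("E[MeV] sig_el_H[1/cm] sig_el_A[1/cm] sig_in_A[1/cm]\n")
        for row in zip(eg, sig_h, sig_a, sig_i):
            fh.write(" ".join(f"{v:.6e}" for v in row) + "\n")
    print(f"wrote tables to {out}")


if __name__ == "__main__":
    main()
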