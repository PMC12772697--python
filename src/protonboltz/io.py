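"""Plain-text writers for solver outputs.

All outputs are whitespace-separated tables with self-describing headers:
spectra as (E_mid, Phi) per depth, angular distributions as (theta, Phi),
depth dose as (z, D), (z, r) dose grids as a header with the axes followed
by matrix rows, gamma reports and run summaries as key-value text.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .scoring import DoseMap, GammaReport


def write_spectrum(path, spec) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fluence spectrum at z = {spec.z:.6g} cm\n")
        fh.write("# E_mid[MeV] Phi[/MeV/proton]\n")
        for e, p in zip(spec.grid.mids, spec.phi):
            fh.write(f"{e:.6e} {p:.6e}\n")


def write_angular(path, dist) -> None:
    with open(path, "w") as fh:
        fh.write(f"# angular distribution at z = {dist.z:.6g} cm\n")
        fh.write("# theta[deg] Phi[/sr]\n")
        for t, p in zip(np.rad2deg(dist.theta), dist.phi):
            fh.write(f"{t:.6e} {p:.6e}\n")


def write_depth_dose(path, dose_map: DoseMap) -> None:
    if dose_map.r is not None:
        raise ValueError("use write_dose_grid for 2-D maps")
    with open(path, "w") as fh:
        fh.write("# central-axis depth dose\n")
        fh.write("# z[cm] D[Gy]\n")
        for z, d in zip(dose_map.z, dose_map.dose):
            fh.write(f"{z:.6e} {d:.6e}\n")


def write_dose_grid(path, dose_map: DoseMap) -> None:
    if dose_map.r is None:
        raise ValueError("use write_depth_dose for 1-D maps")
    with open(path, "w") as fh:
        fh.write("# cylindrical dose grid D(z, r) [Gy]\n")
        fh.write("# z[cm]: " + " ".join(f"{z:.6e}" for z in dose_map.z) + "\n")
        fh.write("# r[cm]: " + " ".join(f"{r:.6e}" for r in dose_map.r) + "\n")
        for row in dose_map.dose:
            fh.write(" ".join(f"{d:.6e}" for d in row) + "\n")


def read_dose_map(path) -> DoseMap:
    """Read either a depth-dose table or a (z, r) dose grid."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    if lines[1].startswith("# z[cm]:"):
        z = np.array([float(x) for x in lines[1].split(":", 1)[1].split()])
        r = np.array([float(x) for x in lines[2].split(":", 1)[1].split()])
        dose = np.loadtxt(lines[3:])
        return DoseMap(z=z, dose=np.atleast_2d(dose), r=r)
    tab = np.loadtxt(path)
    return DoseMap(z=tab[:, 0], dose=tab[:, 1])


def write_gamma_report(path, report: GammaReport) -> None:
    with open(path, "w") as fh:
        fh.write(f"dd_percent {report.dd_percent}\n")
        fh.write(f"dta_mm {report.dta_mm}\n")
        fh.write(f"threshold {report.threshold}\n")
        fh.write(f"n_included {report.n_included}\n")
        fh.write(f"fail_rate {report.fail_rate:.6f}\n")
        fh.write(f"gamma_mean {report.gamma_mean:.6f}\n")


def write_run_summary(path, config, extras: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in vars(config).items():
            if k in ("material", "range_table", "nuclear_tables"):
                continue
            fh.write(f"{k} {v}\n")
        for k, v in (extras or {}).items():
            fh.write(f"{k} {v}\n")
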