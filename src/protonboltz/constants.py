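"""Physical constants used throughout the solver.

Values follow CODATA 2018 rounded to the precision that matters for
therapeutic proton transport (sub-0.1%).  Energies are in MeV, lengths in
cm, densities in g/cm^3 unless noted otherwise.
"""

# Rest energies [MeV]
ELECTRON_REST_MEV = 0.510998950
PROTON_REST_MEV = 938.2720882
AMU_MEV = 931.49410242  # atomic mass unit

# Classical electron radius [cm]
RE_CM = 2.8179403262e-13

# Avogadro's number [1/mol]
N_AVOGADRO = 6.02214076e23

# Fine-structure constant
ALPHA_FS = 7.2973525693e-3

# Thomas-Fermi constant entering the Moliere screening angle
C_TF = 0.88534

# Euler-Mascheroni constant
EULER_GAMMA = 0.5772156649015329

# 4*pi*N_A*re^2*me*c^2 [MeV cm^2 / mol]; the Bethe stopping-power prefactor
K_BETHE = 0.307075

# Conversion: 1 MeV/g = 1.602176634e-10 Gy
MEV_PER_G_TO_GY = 1.602176634e-10


def beta_squared(E: float, mass: float = PROTON_REST_MEV) -> float:
    """(v/c)^2 of a particle with kinetic energy ``E`` and rest energy ``mass``."""
    gamma = 1.0 + E / mass
    return 1.0 - 1.0 / (gamma * gamma)
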