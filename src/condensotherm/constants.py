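"""Physical constants and unit conventions.

Internal units throughout the package:

================  =========================
length            nm
time              ps
mass              amu
energy            kJ/mol
temperature       K
entropy           J mol^-1 K^-1 (reported)
================  =========================

A convenient identity of this unit system is that 1 amu nm^2 ps^-2 equals
1 kJ/mol (to the precision of the Avogadro constant), so kinetic energies
computed from amu masses and nm/ps velocities are directly molar energies.

All values are CODATA 2018 exact/recommended values.
"""

# Avogadro constant [1/mol]
N_AVOGADRO = 6.02214076e23

# Molar gas constant [J mol^-1 K^-1]
R_GAS = 8.314462618

# Boltzmann constant expressed in internal energy units [kJ mol^-1 K^-1].
# Identical to R/1000; per-molecule and per-mole formulas coincide in this
# unit system.
KB = R_GAS / 1000.0

# Planck constant in internal units [kJ mol^-1 ps]:
# 6.62607015e-34 J s  *  N_A / 1000  *  1e12 ps/s
H_PLANCK = 6.62607015e-34 * N_AVOGADRO / 1000.0 * 1e12

# Coulomb prefactor 1/(4 pi eps0) [kJ mol^-1 nm e^-2]
KE_COULOMB = 138.935458

# Standard atomic masses [amu]
ATOMIC_MASSES = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "FE": 55.845,
    "ZN": 65.38,
    # virtual / dummy sites
    "M": 0.0,
    "X": 0.0,
}

# Mass of one water molecule [amu]
M_WATER = ATOMIC_MASSES["O"] + 2.0 * ATOMIC_MASSES["H"]

# Density of liquid water at ambient conditions [mg/mL == g/cm^3]
WATER_DENSITY = 0.997


def mass_from_name(name: str) -> float:
    """Guess an atomic mass from an atom name (GRO/PDB style).

    Digits are stripped; two-letter element symbols (NA, CL, ...) are tried
    before the one-letter ones so that e.g. ``CL`` is not read as carbon.
    """
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if stripped in ATOMIC_MASSES:
        return ATOMIC_MASSES[stripped]
    if stripped[:2] in ATOMIC_MASSES:
        return ATOMIC_MASSES[stripped[:2]]
    if stripped[0] in ATOMIC_MASSES:
        return ATOMIC_MASSES[stripped[0]]
    raise ValueError(f"unknown element for atom name {name!r}")
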