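"""Element tables and physical constants used across the package.

All internal units are nm, elementary charge and kJ/mol; PDB files
(Angstrom) are converted at the I/O boundary.
"""

from __future__ import annotations

#: Elements the package supports (PET is C/H/O; proteins add N and S).
SUPPORTED_ELEMENTS = frozenset({"C", "H", "O", "N", "S"})

#: Standard atomic weights, g/mol (IUPAC 2021 abridged).
ATOMIC_WEIGHTS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

#: Covalent radii, nm (Cordero-style single-bond values).
COVALENT_RADII = {
    "H": 0.031,
    "C": 0.076,
    "N": 0.071,
    "O": 0.066,
    "S": 0.105,
}

#: van der Waals radii, nm (Bondi).
VDW_RADII = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
}

#: Generic per-element Lennard-Jones parameters (sigma nm, epsilon kJ/mol).
#: Element-based stand-ins in the spirit of common biomolecular force
#: fields; pair terms use Lorentz-Berthelot mixing.
LJ_PARAMS = {
    "H": (0.107, 0.066),
    "C": (0.340, 0.360),
    "N": (0.325, 0.711),
    "O": (0.296, 0.879),
    "S": (0.356, 1.046),
}

#: Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
COULOMB_CONSTANT = 138.935458

#: Boltzmann constant in kJ mol^-1 K^-1 (i.e. the molar gas constant).
KB = 0.00831446261815324

#: Avogadro constant, mol^-1.
AVOGADRO = 6.02214076e23

#: Elementary charge, C.
ELEMENTARY_CHARGE = 1.602176634e-19

#: Vacuum permittivity, C^2 J^-1 m^-1.
VACUUM_PERMITTIVITY = 8.8541878128e-12

#: Relative permittivity of water near 300 K.
WATER_RELATIVE_PERMITTIVITY = 78.5

#: Default covalent-bond perception tolerance (scale on radii sum).
BOND_TOLERANCE = 1.2

#: Hard floor below which two atoms are considered overlapping, nm.
OVERLAP_DISTANCE = 0.03


def debye_length(ionic_strength_molar: float = 0.15,
                 temperature: float = 300.0,
                 epsilon_r: float = WATER_RELATIVE_PERMITTIVITY) -> float:
    """Debye screening length (nm) of a 1:1 electrolyte.

    lambda_D = sqrt(eps_r eps_0 k_B T / (2 N_A e^2 I)) with I in mol/m^3.
    For 0.15 mol/L at 300 K in water this is about 0.78 nm.
    """
    import math

    if ionic_strength_molar <= 0:
        raise ValueError("ionic strength must be positive")
    i_si = ionic_strength_molar * 1000.0  # mol/m^3
    kb_si = 1.380649e-23
    num = epsilon_r * VACUUM_PERMITTIVITY * kb_si * temperature
    den = 2.0 * AVOGADRO * ELEMENTARY_CHARGE ** 2 * i_si
    return math.sqrt(num / den) * 1e9
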