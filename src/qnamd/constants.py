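"""Physical constants, unit conversions and per-element data.

Internal unit system is atomic units throughout (hartree, bohr, electron
mass, hbar = 1).  Angstrom, eV, fs and cm^-1 appear only at I/O boundaries.
"""

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903

HARTREE_PER_EV = 1.0 / 27.211386245988
EV_PER_HARTREE = 27.211386245988

# 1 a.u. of time = 0.02418884254 fs
FS_PER_AUT = 2.4188843265857e-2
AUT_PER_FS = 1.0 / FS_PER_AUT

# hartree -> cm^-1 (wavenumber of a photon with that energy)
WAVENUMBER_PER_HARTREE = 219474.6313632

# electron masses per unified atomic mass unit
AMU_TO_ME = 1822.888486209

# Most-abundant-isotope masses (u), the convention of trajectory codes.
ISOTOPE_MASS_U = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
}

ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8}


def mass_au(symbol: str) -> float:
    """Nuclear mass of the most abundant isotope in electron-mass units."""
    return ISOTOPE_MASS_U[symbol] * AMU_TO_ME
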