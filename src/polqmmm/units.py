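"""Physical constants and unit conversions.

Internal convention: all energies in hartree, lengths in bohr, charges in e,
masses in electron masses, time in atomic time units.  File formats (txyz, prm)
use the Tinker conventions: Angstrom, kcal/mol, degrees.
"""

import math

# CODATA 2018
BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903
HARTREE_PER_KCALMOL = 1.0 / 627.509474063
KCALMOL_PER_HARTREE = 627.509474063
EV_PER_HARTREE = 27.211386245988
KB_HARTREE_PER_K = 3.166811563e-6
AMU_PER_ELECTRON_MASS = 1.0 / 1822.888486209
ELECTRON_MASS_PER_AMU = 1822.888486209
# 1 fs in atomic time units
AU_TIME_PER_FS = 41.341374575751
FS_PER_AU_TIME = 1.0 / AU_TIME_PER_FS

DEG_PER_RAD = 180.0 / math.pi
RAD_PER_DEG = math.pi / 180.0


def mhartree_to_kcalmol(x_mEh: float) -> float:
    """Convert milli-hartree to kcal/mol (0.3 mEh -> 0.188 kcal/mol)."""
    return x_mEh * 1e-3 * KCALMOL_PER_HARTREE
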