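"""Physical constants and unit conversions.

The internal energy unit throughout the package is the wavenumber (cm^-1).
Electric transition dipoles are in Debye, magnetic transition dipoles in
Bohr magnetons, distances in Angstrom, monopole charges in elementary
charges.  Everything that converts between these lives here so the
conversions are written (and unit-tested) exactly once.
"""

from __future__ import annotations

import numpy as np

#: k_B in cm^-1 per Kelvin
KB_CM = 0.695034800
#: 1 eV in cm^-1
EV_CM = 8065.54
#: hc in cm^-1 * cm  (i.e. energy(cm^-1) * wavelength(cm) = 1e7 nm*cm^-1)
NM_CM = 1.0e7
#: Coulomb coupling prefactor: e^2 / (4 pi eps0 * 1 Angstrom) in cm^-1.
#: Two unit charges 1 A apart interact with 116,140 cm^-1.
COULOMB_CM_ANG = 116_140.0
#: 1 Debye in e*Angstrom
DEBYE_E_ANG = 0.2081943
#: dipole-dipole prefactor in cm^-1 for mu in Debye, R in Angstrom:
#: K * DEBYE_E_ANG^2 = 116140 * 0.2081943^2 = 5034 cm^-1 A^3 / D^2
DIPOLE_CM = COULOMB_CM_ANG * DEBYE_E_ANG**2
#: 1 Debye * 1 Bohr magneton in 1e-40 cgs (esu cm * erg/G) units.
#: 1 D = 1e-18 esu cm, 1 mu_B = 0.92740e-20 erg/G.
DEBYE_BOHRMAG_CGS40 = 92.740
#: speed of light in cm/fs (to convert fs time grids to the 1/cm^-1
#: conjugate variable x = 2 pi c t used by the lineshape module)
C_CM_FS = 2.99792458e-5


def wavenumber_to_nm(wavenumber):
    """Convert cm^-1 to nm (and back: the map is an involution)."""
    wavenumber = np.asarray(wavenumber, dtype=float)
    if np.any(wavenumber <= 0):
        raise ValueError("wavenumber must be positive for nm conversion")
    return NM_CM / wavenumber


def nm_to_wavenumber(nm):
    return wavenumber_to_nm(nm)


def ev_to_wavenumber(ev):
    return np.asarray(ev, dtype=float) * EV_CM


def wavenumber_to_ev(wavenumber):
    return np.asarray(wavenumber, dtype=float) / EV_CM


def fs_to_x(t_fs):
    """Map a time in fs to x = 2*pi*c*t (cm), the variable conjugate to
    wavenumber: a phase factor is exp(-i * nu(cm^-1) * x)."""
    return 2.0 * np.pi * C_CM_FS * np.asarray(t_fs, dtype=float)
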