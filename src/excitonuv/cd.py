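"""Matrix-method circular dichroism: rotational strengths from exciton
states, Gaussian band convolution on the wavelength axis, ensemble
averaging and RMSD-based spectrum comparison.

The rotational strength of exciton k combines the intrinsic magnetic
moments of the basis transitions with the origin (coupled-oscillator)
term generated by delocalisation over spatially separated sites:

    R_k = Im(mu_k . m_k)  +  pi * nu_k / 2 * sum_ij c_ki c_kj (R_i - R_j) . (mu_i x mu_j)

in 1e-40 cgs units, with mu in Debye, m in Bohr magnetons, positions in
Angstrom and nu in cm^-1.  The double-difference form of the origin term
makes R_k exactly independent of the coordinate origin; a positive R_k
corresponds to electric and magnetic moments subtending less than 90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import DEBYE_BOHRMAG_CGS40, wavenumber_to_nm

#: pi * nu(cm^-1) * R(A) * mu(D) * mu(D) -> 1e-40 cgs:
#: 1 cm^-1 * 1 A * 1 D^2 = 1e-8 cm * 1e-36 esu^2 cm^2 = 1e-44 cgs = 1e-4 units
_ORIGIN_CGS40 = 1.0e-4


@dataclass
class RotationalLine:
    wavenumber: float
    rotational_strength: float

    @property
    def wavelength(self) -> float:
        return float(wavenumber_to_nm(self.wavenumber))


@dataclass
class CDSpectrum:
    """Band spectrum on a strictly increasing wavelength grid (nm);
    intensity in arbitrary units proportional to delta-epsilon."""

    wavelength: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")

    def write_tsv(self, path, header: str = ""):
        with open(path, "w") as fh:
            fh.write("# excitonuv CD spectrum\n")
            for line in header.splitlines():
                fh.write(f"# {line}\n")
            fh.write("# wavelength_nm\tintensity\n")
            for wl, it in zip(self.wavelength, self.intensity):
                fh.write(f"{wl:.4f}\t{it:.8e}\n")


def rotational_strengths(states, basis) -> list[RotationalLine]:
    """Rotational strengths (1e-40 cgs) of exciton states.

    ``states`` from :func:`excitonuv.hamiltonian.diagonalize`;
    ``basis`` the matching Hamiltonian basis (positions required on each
    basis state for the origin term).
    """
    mus = np.array([b.mu for b in basis])
    mags = np.array([b.mag for b in basis])
    pos = np.array([b.position if b.position is not None else np.zeros(3)
                    for b in basis])
    lines = []
    for st in states:
        c = st.coefficients
        intrinsic = DEBYE_BOHRMAG_CGS40 * float(np.dot(c @ mus, c @ mags))
        # origin term: -(pi nu / 2) sum_ij c_i c_j (R_i - R_j).(mu_i x mu_j)
        cm = c[:, None] * c[None, :]
        cross = np.cross(mus[:, None, :], mus[None, :, :])
        dR = pos[:, None, :] - pos[None, :, :]
        origin = -0.5 * np.pi * st.energy * _ORIGIN_CGS40 * float(
            np.sum(cm * np.sum(dR * cross, axis=-1)))
        lines.append(RotationalLine(st.energy, intrinsic + origin))
    return lines


def default_grid(lo: float = 250.0, hi: float = 320.0,
                 step: float = 0.1) -> np.ndarray:
    return np.arange(lo, hi + 0.5 * step, step)


def convolve_gaussian(lines, fwhm: float = 4.0,
                      grid: np.ndarray | None = None) -> CDSpectrum:
    """Convolve a rotational-strength line spectrum with a Gaussian of the
    given FWHM on the wavelength axis (nm).  Each line contributes a band
    of integrated area proportional to its rotational strength."""
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    if grid is None:
        grid = default_grid()
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    intensity = np.zeros_like(grid, dtype=float)
    for ln in lines:
        wl = ln.wavelength
        intensity += ln.rotational_strength * np.exp(
            -0.5 * ((grid - wl) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    return CDSpectrum(grid.copy(), intensity)


def average_spectra(spectra) -> CDSpectrum:
    """Pointwise mean of CD spectra; spectra on different grids are
    linearly interpolated onto the first spectrum's grid."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    grid = spectra[0].wavelength
    acc = np.zeros_like(grid)
    for sp in spectra:
        if sp.wavelength.shape == grid.shape and np.allclose(sp.wavelength, grid):
            acc += sp.intensity
        else:
            acc += np.interp(grid, sp.wavelength, sp.intensity)
    return CDSpectrum(grid.copy(), acc / len(spectra))


def cd_rmsd(spectrum: CDSpectrum, reference: CDSpectrum) -> float:
    """Root-mean-square deviation over the overlapping wavelength window."""
    lo = max(spectrum.wavelength[0], reference.wavelength[0])
    hi = min(spectrum.wavelength[-1], reference.wavelength[-1])
    if lo >= hi:
        raise ValueError("disjoint wavelength windows")
    mask = (spectrum.wavelength >= lo) & (spectrum.wavelength <= hi)
    wl = spectrum.wavelength[mask]
    a = spectrum.intensity[mask]
    b = np.interp(wl, reference.wavelength, reference.intensity)
    return float(np.sqrt(np.mean((a - b) ** 2)))
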