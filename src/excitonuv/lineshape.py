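"""Spectral densities and second-cumulant lineshape functions.

Each site couples to (a) an overdamped Drude-Lorentz solvent bath
J(w) = 2 lambda w Lambda / (w^2 + Lambda^2) and (b) a set of discrete
(undamped) intramolecular modes with Huang-Rhys factors S_i =
lambda_i / omega_i.  The lineshape function g(t) is the double time
integral of the bath correlation function; optical coherences are
dressed by exp(-g).

Internally time is carried as x = 2*pi*c*t (units cm) so that a phase is
exp(-i nu x) with nu in cm^-1; grids in fs are converted via
:func:`excitonuv.units.fs_to_x`.  Sign conventions: Im g(t) has long-time
slope -lambda_total * t, which places the relaxed (0-0) line of a mode
progression at (vertical energy - lambda).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import KB_CM
from .vibronic import VibMode


@dataclass
class SpectralDensity:
    """Drude-Lorentz part (reorg lambda, cutoff Lambda, both cm^-1) plus
    discrete intramolecular modes."""

    drude_reorg: float = 0.0
    drude_cutoff: float = 85.0
    modes: list[VibMode] = field(default_factory=list)

    def __post_init__(self):
        if self.drude_reorg < 0:
            raise ValueError("Drude reorganization energy must be >= 0")
        if self.drude_cutoff <= 0:
            raise ValueError("Drude cutoff must be > 0")

    @property
    def total_reorg(self) -> float:
        """Total reorganization energy lambda_drude + sum_i lambda_i."""
        return self.drude_reorg + sum(m.reorg_energy for m in self.modes)


def _g_drude(x, reorg, cutoff, T, rtol=1e-8, max_terms=2000):
    """Analytic overdamped g(x) with Matsubara summation.

    g(x) = (2 lambda kT / Lambda^2 - i lambda/Lambda) * (e^-Lx + Lx - 1)
           + 4 lambda Lambda kT * sum_n [e^-vx + vx - 1] / (v (v^2 - L^2))
    with v_n = 2 pi n kT (all quantities in cm^-1, x in cm).
    """
    x = np.asarray(x, dtype=float)
    kT = KB_CM * T
    L = cutoff
    core = np.expm1(-L * x) + L * x
    g = (2.0 * reorg * kT / L**2 - 1j * reorg / L) * core
    scale = max(1.0, float(np.max(np.abs(g))) if g.size else 1.0)
    for n in range(1, max_terms + 1):
        v = 2.0 * np.pi * n * kT
        term = (4.0 * reorg * L * kT / (v * (v**2 - L**2))) * (np.expm1(-v * x) + v * x)
        g = g + term
        if float(np.max(np.abs(term))) < rtol * scale:
            break
    return g


def _g_mode(x, mode: VibMode, T):
    """Discrete-mode g: S [coth(w/2kT)(1-cos wx) + i(sin wx - wx)]."""
    x = np.asarray(x, dtype=float)
    S = mode.huang_rhys
    w = mode.frequency
    if S == 0.0:
        return np.zeros_like(x, dtype=complex)
    if T <= 0:
        coth = 1.0
    else:
        coth = 1.0 / np.tanh(w / (2.0 * KB_CM * T))
    return S * (coth * (1.0 - np.cos(w * x)) + 1j * (np.sin(w * x) - w * x))


@dataclass
class LineshapeFunction:
    """g(t) sampled on an x = 2 pi c t grid (cm), with the generating
    spectral density and temperature retained so g can be re-evaluated on
    arbitrary (e.g. t1+t3) argument arrays."""

    x: np.ndarray
    values: np.ndarray
    sd: SpectralDensity
    temperature: float

    def __call__(self, x):
        return evaluate_g(self.sd, self.temperature, x)


def evaluate_g(sd: SpectralDensity, T: float, x) -> np.ndarray:
    """Evaluate g on an arbitrary array of x = 2 pi c t values (x >= 0)."""
    if T <= 0:
        raise ValueError("temperature must be > 0 K (use a tiny T for T->0)")
    x = np.asarray(x, dtype=float)
    g = np.zeros(x.shape, dtype=complex)
    if sd.drude_reorg > 0:
        g = g + _g_drude(x, sd.drude_reorg, sd.drude_cutoff, T)
    for m in sd.modes:
        g = g + _g_mode(x, m, T)
    return g


def lineshape_g(sd: SpectralDensity, T: float, t_fs) -> LineshapeFunction:
    """g(t) on a time grid in fs (grid must start at 0)."""
    from .units import fs_to_x

    t_fs = np.asarray(t_fs, dtype=float)
    if t_fs[0] != 0:
        raise ValueError("time grid must start at 0")
    x = fs_to_x(t_fs)
    return LineshapeFunction(x, evaluate_g(sd, T, x), sd, T)


def linear_absorption(energies, dipole_strengths, gfuncs, x_grid,
                      apodize: float = 0.1):
    """Linear absorption from sum_e |mu_e|^2 Re FT[e^{-i w_e x - g_e(x)}].

    ``gfuncs`` is one callable per transition.  Returns (nu_grid, sigma)
    with nu in cm^-1.  The FFT uses the same x convention as the 2D
    response module; a cosine tail over the last ``apodize`` fraction of
    the grid suppresses truncation ripple.
    """
    x = np.asarray(x_grid, dtype=float)
    n = x.size
    dx = x[1] - x[0]
    win = np.ones(n)
    ntail = max(1, int(apodize * n))
    win[-ntail:] = 0.5 * (1.0 + np.cos(np.pi * np.arange(ntail) / ntail))
    npad = 4 * n
    # FT convention: spectrum(nu) = Re int dx e^{+i nu x} R(x); for
    # R = e^{-i w x - g} the peak lands at nu = w.  np.fft.fft computes
    # sum R_k e^{-2pi i k j / N}, so evaluate it on the reversed axis.
    nu_rel = -2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(npad, d=dx))
    order = np.argsort(nu_rel)
    nu_rel = nu_rel[order]
    # Each transition's peak sits at nu_rel + w_e; accumulate on a common
    # grid anchored at the first transition.
    common = nu_rel + energies[0]
    total = np.zeros_like(common)
    for w, d2, g in zip(energies, dipole_strengths, gfuncs):
        # computed in the transition's own rotating frame: e^{-g} only
        resp = np.exp(-g(x)) * win
        resp[0] *= 0.5  # trapezoid end-point for the half-Fourier integral
        spec = np.real(np.fft.fftshift(np.fft.fft(resp, n=npad))[order] * dx)
        total += np.interp(common, nu_rel + w, d2 * spec, left=0.0, right=0.0)
    return common, total


# ---------------------------------------------------------------------------
# isotropic orientational averages for four-wave mixing


def _pair_cos(e1, e2):
    return float(np.dot(e1, e2))


def orientational_factor(d1, d2, d3, d4, scheme) -> float:
    """Isotropic four-point orientational average for a pulse-polarization
    scheme.

    ``scheme`` is a four-character string over {x, y} (pulse order =
    interaction order, e.g. "xxxx", "xxyy") or a dict mapping such
    strings to weights (e.g. {"xxxx": 1, "xxyy": -3}).

    For unit molecular dipoles d1..d4 and lab polarizations e1..e4:
    <prod (e_a . d_a)> = [ L_A(4A-B-C) + L_B(4B-A-C) + L_C(4C-A-B) ] / 30
    with A=(d1.d2)(d3.d4), B=(d1.d3)(d2.d4), C=(d1.d4)(d2.d3) and the
    L's the analogous lab-frame cosine products.
    """
    if isinstance(scheme, dict):
        return sum(w * orientational_factor(d1, d2, d3, d4, s)
                   for s, w in scheme.items())
    ds = []
    for d in (d1, d2, d3, d4):
        d = np.asarray(d, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm < 1e-12:
            raise ValueError("zero-length dipole in orientational average")
        if abs(nrm - 1.0) > 1e-6:
            import warnings
            warnings.warn("non-unit dipole normalized in orientational average")
            d = d / nrm
        ds.append(d)
    d1, d2, d3, d4 = ds
    lab = {"x": np.array([1.0, 0.0, 0.0]), "y": np.array([0.0, 1.0, 0.0])}
    try:
        e1, e2, e3, e4 = (lab[c] for c in scheme)
    except (KeyError, ValueError):
        raise ValueError(f"invalid polarization scheme {scheme!r}")
    A = _pair_cos(d1, d2) * _pair_cos(d3, d4)
    B = _pair_cos(d1, d3) * _pair_cos(d2, d4)
    C = _pair_cos(d1, d4) * _pair_cos(d2, d3)
    LA = _pair_cos(e1, e2) * _pair_cos(e3, e4)
    LB = _pair_cos(e1, e3) * _pair_cos(e2, e4)
    LC = _pair_cos(e1, e4) * _pair_cos(e2, e3)
    return (LA * (4 * A - B - C) + LB * (4 * B - A - C)
            + LC * (4 * C - A - B)) / 30.0


#: convenience polarization-combination presets
COMBO_XXXX_M3XXYY = {"xxxx": 1.0, "xxyy": -3.0}
COMBO_XYXY_MXYYX = {"xyxy": 1.0, "xyyx": -1.0}
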