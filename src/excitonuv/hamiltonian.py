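"""Vibronic Frenkel-exciton Hamiltonian: Coulomb couplings between
transition densities, FC-weighted assembly, diagonalization, and
exciton-mixing classification.

Couplings are computed either from transition monopoles (point charges
that reproduce the transition density's electrostatic potential) or, as a
fallback, in the point-dipole approximation.  The vibronic expansion
multiplies the electronic inter-site coupling by the FC amplitudes of the
two vibronic levels involved; vibronic levels on the same site are not
coupled to each other (displaced-oscillator model).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .units import COULOMB_CM_ANG, DIPOLE_CM
from .vibronic import VibMode, VibronicLevel, enumerate_levels, scale_transition

log = logging.getLogger(__name__)

#: coupling classes that can be zeroed, mirroring the Forster-limit
#: strategy (inter-aromatic couplings set to zero) and backbone exclusion
COUPLING_CLASSES = ("TYR-TYR", "PHE-PHE", "TYR-PHE", "AROMATIC-BB")


def coulomb_coupling_monopole(mono_a, mono_b) -> float:
    """Coulomb coupling (cm^-1) between two monopole sets:
    V = K sum_ij q_i q_j / r_ij with q in e, r in A, K = 116,140 cm^-1 A.
    """
    pa = np.array([m["position"] for m in mono_a], dtype=float)
    qa = np.array([m["charge"] for m in mono_a], dtype=float)
    pb = np.array([m["position"] for m in mono_b], dtype=float)
    qb = np.array([m["charge"] for m in mono_b], dtype=float)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    if np.any(d < 1e-9):
        raise ValueError("coincident monopoles between the two sets")
    if d.min() < 0.5:
        log.warning("monopole sets closer than 0.5 A (min %.3f A); "
                    "penetration errors likely", d.min())
    return float(COULOMB_CM_ANG * np.sum(qa[:, None] * qb[None, :] / d))


def dipole_dipole_coupling(mu1, mu2, R) -> float:
    """Point-dipole coupling (cm^-1); mu in Debye, R (vector from site 1
    to site 2) in Angstrom:

    V = 5034 * [mu1.mu2 - 3 (mu1.R^)(mu2.R^)] / |R|^3
    """
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    R = np.asarray(R, dtype=float)
    r = np.linalg.norm(R)
    if r < 1e-9:
        raise ValueError("zero separation between dipoles")
    rh = R / r
    kappa = np.dot(mu1, mu2) - 3.0 * np.dot(mu1, rh) * np.dot(mu2, rh)
    return float(DIPOLE_CM * kappa / r**3)


def electronic_coupling(site_a, label_a, site_b, label_b) -> float:
    """Inter-site electronic coupling, monopole-based when both
    transitions carry monopoles, point-dipole otherwise."""
    tr_a = site_a.transitions[label_a]
    tr_b = site_b.transitions[label_b]
    if tr_a.get("monopoles") and tr_b.get("monopoles"):
        return coulomb_coupling_monopole(tr_a["monopoles"], tr_b["monopoles"])
    return dipole_dipole_coupling(tr_a["mu"], tr_b["mu"],
                                  site_b.origin - site_a.origin)


@dataclass
class SiteBasisState:
    """One FC-scaled vibronic transition of one site."""

    site_index: int
    label: str
    level: VibronicLevel
    energy: float
    mu: np.ndarray
    mag: np.ndarray
    monopoles: list | None = None
    position: np.ndarray | None = None
    residue_type: str = ""

    @property
    def fc(self) -> float:
        return self.level.fc_amplitude


@dataclass
class ExcitonHamiltonian:
    basis: list[SiteBasisState]
    matrix: np.ndarray
    sites: list = field(default_factory=list)

    def __post_init__(self):
        H = np.asarray(self.matrix, dtype=float)
        if not np.allclose(H, H.T, atol=1e-9):
            raise ValueError("Hamiltonian must be symmetric")
        diag = np.array([b.energy for b in self.basis])
        if not np.allclose(np.diag(H), diag, atol=1e-9):
            raise ValueError("diagonal must equal basis energies")
        self.matrix = H

    @property
    def n(self) -> int:
        return len(self.basis)

    def shifted(self, site_shifts) -> "ExcitonHamiltonian":
        """Rigidly shift every vibronic level of site i by site_shifts[i]
        (static-disorder realization); couplings are unchanged."""
        basis = []
        H = self.matrix.copy()
        for k, b in enumerate(self.basis):
            s = float(site_shifts[b.site_index])
            nb = SiteBasisState(b.site_index, b.label, b.level, b.energy + s,
                                b.mu, b.mag, b.monopoles, b.position,
                                b.residue_type)
            basis.append(nb)
            H[k, k] += s
        return ExcitonHamiltonian(basis, H, self.sites)

    # -- plain-text round trip -------------------------------------------
    def save(self, matrix_path, meta_path):
        np.savetxt(matrix_path, self.matrix)
        meta = [{
            "site_index": b.site_index, "label": b.label,
            "quanta": list(b.level.quanta),
            "energy_offset": b.level.energy_offset,
            "fc_amplitude": b.level.fc_amplitude,
            "energy": b.energy, "mu": list(map(float, b.mu)),
            "mag": list(map(float, b.mag)),
            "position": None if b.position is None else list(map(float, b.position)),
            "residue_type": b.residue_type,
        } for b in self.basis]
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, matrix_path, meta_path):
        H = np.atleast_2d(np.loadtxt(matrix_path))
        with open(meta_path) as fh:
            meta = json.load(fh)
        basis = [SiteBasisState(
            m["site_index"], m["label"],
            VibronicLevel(tuple(m["quanta"]), m["energy_offset"],
                          m["fc_amplitude"]),
            m["energy"], np.array(m["mu"]), np.array(m["mag"]),
            None,
            None if m["position"] is None else np.array(m["position"]),
            m["residue_type"]) for m in meta]
        return cls(basis, H)


def _coupling_class(type_a: str, type_b: str) -> str:
    pair = tuple(sorted((type_a, type_b)))
    if pair == ("TYR", "TYR"):
        return "TYR-TYR"
    if pair == ("PHE", "PHE"):
        return "PHE-PHE"
    if pair == ("PHE", "TYR"):
        return "TYR-PHE"
    return "AROMATIC-BB"


def assemble_hamiltonian(sites, vibronic_cutoff: float = 3200.0,
                         zero_classes=(), coupling_threshold: float = 0.0,
                         couplings: dict | None = None,
                         vibronic_labels=("L_b",)) -> ExcitonHamiltonian:
    """Build the FC-weighted vibronic exciton Hamiltonian.

    Each site transition named in ``vibronic_labels`` whose parameter set
    declares modes is expanded into its vibronic manifold (energy cutoff
    in cm^-1 above the 0-0 line); other transitions enter as single
    lines.  Off-diagonal elements between vibronic states on different
    sites are V_electronic * fc_a * fc_b; intra-site elements are zero.

    ``zero_classes`` names coupling classes ("TYR-TYR", "PHE-PHE",
    "TYR-PHE", "AROMATIC-BB") forced to zero (the Forster-limit mode);
    ``coupling_threshold`` additionally zeroes any |V| below it.
    ``couplings`` optionally overrides the electronic coupling for
    specific pairs: {((i, label_i), (j, label_j)): V_cm}.
    """
    basis: list[SiteBasisState] = []
    for i, site in enumerate(sites):
        for label, tr in site.transitions.items():
            modes_spec = getattr(site, "modes", {}).get(label, [])
            if label in vibronic_labels and modes_spec:
                modes = [VibMode(*m) for m in modes_spec]
                levels = enumerate_levels(modes, vibronic_cutoff)
            else:
                levels = [VibronicLevel((), 0.0, 1.0)]
            for lv in levels:
                scaled = scale_transition(tr, lv)
                basis.append(SiteBasisState(
                    i, label, lv, scaled["energy"], scaled["mu"],
                    scaled["mag"], scaled.get("monopoles"),
                    site.origin, site.residue_type))

    n = len(basis)
    H = np.zeros((n, n))
    for k in range(n):
        H[k, k] = basis[k].energy
    elec_cache: dict = {}
    for k in range(n):
        for l in range(k + 1, n):
            a, b = basis[k], basis[l]
            if a.site_index == b.site_index:
                continue  # displaced-oscillator model: no intra-site mixing
            cls_ = _coupling_class(a.residue_type, b.residue_type)
            if cls_ in zero_classes:
                continue
            key = ((a.site_index, a.label), (b.site_index, b.label))
            if couplings and key in couplings:
                v_el = couplings[key]
            elif couplings and (key[1], key[0]) in couplings:
                v_el = couplings[(key[1], key[0])]
            elif key in elec_cache:
                v_el = elec_cache[key]
            else:
                v_el = electronic_coupling(sites[a.site_index], a.label,
                                           sites[b.site_index], b.label)
                elec_cache[key] = v_el
            v = v_el * a.fc * b.fc
            if abs(v) < coupling_threshold:
                v = 0.0
            H[k, l] = H[l, k] = v
    return ExcitonHamiltonian(basis, H, list(sites))


@dataclass
class ExcitonState:
    energy: float
    coefficients: np.ndarray
    mu: np.ndarray
    mag: np.ndarray
    site_weights: np.ndarray  # |c|^2 summed per site
    mixing_class: str = ""


def diagonalize(H: ExcitonHamiltonian) -> list[ExcitonState]:
    """Eigenstates in ascending energy with the deterministic sign
    convention that each eigenvector's largest-magnitude coefficient is
    positive.  Collective dipoles are mu_k = sum_i c_ki mu_i (and
    likewise for the magnetic moments)."""
    evals, evecs = np.linalg.eigh(H.matrix)
    n_sites = 1 + max(b.site_index for b in H.basis)
    mus = np.array([b.mu for b in H.basis])
    mags = np.array([b.mag for b in H.basis])
    states = []
    for k in range(H.n):
        c = evecs[:, k]
        imax = int(np.argmax(np.abs(c)))
        if c[imax] < 0:
            c = -c
        w = np.zeros(n_sites)
        for i, b in enumerate(H.basis):
            w[b.site_index] += c[i] ** 2
        st = ExcitonState(float(evals[k]), c, c @ mus, c @ mags, w)
        st.mixing_class = classify_mixing(st)
        states.append(st)
    return states


def classify_mixing(state: ExcitonState,
                    strong_bounds=(0.707, 0.90),
                    localized_bound: float = 0.999) -> str:
    """Classify exciton delocalisation from the per-site coefficient
    (root-sum-square over a site's vibronic sublevels):

    strong     max site coefficient in [0.707, 0.90]
    weak       in (0.90, 0.999)
    localized  >= 0.999
    """
    cmax = float(np.sqrt(state.site_weights.max()))
    if cmax >= localized_bound:
        return "localized"
    if cmax <= strong_bounds[1]:
        return "strong"
    return "weak"
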