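"""Chromophore geometry: cyclic-dipeptide conformers, PDB input,
transition-dipole frames on aromatic rings, dihedral and inter-dipole
angles.

The cyclic dipeptides cyclo(Pro-Tyr) (cPY) and cyclo(Tyr-Tyr) (cYY) are
built from fixed internal coordinates: a diketopiperazine (DKP) six-ring
in a boat pucker with standard amide bond lengths, L-configured side
chains placed by the chi1 (N-CA-CB-CG) and chi2 (CA-CB-CG-CD1) torsions.
Conformers are conventionally named by their Tyr chi1 angles, e.g.
cYY_300_60.  The builder is deterministic and force-field free; it is a
model geometry, not an energy-minimised one.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# basic vector geometry


def _unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees in (-180, 180], IUPAC convention
    (looking down p1->p2, positive clockwise rotation of p3 w.r.t. p0)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("undefined dihedral: collinear atoms")
    m1 = np.cross(n1, _unit(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return math.degrees(math.atan2(y, x))


def chi1_dihedral(n, ca, cb, cg) -> float:
    """chi1 = N-CA-CB-CG torsion mapped to [0, 360) degrees."""
    return dihedral(n, ca, cb, cg) % 360.0


def place_atom(a, b, c, bond: float, angle: float, tors: float) -> np.ndarray:
    """NeRF placement: position a new atom at distance ``bond`` from c,
    angle ``angle`` (deg) to b-c, torsion ``tors`` (deg) about a-b-c."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle)
    tor = math.radians(tors)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(ang),
                  bond * math.sin(ang) * math.cos(tor),
                  -bond * math.sin(ang) * math.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def tdm_angle_vectors(u, v) -> float:
    """Acute angle (deg, in [0, 90]) between two dipole lines; sign of
    either vector is immaterial."""
    cu, cv = _unit(u), _unit(v)
    c = abs(float(np.dot(cu, cv)))
    return math.degrees(math.acos(min(1.0, c)))


# ---------------------------------------------------------------------------
# chromophore sites


@dataclass
class ChromophoreSite:
    """A residue-attached chromophore: a local right-handed orthonormal
    frame plus its electronic transitions.

    ``transitions`` maps a label (L_b, L_a, B_a, B_b, npi*, pipi*) to a
    dict with keys energy (cm^-1), mu (Debye, global frame), mag
    (Bohr magnetons, global frame; may be zero) and optional monopoles
    (list of {'position': A global, 'charge': e}).
    """

    residue_id: str
    residue_type: str  # TYR, PHE or AMIDE
    origin: np.ndarray
    axes: np.ndarray  # rows x, y, z
    transitions: dict = field(default_factory=dict)
    atoms: dict = field(default_factory=dict)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-10):
            raise ValueError("site axes must be orthonormal")
        for label, tr in self.transitions.items():
            mono = tr.get("monopoles")
            if mono:
                q = sum(m["charge"] for m in mono)
                if abs(q) > 1e-9:
                    raise ValueError(
                        f"monopoles of {label} carry net charge {q:g}")

    def to_global(self, local_vec) -> np.ndarray:
        """Rotate a local-frame vector into the global frame."""
        return np.asarray(local_vec, dtype=float) @ self.axes

    def point_to_global(self, local_point) -> np.ndarray:
        return self.origin + self.to_global(local_point)


def place_transition_frame(ring_atoms: dict) -> tuple[np.ndarray, np.ndarray]:
    """Build the aromatic-ring frame: origin = ring centroid, x = centroid
    -> CZ direction projected into the best-fit ring plane, z = ring
    normal with sign fixed by the CD1-before-CD2 ordering, y = z cross x.

    ``ring_atoms`` maps atom names (CG, CD1, CD2, CE1, CE2, CZ) to
    coordinates.  Returns (origin, axes) with axes rows (x, y, z).
    """
    names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    missing = [n for n in names if n not in ring_atoms]
    if missing:
        raise ValueError(f"ring atoms missing: {missing}")
    P = np.array([ring_atoms[n] for n in names], dtype=float)
    centroid = P.mean(axis=0)
    Q = P - centroid
    # best-fit plane normal = smallest singular vector
    _, s, vt = np.linalg.svd(Q)
    if s[1] < 1e-8:
        raise ValueError("degenerate (collinear) ring")
    z = vt[2]
    # fix the normal sign from the atom ordering CG -> CD1 -> CE1 (a
    # consistent circulation of the ring); a mirrored ring flips z
    circ = np.cross(ring_atoms["CD1"] - np.asarray(ring_atoms["CG"]),
                    np.asarray(ring_atoms["CE1"]) - np.asarray(ring_atoms["CD1"]))
    if np.dot(z, circ) < 0:
        z = -z
    x = np.asarray(ring_atoms["CZ"], dtype=float) - centroid
    x = x - np.dot(x, z) * z
    x = _unit(x)
    y = np.cross(z, x)
    return centroid, np.vstack([x, y, z])


# ---------------------------------------------------------------------------
# cyclic dipeptide builder

#: internal-coordinate table (bond A, angle deg) for the heavy atoms we
#: place; values are standard peptide/aromatic geometry.
_BOND = {"N-CA": 1.455, "CA-C": 1.525, "C-N": 1.335, "C-O": 1.230,
         "CA-CB": 1.530, "CB-CG": 1.510, "CAR": 1.390, "CZ-OH": 1.375}


@dataclass(frozen=True)
class ConformerSpec:
    """Which cyclic dipeptide to build and the Tyr side-chain torsions."""

    peptide: str  # "cPY" or "cYY"
    chi1: tuple[float, ...]
    chi2: tuple[float, ...] = ()

    def __post_init__(self):
        if self.peptide not in ("cPY", "cYY"):
            raise ValueError(f"unknown peptide type {self.peptide!r}")
        n_tyr = 1 if self.peptide == "cPY" else 2
        if len(self.chi1) != n_tyr:
            raise ValueError(f"{self.peptide} needs {n_tyr} chi1 value(s)")
        # default chi2 = 120 deg: with the idealized C-boat ring below this
        # reproduces the known inter-Tyr TDM-angle pattern of the cYY
        # conformer family (near-parallel for 60_60, 50-80 deg for
        # 300_60/300_300)
        chi2 = self.chi2 if self.chi2 else (120.0,) * n_tyr
        object.__setattr__(self, "chi2", tuple(c % 360.0 for c in chi2))
        object.__setattr__(self, "chi1", tuple(c % 360.0 for c in self.chi1))

    @property
    def name(self) -> str:
        return "_".join([self.peptide] + [f"{c:.0f}" for c in self.chi1])


#: boat pucker amplitude (A): displacement of the two carbonyl carbons
#: above the N1-CA1-N2-CA2 base plane
_PUCKER = 0.55


def _dkp_ring() -> dict:
    """Six-membered diketopiperazine ring N1 CA1 C1 N2 CA2 C2 in a boat
    pucker, built from fixed internal coordinates via least-squares ring
    closure (deterministic: fixed initial guess, no randomness).

    The boat form used displaces the two carbonyl carbons to the same
    side of the N1-CA1-N2-CA2 base plane; together with the chi2 default
    this reproduces the characteristic inter-Tyr transition-dipole angle
    pattern of the cYY conformers.
    """
    from scipy.optimize import least_squares

    order = ["N1", "CA1", "C1", "N2", "CA2", "C2"]
    bonds = [_BOND["N-CA"], _BOND["CA-C"], _BOND["C-N"],
             _BOND["N-CA"], _BOND["CA-C"], _BOND["C-N"]]
    # interior angles at N (amide), CA, C (carbonyl)
    angles = [126.0, 111.0, 118.0, 126.0, 111.0, 118.0]
    flag = (2, 5)           # C1, C2 displaced
    base_idx = [0, 1, 3, 4]  # N1, CA1, N2, CA2 base plane

    mean_b = float(np.mean(bonds))
    pts = np.array([[mean_b * math.cos(math.pi / 3 * i),
                     mean_b * math.sin(math.pi / 3 * i), 0.0]
                    for i in range(6)])
    for i in flag:
        pts[i, 2] = 0.3

    def resid(x):
        p = x.reshape(6, 3)
        out = []
        for i in range(6):
            out.append(np.linalg.norm(p[(i + 1) % 6] - p[i]) - bonds[i])
        for i in range(6):
            a, b, c = p[(i - 1) % 6], p[i], p[(i + 1) % 6]
            v1, v2 = _unit(a - b), _unit(c - b)
            ang = math.degrees(math.acos(np.clip(np.dot(v1, v2), -1, 1)))
            out.append(0.2 * (ang - angles[i]))
        base = [p[j] for j in base_idx]
        ctr = np.mean(base, axis=0)
        nrm = _unit(np.cross(base[1] - base[0], base[2] - base[0]))
        out.append(2.0 * (np.dot(p[flag[0]] - ctr, nrm) - _PUCKER))
        out.append(2.0 * (np.dot(p[flag[1]] - ctr, nrm) - _PUCKER))
        out.append(2.0 * np.dot(p[base_idx[3]] - ctr, nrm))  # planar base
        return out

    sol = least_squares(resid, pts.ravel(), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return dict(zip(order, sol.x.reshape(6, 3)))


def _attach_tyr_sidechain(atoms: dict, prefix: str, n, ca, c_prev_for_ref,
                          chi1: float, chi2: float):
    """Place CB..OH of a tyrosine side chain on residue atoms.

    The L-configuration is selected by placing CB with a torsion relative
    to the ring path such that H would complete the tetrahedron.
    """
    c_own = atoms[prefix + "C"]
    # CB: tetrahedral on CA; torsion chosen off the C(own)-N-CA path.
    # +122 deg selects the L (S) configuration at CA.
    cb = place_atom(c_own, n, ca, _BOND["CA-CB"], 110.5, 122.0)
    cg = place_atom(n, ca, cb, _BOND["CB-CG"], 113.8, chi1)
    cd1 = place_atom(ca, cb, cg, _BOND["CAR"], 120.9, chi2)
    # aromatic ring: planar hexagon continuing from CD1
    cd2 = place_atom(ca, cb, cg, _BOND["CAR"], 120.9, chi2 + 180.0)
    ce1 = place_atom(cb, cg, cd1, _BOND["CAR"], 120.0, 180.0)
    ce2 = place_atom(cb, cg, cd2, _BOND["CAR"], 120.0, 180.0)
    cz = place_atom(cg, cd1, ce1, _BOND["CAR"], 120.0, 0.0)
    oh = place_atom(cd1, ce1, cz, _BOND["CZ-OH"], 120.0, 180.0)
    for nm, p in [("CB", cb), ("CG", cg), ("CD1", cd1), ("CD2", cd2),
                  ("CE1", ce1), ("CE2", ce2), ("CZ", cz), ("OH", oh)]:
        atoms[prefix + nm] = p


def build_cyclic_dipeptide(spec: ConformerSpec) -> dict:
    """Build a cPY or cYY conformer.  Returns {atom_name: xyz} with atom
    names prefixed by residue ("1:N", "1:CA", ... "2:OH").

    Residue 1 is Pro for cPY (only backbone atoms are placed; the
    pyrrolidine ring carries no near-UV chromophore) and Tyr otherwise;
    residue 2 is always Tyr.
    """
    ring = _dkp_ring()
    atoms = {
        "1:N": ring["N1"], "1:CA": ring["CA1"], "1:C": ring["C1"],
        "2:N": ring["N2"], "2:CA": ring["CA2"], "2:C": ring["C2"],
    }
    # carbonyl oxygens, trans to the ring nitrogens, in the amide plane
    atoms["1:O"] = place_atom(ring["CA1"], ring["N2"], ring["C1"],
                              _BOND["C-O"], 122.5, 180.0)
    atoms["2:O"] = place_atom(ring["CA2"], ring["N1"], ring["C2"],
                              _BOND["C-O"], 122.5, 180.0)

    tyr_residues = [2] if spec.peptide == "cPY" else [1, 2]
    for i, res in enumerate(tyr_residues):
        pre = f"{res}:"
        _attach_tyr_sidechain(atoms, pre, atoms[pre + "N"], atoms[pre + "CA"],
                              None, spec.chi1[i], spec.chi2[i])
    return atoms


def conformer_sites(atoms: dict, params: dict | None = None,
                    include_backbone: bool = True) -> list[ChromophoreSite]:
    """Build ChromophoreSites (Tyr rings and backbone amides) from a
    cyclic-dipeptide atom dict produced by :func:`build_cyclic_dipeptide`.

    ``params`` maps residue type (TYR, AMIDE) to a parameter dict as
    produced by :mod:`excitonuv.fixtures`; when given, transitions are
    attached in the global frame.
    """
    sites = []
    for res in (1, 2):
        pre = f"{res}:"
        ring = {nm: atoms[pre + nm] for nm in
                ("CG", "CD1", "CD2", "CE1", "CE2", "CZ") if pre + nm in atoms}
        if len(ring) == 6:
            origin, axes = place_transition_frame(ring)
            site = ChromophoreSite(f"A{res}", "TYR", origin, axes,
                                   atoms={k: atoms[pre + k] for k in
                                          ("N", "CA", "CB", "CG", "CZ", "OH")
                                          if pre + k in atoms})
            if params and "TYR" in params:
                attach_transitions(site, params["TYR"])
            sites.append(site)
        if include_backbone:
            site = amide_site(f"A{res}b", atoms[pre + "C"], atoms[pre + "O"],
                              atoms[f"{1 + res % 2}:N"])
            if params and "AMIDE" in params:
                attach_transitions(site, params["AMIDE"])
            sites.append(site)
    return sites


def amide_site(residue_id: str, c, o, n) -> ChromophoreSite:
    """Backbone amide chromophore frame: origin at the carbonyl C,
    x along C=O, z normal to the O=C-N plane."""
    c, o, n = (np.asarray(p, dtype=float) for p in (c, o, n))
    x = _unit(o - c)
    z = np.cross(x, _unit(n - c))
    z = _unit(z)
    y = np.cross(z, x)
    return ChromophoreSite(residue_id, "AMIDE", c, np.vstack([x, y, z]),
                           atoms={"C": c, "O": o, "N": n})


def attach_transitions(site: ChromophoreSite, param: dict):
    """Rotate a parameter file's local-frame transitions into the global
    frame of ``site`` (see :mod:`excitonuv.fixtures` for the schema)."""
    for label, tr in param["transitions"].items():
        entry = {
            "energy": float(tr["energy"]),
            "mu": site.to_global(tr["mu"]),
            "mag": site.to_global(tr.get("mag", (0.0, 0.0, 0.0))),
        }
        if tr.get("monopoles"):
            entry["monopoles"] = [
                {"position": site.point_to_global(m["position"]),
                 "charge": float(m["charge"])}
                for m in tr["monopoles"]]
        site.transitions[label] = entry
    # modes/origin metadata travel with the site for vibronic expansion
    site.modes = {lbl: [tuple(m) for m in tr.get("modes", [])]
                  for lbl, tr in param["transitions"].items()}


def tdm_angle(site_a: ChromophoreSite, label_a: str,
              site_b: ChromophoreSite, label_b: str) -> float:
    """Acute angle between the electric TDM lines of two transitions."""
    mu_a = site_a.transitions[label_a]["mu"]
    mu_b = site_b.transitions[label_b]["mu"]
    if np.linalg.norm(mu_a) < 1e-12 or np.linalg.norm(mu_b) < 1e-12:
        raise ValueError("zero-length transition dipole")
    return tdm_angle_vectors(mu_a, mu_b)


# ---------------------------------------------------------------------------
# PDB input

_RING_ATOMS = {"TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
               "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")}


def read_pdb(path, all_models: bool = False,
             include_backbone: bool = True):
    """Read TYR/PHE rings and backbone amides from a PDB file.

    Returns a list of ChromophoreSite lists, one per MODEL (a single-model
    file yields a one-element list unless ``all_models`` is False, in
    which case the first model's site list is returned directly as a
    list).  Residues with missing ring atoms are skipped with a warning.
    Altloc A is preferred; hydrogens are ignored.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model_sites = []
    for model in structure:
        sites = []
        for chain in model:
            residues = [r for r in chain if r.id[0] == " "]
            for i, res in enumerate(residues):
                rname = res.get_resname().strip()
                rid = f"{chain.id}{res.id[1]}"
                if rname in _RING_ATOMS:
                    try:
                        ring = {a: res[a].get_coord().astype(float)
                                for a in _RING_ATOMS[rname]}
                    except KeyError:
                        log.warning("skipping %s %s: missing ring atoms",
                                    rname, rid)
                        continue
                    origin, axes = place_transition_frame(ring)
                    site = ChromophoreSite(rid, rname, origin, axes, atoms=ring)
                    if "OH" in res:
                        site.atoms["OH"] = res["OH"].get_coord().astype(float)
                    for a in ("N", "CA", "CB"):
                        if a in res:
                            site.atoms[a] = res[a].get_coord().astype(float)
                    sites.append(site)
                if include_backbone and "C" in res and "O" in res:
                    # amide group C(=O)-N with the next residue's N
                    if i + 1 < len(residues) and "N" in residues[i + 1]:
                        n_at = residues[i + 1]["N"].get_coord().astype(float)
                        sites.append(amide_site(
                            rid + "b", res["C"].get_coord().astype(float),
                            res["O"].get_coord().astype(float), n_at))
        model_sites.append(sites)
        if not all_models:
            return sites
    if not model_sites:
        warnings.warn(f"no models found in {path}")
        return []
    return model_sites


def write_pdb(atoms: dict, path, resname_map=None):
    """Write a cyclic-dipeptide atom dict as a minimal PDB file."""
    lines = ["REMARK generated by excitonuv"]
    serial = 1
    for name, xyz in atoms.items():
        res, at = name.split(":")
        resname = (resname_map or {}).get(int(res), "TYR")
        element = at[0]
        lines.append(
            f"ATOM  {serial:5d} {at:<4s}{resname:>4s} A{int(res):4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            f"          {element:>2s}")
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
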