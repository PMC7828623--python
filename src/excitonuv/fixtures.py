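"""Synthetic test inputs: chromophore parameter files, cyclic-dipeptide
conformer sets, a toy multi-aromatic protein PDB, multi-model (NMR-like)
variants, reference CD curves and MD-like snapshot shift tables.

Every numeric parameter carries a provenance tag: "reported" values are
taken from published near-UV spectroscopy of phenol/Tyr/Phe; "default"
values are this package's own choices where no number is published
(overridable by the user); "synthetic" marks stand-ins constructed here
(e.g. two-point monopole sets that reproduce a dipole).
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from . import geometry
from .geometry import ConformerSpec, build_cyclic_dipeptide, write_pdb

#: oscillator strength f = F_OSC * nu(cm^-1) * |mu(D)|^2
F_OSC = 4.702e-7

#: the nine conformers named by Tyr chi1 angle(s)
DIPEPTIDE_NAMES = (
    "cPY_60", "cPY_180", "cPY_300",
    "cYY_60_60", "cYY_180_60", "cYY_180_180",
    "cYY_300_60", "cYY_300_180", "cYY_300_300",
)


def _mu_from_f(f: float, energy: float) -> float:
    """|mu| in Debye from oscillator strength and transition energy."""
    return math.sqrt(f / (F_OSC * energy))


def _dipole_monopoles(mu_local, half_sep: float = 0.7):
    """Two-point monopole set reproducing an electric TDM (synthetic).

    Charges +-q at +-half_sep along the dipole direction with
    q = |mu| * 0.2081943 / (2 * half_sep) e."""
    mu_local = np.asarray(mu_local, dtype=float)
    m = np.linalg.norm(mu_local)
    if m < 1e-12:
        return []
    d = mu_local / m
    q = m * 0.2081943 / (2.0 * half_sep)
    return [{"position": list(+half_sep * d), "charge": +q},
            {"position": list(-half_sep * d), "charge": -q}]


def make_parameter_file(chromophore: str, path=None,
                        with_monopoles: bool = True) -> dict:
    """Parameter set for TYR, PHE, AMIDE or PHENOL (a gas-phase fixture).

    Local frames: aromatic sites have x along ring-centroid -> CZ
    (towards OH in Tyr), z the ring normal; amides have x along C=O,
    z normal to the O=C-N plane.  The L_b electric TDM lies in-plane
    perpendicular to x, L_a parallel to x (a standing default: these
    orientations are data, not code).
    """
    chromophore = chromophore.upper()
    if chromophore == "TYR":
        e_lb = 34_965.0
        tr = {
            "L_b": {
                "energy": e_lb,
                "mu": [0.0, _mu_from_f(0.020, e_lb), 0.0],
                "mag": [0.0, 0.0, 0.0],
                "modes": [[800.0, 990.0, "u"], [1250.0, 375.0, "v"]],
                "provenance": {
                    "energy": "reported (0-0, solution Tyr)",
                    "mu": "magnitude from reported phenol f=0.020; "
                          "orientation: default",
                    "mag": "default: not printed in source parameters",
                    "modes": "u frequency/reorg reported; v frequency "
                             "reported, v reorg default S_v=0.3",
                },
            },
            "L_a": {"energy": 46_941.0,
                    "mu": [_mu_from_f(0.132, 46_941.0), 0.0, 0.0],
                    "mag": [0.0, 0.0, 0.0],
                    "provenance": {"energy": "reported phenol 5.82 eV",
                                   "mu": "reported f; orientation default"}},
            "B_a": {"energy": 54_039.0,
                    "mu": [_mu_from_f(0.636, 54_039.0), 0.0, 0.0],
                    "mag": [0.0, 0.0, 0.0],
                    "provenance": {"energy": "reported phenol 6.70 eV"}},
            "B_b": {"energy": 55_894.0,
                    "mu": [0.0, _mu_from_f(0.467, 55_894.0), 0.0],
                    "mag": [0.0, 0.0, 0.0],
                    "provenance": {"energy": "reported phenol 6.93 eV"}},
        }
    elif chromophore == "PHE":
        e_lb = 37_310.0
        tr = {
            "L_b": {
                "energy": e_lb,
                "mu": [0.0, _mu_from_f(0.004, e_lb), 0.0],
                "mag": [0.0, 0.0, 0.0],
                "modes": [[570.0, 300.0, "m1"], [980.0, 660.0, "m2"]],
                "provenance": {
                    "energy": "reported onset of the Phe window "
                              "(0-0 assignment is an inference)",
                    "mu": "default: benzene-like weak L_b",
                    "modes": "frequencies and reorgs reported",
                },
            },
            "L_a": {"energy": 49_000.0,
                    "mu": [_mu_from_f(0.09, 49_000.0), 0.0, 0.0],
                    "mag": [0.0, 0.0, 0.0],
                    "provenance": {"energy": "default", "mu": "default"}},
        }
    elif chromophore == "AMIDE":
        tr = {
            "npi*": {"energy": 45_455.0,
                     "mu": [0.0, 0.0, 0.05],
                     "mag": [1.0, 0.0, 0.0],
                     "provenance": {"energy": "default (220 nm)",
                                    "mag": "default: ~1 Bohr magneton "
                                           "along C=O"}},
            "pipi*": {"energy": 52_632.0,
                      "mu": [3.05 * math.cos(math.radians(-55.0)),
                             3.05 * math.sin(math.radians(-55.0)), 0.0],
                      "mag": [0.0, 0.0, 0.0],
                      "provenance": {"energy": "default (190 nm)",
                                     "mu": "default NV1-like orientation"}},
        }
    elif chromophore == "PHENOL":
        # gas-phase fixture energies/oscillator strengths
        evs = {"L_b": (4.59, 0.020), "L_a": (5.82, 0.132),
               "B_a": (6.70, 0.636), "B_b": (6.93, 0.467)}
        tr = {}
        for lbl, (ev, f) in evs.items():
            e = ev * 8065.54
            direction = [0.0, 1.0, 0.0] if lbl in ("L_b", "B_b") else [1.0, 0.0, 0.0]
            mu = _mu_from_f(f, e)
            tr[lbl] = {"energy": e,
                       "mu": [mu * d for d in direction],
                       "mag": [0.0, 0.0, 0.0],
                       "provenance": {"energy": "reported experimental",
                                      "mu": "magnitude from reported f; "
                                            "orientation default"}}
    else:
        raise ValueError(f"unknown chromophore {chromophore!r}")

    if with_monopoles:
        for lbl, t in tr.items():
            mono = _dipole_monopoles(t["mu"])
            if mono:
                t["monopoles"] = mono
                t["provenance"]["monopoles"] = "synthetic two-point set"

    param = {"chromophore": chromophore, "schema": "excitonuv-parameters-1",
             "frame": "local (see docstring)", "transitions": tr}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(param, fh, indent=1)
    return param


def validate_parameters(param: dict):
    """Schema check for a chromophore parameter mapping."""
    if param.get("schema") != "excitonuv-parameters-1":
        raise ValueError("unknown parameter schema")
    for lbl, t in param["transitions"].items():
        if t["energy"] <= 0:
            raise ValueError(f"{lbl}: energy must be positive")
        if len(t["mu"]) != 3:
            raise ValueError(f"{lbl}: mu must be a 3-vector")
        for f, l, *_ in t.get("modes", []):
            if f <= 0 or l < 0:
                raise ValueError(f"{lbl}: bad mode ({f}, {l})")
        q = sum(m["charge"] for m in t.get("monopoles", []))
        if abs(q) > 1e-9:
            raise ValueError(f"{lbl}: monopoles carry net charge")
        if "provenance" not in t:
            raise ValueError(f"{lbl}: provenance tags missing")
    return True


def dipeptide_spec(name: str) -> ConformerSpec:
    parts = name.split("_")
    return ConformerSpec(parts[0], tuple(float(p) for p in parts[1:]))


def make_dipeptide_fixtures(outdir) -> dict:
    """Write the 3 cPY + 6 cYY conformers as PDB files; returns a
    manifest.  Regeneration is byte-identical (builder is deterministic,
    fixed float formatting)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name in DIPEPTIDE_NAMES:
        atoms = build_cyclic_dipeptide(dipeptide_spec(name))
        resmap = {1: "PRO" if name.startswith("cPY") else "TYR", 2: "TYR"}
        path = outdir / f"{name}.pdb"
        write_pdb(atoms, path, resname_map=resmap)
        files[name] = str(path)
    manifest = {"names": list(DIPEPTIDE_NAMES), "files": files,
                "generator": "excitonuv.fixtures.make_dipeptide_fixtures"}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _ring_atoms(centroid, R, tyr: bool):
    """Aromatic ring atom coordinates for a ring with rotation matrix R
    (rows = local axes) centred at ``centroid``."""
    r = 1.39
    ang = {"CG": 180.0, "CD1": 120.0, "CD2": 240.0,
           "CE1": 60.0, "CE2": 300.0, "CZ": 0.0}
    out = {}
    for nm, a in ang.items():
        local = np.array([r * math.cos(math.radians(a)),
                          r * math.sin(math.radians(a)), 0.0])
        out[nm] = centroid + local @ R
    if tyr:
        out["OH"] = centroid + np.array([r + 1.375, 0.0, 0.0]) @ R
    out["CB"] = centroid + np.array([-(r + 1.5), 0.0, 0.0]) @ R
    return out


def make_protein_fixture(n_tyr: int = 4, n_phe: int = 4, seed: int = 0,
                         n_models: int = 1, path=None) -> str:
    """A toy single-chain protein PDB: alternating aromatic residues and
    glycine spacers on a 6 A pitch, rings in seeded random orientations.
    With ``n_models`` > 1, writes NMR-like MODEL records with small
    seeded coordinate jitter.  Returns the PDB text."""
    if n_tyr < 0 or n_phe < 0:
        raise ValueError("residue counts must be >= 0")
    rng = np.random.default_rng(seed)
    residues = []  # (resname, atoms dict)
    kinds = ["TYR"] * n_tyr + ["PHE"] * n_phe
    pos = 0
    for i, kind in enumerate(kinds):
        base = np.array([6.0 * pos, 0.0, 0.0])
        # backbone
        atoms = {"N": base, "CA": base + [1.45, 0.2, 0.0],
                 "C": base + [2.4, 1.3, 0.0], "O": base + [2.1, 2.5, 0.2]}
        # ring in a random orientation, clear of the backbone
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=rng).as_matrix()
        centroid = base + np.array([1.5, -4.0, 1.0])
        atoms.update(_ring_atoms(centroid, R, tyr=(kind == "TYR")))
        residues.append((kind, atoms))
        pos += 1
        # glycine spacer
        gbase = np.array([6.0 * pos, 0.0, 0.0])
        residues.append(("GLY", {"N": gbase, "CA": gbase + [1.45, 0.2, 0.0],
                                 "C": gbase + [2.4, 1.3, 0.0],
                                 "O": gbase + [2.1, 2.5, 0.2]}))
        pos += 1

    def model_lines(jitter_rng=None):
        lines = []
        serial = 1
        for ri, (resname, atoms) in enumerate(residues, start=1):
            for at, xyz in atoms.items():
                p = np.asarray(xyz, dtype=float)
                if jitter_rng is not None:
                    p = p + jitter_rng.normal(0.0, 0.05, 3)
                lines.append(
                    f"ATOM  {serial:5d} {at:<4s}{resname:>4s} A{ri:4d}    "
                    f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00"
                    f"          {at[0]:>2s}")
                serial += 1
        return lines

    out = ["REMARK synthetic excitonuv protein fixture"]
    if n_models == 1:
        out += model_lines()
    else:
        jrng = np.random.default_rng(seed + 1)
        for m in range(1, n_models + 1):
            out.append(f"MODEL     {m:4d}")
            out += model_lines(jrng)
            out.append("ENDMDL")
    out.append("END")
    text = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def make_degenerate_dimer(angle_deg: float, coupling: float,
                          energy: float = 34_965.0, mu: float = 1.1,
                          separation: float = 6.0):
    """Two degenerate L_b(u0)-like transitions with a fixed inter-site
    coupling and a prescribed angle between their electric TDMs — the
    minimal model for polarization-combination contrast studies.

    ``coupling`` is the FC-weighted coupling between the two vibronic
    0-0 transitions (cm^-1); ``mu`` the per-site TDM magnitude (Debye).
    """
    from .hamiltonian import ExcitonHamiltonian, SiteBasisState
    from .vibronic import VibronicLevel

    th = math.radians(angle_deg)
    lv = VibronicLevel((), 0.0, 1.0)
    basis = [
        SiteBasisState(0, "L_b", lv, energy,
                       mu * np.array([1.0, 0.0, 0.0]), np.zeros(3),
                       None, np.zeros(3), "TYR"),
        SiteBasisState(1, "L_b", lv, energy,
                       mu * np.array([math.cos(th), math.sin(th), 0.0]),
                       np.zeros(3), None,
                       np.array([separation, 0.0, 0.0]), "TYR"),
    ]
    H = np.array([[energy, coupling], [coupling, energy]])
    return ExcitonHamiltonian(basis, H)


def make_reference_cd(center_nm: float = 279.0, amplitude: float = 1.0,
                      fwhm: float = 6.0, grid=None):
    """A single-band synthetic reference CD curve (for snapshot-selection
    tests; not an experimental spectrum)."""
    from .cd import CDSpectrum, default_grid

    g = default_grid() if grid is None else np.asarray(grid, float)
    sigma = fwhm / 2.3548
    return CDSpectrum(g, amplitude * np.exp(-0.5 * ((g - center_nm) / sigma) ** 2))
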