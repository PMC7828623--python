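"""Static disorder: Gaussian site-energy sampling, ensemble-averaged 2D
maps, exciton-mixing statistics, electrostatic-fluctuation emulation,
state filtering and CD-based snapshot selection.

A frozen environment spreads the site energies from realization to
realization.  Site energies are drawn from a Gaussian centred on the
nominal transition energy; the whole vibronic manifold of a site shifts
rigidly.  "sigma = 100 cm^-1" is interpreted as a standard deviation
(the quantity carries cm^-1 units); set ``variance_literal`` to treat it
as a variance instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cd import cd_rmsd
from .hamiltonian import ExcitonHamiltonian, diagonalize
from .response import Map2D, relative_intensity, response_2d
from .units import EV_CM


@dataclass
class DisorderModel:
    sigma: float = 100.0  # cm^-1 standard deviation per site
    n_realizations: int = 500
    seed: int = 0
    variance_literal: bool = False

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_realizations < 1:
            raise ValueError("need at least one realization")

    @property
    def std(self) -> float:
        return float(np.sqrt(self.sigma)) if self.variance_literal else self.sigma


def sample_site_energies(model: DisorderModel, n_sites: int) -> np.ndarray:
    """(n_realizations, n_sites) independent Gaussian shifts in cm^-1."""
    rng = np.random.default_rng(model.seed)
    return rng.normal(0.0, model.std, size=(model.n_realizations, n_sites))


@dataclass
class EnsembleResult:
    mean_maps: dict
    fraction_strong_mixing: float  # percent of realizations
    relative_combo_intensity: float | None  # percent, combo vs first scheme
    n_realizations: int = 0
    meta: dict = field(default_factory=dict)


def mixing_fraction(H: ExcitonHamiltonian, model: DisorderModel) -> float:
    """Percent of disorder realizations containing at least one
    strong-mixing exciton (max site coefficient in [0.707, 0.90])."""
    n_sites = 1 + max(b.site_index for b in H.basis)
    shifts = sample_site_energies(model, n_sites)
    hits = 0
    for row in shifts:
        states = diagonalize(H.shifted(row))
        if any(st.mixing_class == "strong" for st in states):
            hits += 1
    return 100.0 * hits / model.n_realizations


def run_ensemble(H: ExcitonHamiltonian, site_sds, model: DisorderModel,
                 schemes=("xxxx", {"xxxx": 1.0, "xxyy": -3.0}),
                 response_kwargs: dict | None = None) -> EnsembleResult:
    """Static-disorder ensemble: per realization shift site energies,
    diagonalize (for mixing statistics) and accumulate 2D maps; report
    snapshot-averaged maps, the strong-mixing fraction and the relative
    intensity max|combo| / max|first scheme| of the averaged maps.
    """
    kw = dict(response_kwargs or {})
    n_sites = 1 + max(b.site_index for b in H.basis)
    shifts = sample_site_energies(model, n_sites)
    acc: dict[str, Map2D] = {}
    hits = 0
    for row in shifts:
        Hs = H.shifted(row)
        states = diagonalize(Hs)
        if any(st.mixing_class == "strong" for st in states):
            hits += 1
        maps = response_2d(Hs, site_sds, schemes=schemes, **kw)
        for nm, m in maps.items():
            if nm not in acc:
                acc[nm] = m
            else:
                acc[nm] = Map2D(acc[nm].w1, acc[nm].w3,
                                acc[nm].values + m.values, nm, 0.0,
                                acc[nm].meta)
    n = model.n_realizations
    mean_maps = {nm: Map2D(m.w1, m.w3, m.values / n, nm, 0.0, m.meta)
                 for nm, m in acc.items()}
    names = list(mean_maps)
    rel = None
    if len(names) >= 2:
        rel = relative_intensity(mean_maps[names[1]], mean_maps[names[0]])
    return EnsembleResult(mean_maps, 100.0 * hits / n, rel, n,
                          {"sigma": model.std, "seed": model.seed})


# ---------------------------------------------------------------------------
# electrostatic-fluctuation emulation (synthetic stand-in for an external
# MD + electrostatic-fluctuation pipeline)


def ehef_emulator(n_sites: int, fluct_sigma: float, n_snapshots: int,
                  outlier_rate: float = 0.0,
                  outlier_scale: float = 3.0 * EV_CM,
                  seed: int = 0) -> dict:
    """Emulate per-snapshot electrostatic site-energy fluctuations as a
    Gaussian mixture: ordinary shifts of width ``fluct_sigma`` plus rare
    outliers of width ``outlier_scale`` occurring with probability
    ``outlier_rate`` (the pathological multi-eV shifts such pipelines
    occasionally produce).

    Returns {"shifts": (n_snapshots, n_sites) cm^-1, "outlier_mask":
    bool same shape, "meta": {...}}.  Purely synthetic: this stands in
    for energy-shift tables computed by an external electrostatics code.
    """
    if not 0.0 <= outlier_rate <= 1.0:
        raise ValueError("outlier_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    shifts = rng.normal(0.0, fluct_sigma, size=(n_snapshots, n_sites))
    mask = rng.random(size=shifts.shape) < outlier_rate
    if mask.any():
        shifts[mask] = rng.normal(0.0, outlier_scale, size=int(mask.sum()))
    return {"shifts": shifts, "outlier_mask": mask,
            "meta": {"synthetic": True, "fluct_sigma": fluct_sigma,
                     "outlier_rate": outlier_rate,
                     "outlier_scale": outlier_scale, "seed": seed}}


def write_shift_table(shifts: np.ndarray, path, site_labels=None):
    """TSV per-snapshot shift table (snapshot, site, shift_cm-1)."""
    n_snap, n_sites = shifts.shape
    labels = site_labels or [f"site{j}" for j in range(n_sites)]
    with open(path, "w") as fh:
        fh.write("snapshot\tsite\tshift_cm-1\n")
        for i in range(n_snap):
            for j in range(n_sites):
                fh.write(f"{i}\t{labels[j]}\t{shifts[i, j]:.6f}\n")


def read_shift_table(path) -> np.ndarray:
    import csv

    rows = []
    with open(path) as fh:
        rd = csv.DictReader(fh, delimiter="\t")
        for r in rd:
            rows.append((int(r["snapshot"]), r["site"], float(r["shift_cm-1"])))
    n_snap = 1 + max(r[0] for r in rows)
    sites = sorted({r[1] for r in rows})
    out = np.zeros((n_snap, len(sites)))
    si = {s: j for j, s in enumerate(sites)}
    for snap, site, val in rows:
        out[snap, si[site]] = val
    return out


def filter_states(H: ExcitonHamiltonian, max_shift: float | None = None,
                  nominal_energies=None,
                  drop_types: tuple = ()) -> ExcitonHamiltonian:
    """Remove basis states whose energy deviates from its nominal value
    by more than ``max_shift`` (cm^-1) and/or whole residue classes
    (e.g. drop_types=("AMIDE",) removes backbone states)."""
    keep = []
    for k, b in enumerate(H.basis):
        if b.residue_type in drop_types:
            continue
        if max_shift is not None and nominal_energies is not None:
            if abs(b.energy - nominal_energies[k]) > max_shift:
                continue
        keep.append(k)
    if not keep:
        raise ValueError("state filter removed every basis state")
    idx = np.array(keep)
    return ExcitonHamiltonian([H.basis[k] for k in keep],
                              H.matrix[np.ix_(idx, idx)], H.sites)


def select_snapshots(spectra, reference, k: int = 200):
    """Indices of the k snapshots whose CD is closest (RMSD) to the
    reference spectrum; ties break on the snapshot index."""
    spectra = list(spectra)
    if k > len(spectra):
        raise ValueError(f"k={k} exceeds the {len(spectra)} snapshots")
    scored = sorted((cd_rmsd(sp, reference), i) for i, sp in enumerate(spectra))
    return [i for _, i in scored[:k]]
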