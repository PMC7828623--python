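"""Quasi-absorptive 2D electronic spectra at t2 = 0.

The third-order response is summed over ground-state-bleach (GSB),
stimulated-emission (SE) and excited-state-absorption (ESA) pathways in
the one- and two-exciton manifolds, each dressed by second-cumulant
lineshape factors and weighted by the isotropic four-point orientational
average of its transition dipoles.  Transport between excitons is
neglected, so the lineshapes are exact within the cumulant treatment.

Pathway lineshape factors are derived by accumulating bath-correlation
integrals over every pair of excited-state segments on the two branches
of the Keldysh contour (see docs/methods.md for the derivation).  With
g_ab(t) the cross-lineshape of excitons a and b (site lineshapes g_n
weighted by |c_n^a|^2 |c_n^b|^2 for uncorrelated site baths), the t2 = 0
factors used below are, writing g1 = g(t1), g3 = g(t3), g13 = g(t1+t3):

  SE/GSB rephasing (t1 coherence on e, t3 on e')
      exp[-g_ee,1* - g_e'e',3 - g_ee',1* - g_ee',3* + g_ee',13*]
  SE non-rephasing      exp[-g_ee,13]
  GSB non-rephasing     exp[-g_ee,1 - g_e'e',3 - g_ee',13 + g_ee',1 + g_ee',3]
  ESA rephasing (e, e', f)
      exp[-g_ee,13* - g_ff,3 + g_ef,3 - g_ef,1* + g_ef,13*]
  ESA non-rephasing
      exp[-g_ee,1 - g_ff,3 - g_ef,13 + g_ef,1 + g_ef,3 - g_e'e',3*
          + g_e'e,13 - g_e'e,1 - g_e'e,3 + 2 Re g_e'f,3]

Two-exciton states are site-pair products (no double excitation of one
site) with additive energies.  These formulas make the cross pathways of
uncoupled chromophores cancel identically, so the response of a system
is additive over the connected components of its coupling graph; the
implementation exploits this by computing each component separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .hamiltonian import ExcitonHamiltonian, diagonalize
from .lineshape import SpectralDensity, evaluate_g, orientational_factor
from .units import fs_to_x


@dataclass
class Map2D:
    """(w1, w3) spectrum; ``values`` complex, the quasi-absorptive map is
    its real part.  t2 is fixed at 0."""

    w1: np.ndarray
    w3: np.ndarray
    values: np.ndarray
    scheme: str = "xxxx"
    t2_fs: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.w1 = np.asarray(self.w1, dtype=float)
        self.w3 = np.asarray(self.w3, dtype=float)
        self.values = np.asarray(self.values)
        if not np.all(np.isfinite(self.values.real)):
            raise ValueError("non-finite map values")
        for g in (self.w1, self.w3):
            step = np.diff(g)
            if step.size and not np.allclose(step, step[0], rtol=1e-6):
                raise ValueError("map grids must be uniform")

    @property
    def real(self) -> np.ndarray:
        return self.values.real

    def max_abs(self) -> float:
        return float(np.abs(self.values.real).max())

    def restrict(self, w1_range=None, w3_range=None) -> "Map2D":
        m1 = np.ones(self.w1.size, bool) if w1_range is None else \
            (self.w1 >= w1_range[0]) & (self.w1 <= w1_range[1])
        m3 = np.ones(self.w3.size, bool) if w3_range is None else \
            (self.w3 >= w3_range[0]) & (self.w3 <= w3_range[1])
        return Map2D(self.w1[m1], self.w3[m3],
                     self.values[np.ix_(m1, m3)], self.scheme, self.t2_fs,
                     dict(self.meta))

    def apply_threshold(self, frac: float = 0.001) -> "Map2D":
        """Zero values whose magnitude is below frac * max|map|."""
        cut = frac * self.max_abs()
        vals = np.where(np.abs(self.values.real) < cut, 0.0, self.values)
        return Map2D(self.w1, self.w3, vals, self.scheme, self.t2_fs,
                     dict(self.meta))

    def save_hdf5(self, path):
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("w1", data=self.w1)
            fh.create_dataset("w3", data=self.w3)
            fh.create_dataset("real", data=self.values.real)
            fh.create_dataset("imag", data=self.values.imag)
            fh.attrs["scheme"] = self.scheme
            fh.attrs["t2_fs"] = self.t2_fs
            fh.attrs["meta"] = json.dumps(self.meta, default=str)

    def save_tsv_gz(self, path):
        """Gzipped TSV grid dump (w1, w3, real, imag per line)."""
        import gzip

        with gzip.open(path, "wt") as fh:
            fh.write(f"# scheme {self.scheme} t2_fs {self.t2_fs}\n")
            fh.write("w1_cm-1\tw3_cm-1\treal\timag\n")
            for i, w1 in enumerate(self.w1):
                for j, w3 in enumerate(self.w3):
                    v = self.values[i, j]
                    fh.write(f"{w1:.4f}\t{w3:.4f}\t{v.real:.8e}\t{v.imag:.8e}\n")

    def plot_contour(self, path, n_levels: int = 12):
        """Contour plot of the real part (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4.5))
        vmax = self.max_abs() or 1.0
        levels = np.linspace(-vmax, vmax, 2 * n_levels + 1)
        cs = ax.contourf(self.w1, self.w3, self.values.real.T, levels=levels,
                         cmap="RdBu_r")
        ax.plot(self.w1, self.w1, lw=0.5, color="k", alpha=0.4)
        ax.set_xlabel(r"$\omega_1$ (cm$^{-1}$)")
        ax.set_ylabel(r"$\omega_3$ (cm$^{-1}$)")
        ax.set_title(self.scheme)
        fig.colorbar(cs, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)

    @classmethod
    def load_hdf5(cls, path):
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(fh["w1"][...], fh["w3"][...],
                       fh["real"][...] + 1j * fh["imag"][...],
                       str(fh.attrs["scheme"]), float(fh.attrs["t2_fs"]),
                       json.loads(fh.attrs["meta"]))


def combine_polarizations(map_a: Map2D, map_b: Map2D, weights=(1.0, -3.0)) -> Map2D:
    """Pointwise weighted sum of two maps on identical grids."""
    if map_a.w1.shape != map_b.w1.shape or map_a.w3.shape != map_b.w3.shape \
            or not (np.allclose(map_a.w1, map_b.w1) and np.allclose(map_a.w3, map_b.w3)):
        raise ValueError("grid mismatch between maps")
    wa, wb = weights
    name = f"{wa:g}*{map_a.scheme}{wb:+g}*{map_b.scheme}"
    return Map2D(map_a.w1, map_a.w3, wa * map_a.values + wb * map_b.values,
                 name, map_a.t2_fs, dict(map_a.meta))


def relative_intensity(combo: Map2D, reference: Map2D) -> float:
    """max|combo| / max|reference| as a percentage."""
    return 100.0 * combo.max_abs() / reference.max_abs()


def narrowband_restrict(H: ExcitonHamiltonian, center: float,
                        width: float) -> ExcitonHamiltonian:
    """Retain only basis states with energy in [center - width/2,
    center + width/2] — the narrowband-pulse surrogate."""
    if width <= 0 or center <= 0:
        raise ValueError("center and width must be positive")
    keep = [k for k, b in enumerate(H.basis)
            if abs(b.energy - center) <= width / 2.0]
    if not keep:
        raise ValueError("narrowband window retains no states")
    idx = np.array(keep)
    return ExcitonHamiltonian([H.basis[k] for k in keep],
                              H.matrix[np.ix_(idx, idx)], H.sites)


# ---------------------------------------------------------------------------


def _components(H: ExcitonHamiltonian):
    """Connected components of the coupling graph over basis states."""
    n = H.n
    seen = np.zeros(n, bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            k = stack.pop()
            comp.append(k)
            for l in range(n):
                if not seen[l] and H.matrix[k, l] != 0.0:
                    seen[l] = True
                    stack.append(l)
        comps.append(sorted(comp))
    return comps


def _orient(vectors, scheme) -> float:
    """Orientational average for full (unnormalised) dipole vectors: the
    average is multilinear, so magnitudes ride along."""
    mags = [np.linalg.norm(v) for v in vectors]
    if min(mags) < 1e-14:
        return 0.0
    units = [v / m for v, m in zip(vectors, mags)]
    return float(np.prod(mags)) * orientational_factor(*units, scheme)


class _GCache:
    """Cross-lineshapes g_ab on the extended 1-D x grid, keyed by the
    site-weight vector of the (a, b) pair."""

    def __init__(self, site_g_1d):
        self.site_g = site_g_1d  # (n_sites, 2N) complex
        self.cache = {}

    def get(self, wa: np.ndarray, wb: np.ndarray) -> np.ndarray:
        w = wa * wb
        key = tuple(np.round(w, 12))
        if key not in self.cache:
            self.cache[key] = np.tensordot(w, self.site_g, axes=(0, 0))
        return self.cache[key]


def response_2d(H: ExcitonHamiltonian, site_sds, schemes=("xxxx",),
                temperature: float = 300.0, t2_fs: float = 0.0,
                n_t: int = 2048, dt_fs: float = 2.0, pad: int = 2,
                apodize: float = 0.1, include_esa: bool = True,
                per_tyr: bool = True) -> dict[str, Map2D]:
    """Quasi-absorptive 2D maps at t2 = 0 for one or more polarization
    schemes.

    ``H`` supplies the electronic (or narrowband vibronic) basis; the
    vibronic progressions that fall inside the probed window should be
    carried by the discrete modes of ``site_sds`` (one SpectralDensity
    per site, or a single one shared by all sites).  ``schemes`` entries
    are strings ("xxxx", "xxyy", ...) or weight dicts such as
    ``{"xxxx": 1, "xxyy": -3}``; dict entries are evaluated pathway-wise.

    Returns {scheme_name: Map2D}.  Intensities are divided by the number
    of Tyr sites when ``per_tyr`` (and at least one Tyr is present).
    """
    if t2_fs != 0.0:
        raise NotImplementedError(
            "only t2 = 0 quasi-absorptive maps are implemented; "
            "finite waiting times are out of scope")

    n_sites = 1 + max(b.site_index for b in H.basis)
    if isinstance(site_sds, SpectralDensity):
        site_sds = [site_sds] * n_sites
    if len(site_sds) < n_sites:
        raise ValueError("need one spectral density per site")

    # time grids: x = 2 pi c t, extended to 2N so g(t1+t3) is a lookup
    x = fs_to_x(dt_fs) * np.arange(n_t)
    x_ext = fs_to_x(dt_fs) * np.arange(2 * n_t)
    dx = x[1] - x[0]
    site_g = np.array([evaluate_g(sd, temperature, x_ext) for sd in site_sds])
    gcache = _GCache(site_g)
    IDX = np.add.outer(np.arange(n_t), np.arange(n_t))

    # one-exciton states per connected component
    comps = _components(H)
    w0 = float(np.mean([b.energy for b in H.basis]))  # rotating frame

    scheme_names = [s if isinstance(s, str) else _combo_name(s) for s in schemes]
    acc_R = {nm: np.zeros((n_t, n_t), complex) for nm in scheme_names}
    acc_N = {nm: np.zeros((n_t, n_t), complex) for nm in scheme_names}

    for comp in comps:
        idx = np.array(comp)
        sub = H.matrix[np.ix_(idx, idx)]
        evals, evecs = np.linalg.eigh(sub)
        # deterministic sign
        for k in range(evecs.shape[1]):
            imax = int(np.argmax(np.abs(evecs[:, k])))
            if evecs[imax, k] < 0:
                evecs[:, k] *= -1
        mus_site = np.array([H.basis[k].mu for k in comp])
        sites_of = np.array([H.basis[k].site_index for k in comp])
        n1 = idx.size
        mu_e = evecs.T @ mus_site  # (n1, 3)
        om_e = evals - w0
        # site weights of each exciton
        w_e = np.zeros((n1, n_sites))
        for a in range(n1):
            for j, s in enumerate(sites_of):
                w_e[a, s] += evecs[j, a] ** 2

        # two-exciton pair states (basis-state pairs on different sites)
        pairs = []
        if include_esa:
            for p in range(n1):
                for q in range(p + 1, n1):
                    if sites_of[p] != sites_of[q]:
                        pairs.append((p, q))
        n2 = len(pairs)
        om_f = np.empty(n2)
        w_f = np.zeros((n2, n_sites))
        mu_fe = np.zeros((n2, n1, 3))
        for fi, (p, q) in enumerate(pairs):
            om_f[fi] = H.basis[comp[p]].energy + H.basis[comp[q]].energy - 2 * w0
            w_f[fi, sites_of[p]] += 1.0
            w_f[fi, sites_of[q]] += 1.0
            for a in range(n1):
                mu_fe[fi, a] = (evecs[p, a] * H.basis[comp[q]].mu
                                + evecs[q, a] * H.basis[comp[p]].mu)

        def g1(garr):  # g(t1), column vector
            return garr[:n_t][:, None]

        def g3(garr):  # g(t3), row vector
            return garr[:n_t][None, :]

        def g13(garr):  # g(t1+t3)
            return garr[IDX]

        ph1 = {a: np.exp(1j * om_e[a] * x)[:, None] for a in range(n1)}
        ph1c = {a: np.conj(ph1[a]) for a in range(n1)}
        ph3 = {}

        def phase3(om):
            key = round(float(om), 9)
            if key not in ph3:
                ph3[key] = np.exp(-1j * om * x)[None, :]
            return ph3[key]

        for a in range(n1):
            g_aa = gcache.get(w_e[a], w_e[a])
            for b in range(n1):
                g_bb = gcache.get(w_e[b], w_e[b])
                g_ab = gcache.get(w_e[a], w_e[b])
                # rephasing SE + GSB share the lineshape factor
                E_r = np.exp(-np.conj(g1(g_aa)) - g3(g_bb)
                             - np.conj(g1(g_ab)) - np.conj(g3(g_ab))
                             + np.conj(g13(g_ab)))
                base_r = E_r * ph1[a] * phase3(om_e[b])
                # non-rephasing SE: coherence stays on a
                E_nse = np.exp(-g13(g_aa))
                base_nse = E_nse * ph1c[a] * phase3(om_e[a])
                # non-rephasing GSB
                E_ngsb = np.exp(-g1(g_aa) - g3(g_bb) - g13(g_ab)
                                + g1(g_ab) + g3(g_ab))
                base_ngsb = E_ngsb * ph1c[a] * phase3(om_e[b])
                for nm, sch in zip(scheme_names, schemes):
                    f_se = _orient([mu_e[a], mu_e[b], mu_e[a], mu_e[b]], sch)
                    f_gsb = _orient([mu_e[a], mu_e[a], mu_e[b], mu_e[b]], sch)
                    f_nse = _orient([mu_e[a], mu_e[b], mu_e[b], mu_e[a]], sch)
                    if f_se or f_gsb:
                        acc_R[nm] += (f_se + f_gsb) * base_r
                    if f_nse:
                        acc_N[nm] += f_nse * base_nse
                    if f_gsb:
                        acc_N[nm] += f_gsb * base_ngsb
                for fi in range(n2):
                    g_ff = gcache.get(w_f[fi], w_f[fi])
                    g_af = gcache.get(w_e[a], w_f[fi])
                    g_bf = gcache.get(w_e[b], w_f[fi])
                    # rephasing ESA: t1 on a (bra), via b, t3 on f<-a
                    E_resa = np.exp(-np.conj(g13(g_aa)) - g3(g_ff)
                                    + g3(g_af) - np.conj(g1(g_af))
                                    + np.conj(g13(g_af)))
                    base_resa = E_resa * ph1[a] * phase3(om_f[fi] - om_e[a])
                    # non-rephasing ESA: t1 on a (ket), bra on b, t3 f<-b
                    E_nesa = np.exp(-g1(g_aa) - g3(g_ff) - g13(g_af)
                                    + g1(g_af) + g3(g_af)
                                    - np.conj(g3(g_bb))
                                    + g13(g_ab) - g1(g_ab) - g3(g_ab)
                                    + 2.0 * np.real(g3(g_bf)))
                    base_nesa = E_nesa * ph1c[a] * phase3(om_f[fi] - om_e[b])
                    for nm, sch in zip(scheme_names, schemes):
                        f_resa = _orient([mu_e[a], mu_e[b], mu_fe[fi, b],
                                          mu_fe[fi, a]], sch)
                        f_nesa = _orient([mu_e[a], mu_e[b], mu_fe[fi, a],
                                          mu_fe[fi, b]], sch)
                        if f_resa:
                            acc_R[nm] -= f_resa * base_resa
                        if f_nesa:
                            acc_N[nm] -= f_nesa * base_nesa

    # windows + endpoint weights, then half-Fourier both axes
    win = np.ones(n_t)
    ntail = max(1, int(apodize * n_t))
    win[-ntail:] = 0.5 * (1.0 + np.cos(np.pi * np.arange(ntail) / ntail))
    win[0] = 0.5
    W = win[:, None] * win[None, :]

    npad = pad * n_t
    freqs = 2.0 * np.pi * np.fft.fftfreq(npad, d=dx)

    n_tyr = sum(1 for s in H.sites if getattr(s, "residue_type", "") == "TYR")
    if not H.sites:
        site_ids = {b.site_index for b in H.basis
                    if b.residue_type == "TYR"}
        n_tyr = len(site_ids)
    norm = 1.0 / n_tyr if (per_tyr and n_tyr > 0) else 1.0

    out = {}
    for nm in scheme_names:
        # rephasing: S(w1,w3) = sum e^{-i w1 x1} e^{+i w3 x3} R
        SR = np.fft.fft(np.fft.ifft(acc_R[nm] * W, n=npad, axis=1) * npad,
                        n=npad, axis=0)
        # non-rephasing: e^{+i w1 x1} e^{+i w3 x3}
        SN = np.fft.ifft(np.fft.ifft(acc_N[nm] * W, n=npad, axis=1) * npad,
                         n=npad, axis=0) * npad
        S = (SR + SN) * dx * dx * norm
        order = np.argsort(freqs)
        S = S[np.ix_(order, order)]
        w1_axis = freqs[order] + w0
        w3_axis = freqs[order] + w0
        out[nm] = Map2D(w1_axis, w3_axis, S, nm, 0.0,
                        {"temperature": temperature, "n_t": n_t,
                         "dt_fs": dt_fs, "pad": pad, "apodize": apodize,
                         "include_esa": include_esa, "n_tyr": n_tyr,
                         "rotating_frame_cm": w0})
    return out


def _combo_name(weights: dict) -> str:
    parts = []
    for s, w in weights.items():
        parts.append(f"{w:+g}*{s}")
    return "".join(parts).lstrip("+")
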