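"""Run configuration, parameter-file IO and pipeline glue.

The :class:`RunConfig` gathers every knob of a calculation (bath,
convolution width, polarization schemes, disorder, coupling zeroing,
grids) with the package defaults; it round-trips through JSON/YAML so a
run is fully described by one file.  Output files embed the resolved
config and a content hash of their inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cd import average_spectra, convolve_gaussian, rotational_strengths
from .geometry import attach_transitions, read_pdb
from .hamiltonian import assemble_hamiltonian, diagonalize
from .lineshape import SpectralDensity
from .response import narrowband_restrict, response_2d
from .vibronic import VibMode

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # bath (homogeneous broadening of every transition)
    bath_reorg: float = 300.0      # cm^-1
    bath_cutoff: float = 85.0      # cm^-1
    temperature: float = 300.0     # K
    # CD
    cd_fwhm: float = 4.0           # nm, Gaussian convolution width
    all_models: bool = True        # average over PDB MODELs
    # 2D
    schemes: tuple = ("xxxx", "xxxx-3xxyy")
    n_t: int = 512
    dt_fs: float = 2.0
    energy_window: tuple = (32_000.0, 40_000.0)  # basis states kept for 2D
    narrowband: tuple | None = None  # (center, width) cm^-1
    zero_couplings: tuple = ()     # e.g. ("TYR-TYR", "PHE-PHE", "TYR-PHE")
    combo_zero_threshold: float = 0.001  # zero |map| < 0.1% of max
    vibronic_cutoff: float = 3200.0      # cm^-1, CD vibronic expansion
    #: discrete-mode labels carried into the 2D site spectral densities;
    #: the Tyr C-H bending mode ("v") is excluded by default, its
    #: coupling being negligible for the 2D maps
    sd_mode_labels: tuple = ("u", "m1", "m2")
    # disorder
    disorder_sigma: float = 100.0  # cm^-1
    disorder_n: int = 500
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def validate(self):
        for name in ("bath_cutoff", "temperature", "cd_fwhm", "dt_fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("bath_reorg", "disorder_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_t < 16:
            raise ValueError("n_t too small")
        return True


#: polarization scheme aliases accepted by configs and the CLI
SCHEME_ALIASES = {
    "xxxx-3xxyy": {"xxxx": 1.0, "xxyy": -3.0},
    "xyxy-xyyx": {"xyxy": 1.0, "xyyx": -1.0},
}


def resolve_scheme(name):
    return SCHEME_ALIASES.get(name, name)


def content_hash(*paths) -> str:
    h = hashlib.sha256()
    for p in paths:
        h.update(Path(p).read_bytes())
    return h.hexdigest()[:16]


def load_params_dir(params_dir) -> dict:
    """Read every chromophore parameter JSON in a directory; returns
    {chromophore: params} (see excitonuv.fixtures for the schema)."""
    from .fixtures import validate_parameters

    out = {}
    for p in sorted(Path(params_dir).glob("*.json")):
        try:
            data = json.loads(p.read_text())
        except json.JSONDecodeError:
            continue
        if isinstance(data, dict) and "chromophore" in data:
            validate_parameters(data)
            out[data["chromophore"]] = data
    if not out:
        raise FileNotFoundError(f"no parameter files found in {params_dir}")
    return out


def sites_with_parameters(sites, params: dict):
    """Attach parameter-file transitions to geometry sites in place."""
    out = []
    for s in sites:
        key = s.residue_type
        if key in params:
            attach_transitions(s, params[key])
            out.append(s)
        else:
            log.warning("no parameters for %s site %s; skipped",
                        s.residue_type, s.residue_id)
    return out


def cd_pipeline(model_sites, config: RunConfig):
    """CD for one or more site lists (PDB models): per-model rotational
    strength lines + convolved spectra + the model average."""
    spectra, all_lines = [], []
    for sites in model_sites:
        H = assemble_hamiltonian(sites, vibronic_cutoff=config.vibronic_cutoff,
                                 zero_classes=config.zero_couplings)
        states = diagonalize(H)
        lines = rotational_strengths(states, H.basis)
        all_lines.append(lines)
        spectra.append(convolve_gaussian(lines, fwhm=config.cd_fwhm))
    return all_lines, spectra, average_spectra(spectra)


def site_spectral_density(site, config: RunConfig,
                          include_modes: bool = True) -> SpectralDensity:
    """Drude-Lorentz bath plus (optionally) the site's L_b discrete modes."""
    modes = []
    if include_modes:
        for f, lam, *lbl in getattr(site, "modes", {}).get("L_b", []):
            label = lbl[0] if lbl else ""
            if config.sd_mode_labels and label not in config.sd_mode_labels:
                continue
            modes.append(VibMode(f, lam, label))
    return SpectralDensity(config.bath_reorg, config.bath_cutoff, modes)


def map_pipeline(sites, config: RunConfig):
    """2D maps for one site list.

    Forster-style full-window maps carry the vibronic progressions in the
    site spectral densities; the narrowband option instead restricts the
    FC-expanded basis to a window (discrete modes then excluded from the
    bath, since their progression lies outside the window).
    """
    narrow = config.narrowband is not None
    H = assemble_hamiltonian(
        sites,
        vibronic_cutoff=config.vibronic_cutoff if narrow else 0.0,
        zero_classes=config.zero_couplings,
        vibronic_labels=("L_b",) if narrow else ())
    sds = [site_spectral_density(s, config, include_modes=not narrow)
           for s in sites]
    if narrow:
        H = narrowband_restrict(H, *config.narrowband)
    else:
        # select basis states on their 0-0 energies, then raise each site
        # to its vertical energy (0-0 + sum of included mode reorgs):
        # the lineshape convention returns the 0-0 to its place
        lo, hi = config.energy_window
        H = narrowband_restrict(H, 0.5 * (lo + hi), hi - lo)
        shifts = np.array([sum(m.reorg_energy for m in sds[i].modes)
                           for i in range(len(sites))])
        H = H.shifted(shifts)
    schemes = [resolve_scheme(s) for s in config.schemes]
    maps = response_2d(H, sds, schemes=schemes,
                       temperature=config.temperature,
                       n_t=config.n_t, dt_fs=config.dt_fs)
    # restore the config's scheme names
    return dict(zip(config.schemes, maps.values()))


def write_summary(path, config: RunConfig, extra: dict, inputs=()):
    """JSON summary embedding the resolved config and input hashes."""
    doc = {"config": config.to_dict(), "results": extra}
    if inputs:
        doc["input_hash"] = content_hash(*inputs)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"cannot serialize {type(o)}")


def read_spectrum_tsv(path):
    from .cd import CDSpectrum

    data = np.loadtxt(path)
    return CDSpectrum(data[:, 0], data[:, 1])
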