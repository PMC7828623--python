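"""Franck-Condon machinery for displaced-harmonic vibronic manifolds.

An electronic transition of an aromatic chromophore (e.g. the L_b state of
tyrosine) couples to a small number of intramolecular modes.  Within the
displaced-harmonic-oscillator model at zero initial temperature, the 0->n
overlap of mode i with Huang-Rhys factor S_i = lambda_i / omega_i is

    |<0|n>| = sqrt( exp(-S) S^n / n! )

and a multimode vibronic level (n_1, n_2, ...) carries the product of the
per-mode amplitudes and an energy offset sum_i n_i * omega_i above the 0-0
line.  Electric/magnetic transition dipoles and monopole charges of the
parent electronic transition are scaled by the (normalised) FC amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np


@dataclass(frozen=True)
class VibMode:
    """A displaced harmonic intramolecular mode.

    frequency and reorg_energy are in cm^-1; label is a free-text tag
    (the tyrosine ring-breathing mode is conventionally "u", the C-H
    bending mode "v").
    """

    frequency: float
    reorg_energy: float
    label: str = ""

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError(f"mode frequency must be > 0, got {self.frequency}")
        if self.reorg_energy < 0:
            raise ValueError("mode reorganization energy must be >= 0")

    @property
    def huang_rhys(self) -> float:
        return self.reorg_energy / self.frequency


def huang_rhys(mode: VibMode) -> float:
    """Huang-Rhys factor S = lambda / omega of a displaced mode."""
    return mode.huang_rhys


def fc_amplitude(S: float, n: int) -> float:
    """0->n Franck-Condon overlap magnitude sqrt(e^-S S^n / n!).

    The squared amplitudes form a Poisson distribution in n and sum to 1.
    """
    if S < 0:
        raise ValueError("Huang-Rhys factor must be >= 0")
    n = int(n)
    if n < 0:
        raise ValueError("vibrational quantum number must be >= 0")
    if S == 0.0:
        return 1.0 if n == 0 else 0.0
    # log-space for large n stability
    log_p = -S + n * math.log(S) - math.lgamma(n + 1)
    return math.exp(0.5 * log_p)


@dataclass(frozen=True)
class VibronicLevel:
    """One vibronic line: per-mode quanta, energy offset above the 0-0
    origin, and the multimode FC amplitude."""

    quanta: tuple[int, ...]
    energy_offset: float
    fc_amplitude: float

    def __post_init__(self):
        if any(q < 0 for q in self.quanta):
            raise ValueError("quanta must be non-negative")
        if not (-1e-12 <= self.fc_amplitude**2 <= 1.0 + 1e-12):
            raise ValueError("fc_amplitude^2 must lie in [0, 1]")


def enumerate_levels(modes: list[VibMode], energy_cutoff: float) -> list[VibronicLevel]:
    """All quanta combinations with sum(n_i * omega_i) <= energy_cutoff.

    Returns levels sorted by energy offset, ties broken lexicographically
    on the quanta tuple.  An empty mode list yields only the zero level.
    """
    if energy_cutoff < 0:
        raise ValueError("energy cutoff must be >= 0")
    if not modes:
        return [VibronicLevel((), 0.0, 1.0)]
    nmax = [int(energy_cutoff // m.frequency) for m in modes]
    S = [m.huang_rhys for m in modes]
    levels = []
    for quanta in product(*(range(n + 1) for n in nmax)):
        offset = sum(q * m.frequency for q, m in zip(quanta, modes))
        if offset > energy_cutoff + 1e-9:
            continue
        amp = 1.0
        for q, s in zip(quanta, S):
            amp *= fc_amplitude(s, q)
        levels.append(VibronicLevel(tuple(quanta), offset, amp))
    levels.sort(key=lambda lv: (lv.energy_offset, lv.quanta))
    return levels


@dataclass
class VibronicManifold:
    """An electronic transition expanded into FC-weighted vibronic levels.

    origin_energy is the 0-0 line in cm^-1.  The truncated set should
    retain at least ``min_weight`` of the total (unit) FC weight.
    """

    origin_energy: float
    modes: list[VibMode]
    levels: list[VibronicLevel] = field(default_factory=list)
    min_weight: float = 0.95

    @classmethod
    def build(cls, origin_energy: float, modes: list[VibMode],
              energy_cutoff: float, min_weight: float = 0.95) -> "VibronicManifold":
        levels = enumerate_levels(modes, energy_cutoff)
        man = cls(origin_energy, list(modes), levels, min_weight)
        man.validate()
        return man

    @property
    def total_fc_weight(self) -> float:
        return sum(lv.fc_amplitude**2 for lv in self.levels)

    def validate(self):
        if not any(all(q == 0 for q in lv.quanta) for lv in self.levels):
            raise ValueError("manifold must contain the all-zero-quanta level")
        if self.total_fc_weight < self.min_weight:
            raise ValueError(
                f"truncated FC weight {self.total_fc_weight:.4f} below "
                f"required {self.min_weight}; raise the energy cutoff")

    def energies(self) -> np.ndarray:
        return np.array([self.origin_energy + lv.energy_offset for lv in self.levels])


def scale_transition(transition: dict, level: VibronicLevel,
                     origin_energy: float | None = None) -> dict:
    """Scale a transition's electric/magnetic dipoles and monopole charges
    by the level's FC amplitude; shift the energy by the level offset.

    ``transition`` is a mapping with keys 'energy' (cm^-1), 'mu' (Debye
    3-vector), optional 'mag' (Bohr-magneton 3-vector) and optional
    'monopoles' (list of {'position': 3-vector A, 'charge': e}).
    Returns a new mapping of the same shape.
    """
    amp = level.fc_amplitude
    origin = transition["energy"] if origin_energy is None else origin_energy
    out = dict(transition)
    out["energy"] = origin + level.energy_offset
    out["mu"] = np.asarray(transition["mu"], dtype=float) * amp
    if transition.get("mag") is not None:
        out["mag"] = np.asarray(transition["mag"], dtype=float) * amp
    if transition.get("monopoles"):
        out["monopoles"] = [
            {"position": np.asarray(m["position"], dtype=float),
             "charge": float(m["charge"]) * amp}
            for m in transition["monopoles"]
        ]
    out["fc_amplitude"] = amp
    out["quanta"] = level.quanta
    return out
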