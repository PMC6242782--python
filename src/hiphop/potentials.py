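"""Pair and angle potentials of the chromatin bead-spring model.

All functions take separations in σ and return energies in kBT.  These are
the reference (and user-facing) implementations; the simulation kernels in
:mod:`hiphop.engine` inline the corresponding forces for speed and are
tested against numerical gradients of these functions.

Potentials:

* WCA — purely repulsive Lennard-Jones truncated at its minimum 2^(1/6)d
  and shifted up by kBT so it vanishes continuously at the cutoff; sterics
  between all non-bonded bead pairs.
* FENE — finitely extensible bond between consecutive chromatin beads
  (WCA core + logarithmic spring diverging at R0).
* Kratky–Porod — bending energy KBEND(1 − cos θ) over bead triplets; sets
  the open-fiber persistence length lp = KBEND/kBT.
* shifted/truncated LJ — attraction between bridging proteins and chromatin
  (ε = 8 kBT for binding beads, 2 kBT non-specific, cutoff 1.8σ).
* harmonic — extruder bonds (with WCA core) and next-nearest-neighbour
  compaction springs of the heteromorphic fiber.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "potential_wca",
    "potential_fene",
    "potential_bend",
    "potential_lj_shifted",
    "potential_harmonic",
    "force_wca",
    "force_fene",
    "force_lj_shifted",
    "force_harmonic",
    "WCA_CUTOFF",
]

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)  # in units of the pair diameter d


def potential_wca(r, d: float = 1.0, kBT: float = 1.0):
    """Weeks–Chandler–Andersen repulsion, zero beyond 2^(1/6) d."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    sr6 = (d / r) ** 6
    u = np.where(r < WCA_CUTOFF * d, 4.0 * kBT * (sr6**2 - sr6) + kBT, 0.0)
    return u if u.ndim else float(u)


def force_wca(r, d: float = 1.0, kBT: float = 1.0):
    """Magnitude of -dU/dr for WCA (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    sr6 = (d / r) ** 6
    f = np.where(r < WCA_CUTOFF * d, 4.0 * kBT * (12.0 * sr6**2 - 6.0 * sr6) / r, 0.0)
    return f if f.ndim else float(f)


def potential_fene(r, KFENE: float = 30.0, R0: float = 1.6, d: float = 1.0,
                   kBT: float = 1.0):
    """FENE bond: WCA core plus -(K R0²/2) log(1 − (r/R0)²); diverges at R0."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    if np.any(r >= R0):
        raise ValueError("FENE bond extended beyond R0 (dt too large?)")
    spring = -(KFENE * R0**2 / 2.0) * np.log(1.0 - (r / R0) ** 2)
    u = potential_wca(r, d, kBT) + spring
    return u if np.ndim(u) else float(u)


def force_fene(r, KFENE: float = 30.0, R0: float = 1.6, d: float = 1.0,
               kBT: float = 1.0):
    """-dU/dr for the FENE bond (negative = attractive pull toward r=0)."""
    r = np.asarray(r, dtype=float)
    if np.any(r >= R0):
        raise ValueError("FENE bond extended beyond R0")
    spring = -KFENE * r / (1.0 - (r / R0) ** 2)
    f = force_wca(r, d, kBT) + spring
    return f if np.ndim(f) else float(f)


def potential_bend(theta, KBEND: float = 4.0):
    """Kratky–Porod bending energy KBEND (1 − cos θ), θ the angle between
    consecutive bond vectors (0 = straight chain)."""
    theta = np.asarray(theta, dtype=float)
    u = KBEND * (1.0 - np.cos(theta))
    return u if u.ndim else float(u)


def potential_lj_shifted(r, eps: float = 8.0, rcut: float = 1.8, d: float = 1.0):
    """Lennard-Jones truncated at ``rcut`` and shifted to vanish there.

    Attractive well between 2^(1/6)d and rcut; used for TF–chromatin
    interactions (eps=8 kBT specific, 2 kBT non-specific).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    if rcut <= WCA_CUTOFF * d:
        warnings.warn("rcut below the LJ minimum: interaction is purely repulsive")

    def _lj0(x):
        s6 = (d / x) ** 6
        return 4.0 * eps * (s6**2 - s6)

    u = np.where(r < rcut, _lj0(r) - _lj0(np.asarray(rcut, dtype=float)), 0.0)
    return u if u.ndim else float(u)


def force_lj_shifted(r, eps: float = 8.0, rcut: float = 1.8, d: float = 1.0):
    r = np.asarray(r, dtype=float)
    s6 = (d / r) ** 6
    f = np.where(r < rcut, 4.0 * eps * (12.0 * s6**2 - 6.0 * s6) / r, 0.0)
    return f if f.ndim else float(f)


def potential_harmonic(r, K: float = 40.0, r0: float = 1.5):
    """Harmonic spring K (r − r0)²; note the convention has no 1/2 factor."""
    r = np.asarray(r, dtype=float)
    u = K * (r - r0) ** 2
    return u if u.ndim else float(u)


def force_harmonic(r, K: float = 40.0, r0: float = 1.5):
    r = np.asarray(r, dtype=float)
    f = -2.0 * K * (r - r0)
    return f if f.ndim else float(f)
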