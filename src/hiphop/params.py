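"""Simulation parameters and unit system.

Internal units: length in σ (one chromatin bead diameter), energy in kBT,
mass in bead masses m.  The natural time unit is τLJ = σ·sqrt(m/kBT); with
friction γ = 2 the Brownian time (time for a bead to diffuse its own
diameter) is τB = γ σ²/kBT = 2 τLJ, so the dynamics are overdamped.
Physical values of σ (nm) and τLJ (ms) are not fixed a priori — they are
obtained afterwards by calibrating simulated FISH distributions and bead
MSD curves against experiment (see :mod:`hiphop.scoring`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict


@dataclass
class SimParams:
    """Parameters of the chromatin Langevin engine (simulation units).

    Defaults follow the published parameterisation of the model: FENE bonds
    KFENE=30 kBT with R0=1.6σ, Kratky–Porod bending KBEND=4 kBT (persistence
    length lp = KBEND/kBT = 4σ for the open fiber), specific/non-specific
    TF–chromatin attractions of 8/2 kBT truncated at 1.8σ, extruder springs
    40 kBT with rest length 1.5σ, TF switching rate 1.25e-4 /τLJ, extrusion
    speed 2 bp/τLJ and unbinding rate 2.5e-5 /τLJ (processivity kex/koff =
    80 kbp), timestep 0.01 τLJ, periodic box of side 150σ and 4000 TFs.
    KHARM/r0_harm (compaction springs) mirror the extruder bond; kon and
    n_le are not pinned by the published parameter set and are configurable.
    """

    # core units
    sigma: float = 1.0
    kBT: float = 1.0
    m: float = 1.0
    gamma: float = 2.0
    dt: float = 0.01
    # bonded interactions
    KFENE: float = 30.0
    R0: float = 1.6
    KBEND: float = 4.0
    # TF (bridging protein) interactions
    eps_specific: float = 8.0
    eps_nonspecific: float = 2.0
    rcut: float = 1.8
    ksw: float = 1.25e-4
    n_tf: int = 4000
    # loop extrusion
    KEXTR: float = 40.0
    r0_extr: float = 1.5
    kon: float = 1e-3
    kex: float = 2.0           # bp per τLJ
    koff: float = 2.5e-5
    n_le: int | None = None    # default ceil(n_beads / 100), resolved at build
    # heteromorphic compaction springs
    KHARM: float = 40.0
    r0_harm: float = 1.5
    # system / schedule
    resolution: int = 1000     # bp per bead
    box: float = 150.0
    t_total: float = 50e4
    t_discard: float = 10e4
    t_snapshot: float = 2e3
    t_equil: float = 10e4      # pre-run without TF attraction / extruders
    t_kinetic: float = 10.0    # interval between TF-switch / LE kinetic updates
    # neighbour list
    skin: float = 0.4
    rebuild_every: int = 10

    def __post_init__(self) -> None:
        for name in ("sigma", "kBT", "m", "gamma", "dt", "KFENE", "R0", "KBEND",
                     "eps_specific", "eps_nonspecific", "rcut", "KEXTR",
                     "r0_extr", "kex", "KHARM", "r0_harm", "box"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ksw", "kon", "koff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dt >= 0.1:
            raise ValueError("dt must be well below τLJ")

    # -- derived quantities -------------------------------------------------
    @property
    def tau_lj(self) -> float:
        """Natural Lennard-Jones time σ·sqrt(m/kBT)."""
        return self.sigma * math.sqrt(self.m / self.kBT)

    @property
    def tau_brownian(self) -> float:
        """Bead self-diffusion time τB = γσ²/kBT (=2 τLJ at defaults)."""
        return self.gamma * self.sigma**2 / self.kBT

    @property
    def persistence_length(self) -> float:
        """Open-fiber persistence length lp = KBEND/kBT, in σ."""
        return self.KBEND / self.kBT

    @property
    def processivity_bp(self) -> float:
        """Expected loop length extruded before unbinding, kex/koff, in bp."""
        return self.kex / self.koff

    def n_snapshots_retained(self) -> int:
        """Snapshots kept for analysis: cadence t_snapshot over
        (t_total - t_discard)."""
        return int(round((self.t_total - self.t_discard) / self.t_snapshot))

    def resolve_n_le(self, n_beads: int) -> int:
        return self.n_le if self.n_le is not None else math.ceil(n_beads / 100)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(**d)


@dataclass
class UnitMapping:
    """Physical calibration of the simulation units."""

    sigma_nm: float
    tau_ms: float

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0 or self.tau_ms <= 0:
            raise ValueError("unit mapping must be positive")

    @property
    def tau_brownian_ms(self) -> float:
        return 2.0 * self.tau_ms
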