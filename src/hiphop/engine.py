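"""Langevin-dynamics engine for the heteromorphic chromatin fiber.

The system is a FENE/Kratky-Porod bead-spring chain (1 bead = ``resolution``
bp of chromatin) plus freely diffusing bridging-protein (TF) beads, in a
periodic cubic box.  Three mechanisms shape the ensemble:

* **bridging** — TFs in the binding state are attracted to marked chromatin
  beads (8 kBT) and weakly to all others (2 kBT); they switch between
  binding and non-binding states at rate ``ksw``, which keeps protein
  clusters dynamic;
* **loop extrusion** — a fixed pool of extruder springs that grow loops and
  halt at convergently oriented CTCF anchors (:mod:`hiphop.extrusion`);
* **heteromorphic compaction** — harmonic i,i+2 springs crumple the fiber
  wherever both beads lack the H3K27ac mark, giving locally thicker,
  more compact chromatin; acetylated (open) regions keep the plain fiber.

``run_simulation`` equilibrates the bare polymer first (no TF attraction,
no extruders), then switches the mechanisms on and records snapshots at a
fixed cadence.  Given a seed, trajectories are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .annotation import AnchorSite, LocusModel, realize_anchors
from .extrusion import Extruders, le_update, make_halting_arrays
from .params import SimParams
from .potentials import (WCA_CUTOFF, potential_fene, potential_harmonic,
                         potential_lj_shifted, potential_wca)

__all__ = [
    "SystemState",
    "Trajectory",
    "IntegrationError",
    "build_system",
    "run_simulation",
    "langevin_step",
    "tf_switch_update",
    "total_energy_reference",
    "compute_forces",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator detects a blow-up (non-finite coordinates
    or a FENE bond stretched to its maximum extension)."""


_STATUS_MSG = {
    1: "FENE bond reached maximum extension R0 (timestep too large?)",
    3: "non-finite coordinate: integration blow-up",
}


@dataclass
class SystemState:
    """Mutable state of one simulation replicate."""

    pos: np.ndarray            # (n_beads + n_tf, 3), σ units, unwrapped
    vel: np.ndarray
    n_beads: int
    binding: np.ndarray        # uint8 per chromatin bead
    open_fiber: np.ndarray     # bool per chromatin bead
    tf_state: np.ndarray       # uint8 per TF: 1 = binding state
    compaction_pairs: np.ndarray   # (m, 2) int64
    extruders: Extruders
    anchors: list[AnchorSite]
    box: float
    time: float = 0.0

    @property
    def n_tf(self) -> int:
        return self.pos.shape[0] - self.n_beads

    def spring_arrays(self, params: SimParams):
        """Concatenate compaction and bound-extruder springs for the kernel."""
        ext = self.extruders.spring_pairs()
        comp = self.compaction_pairs
        sp = np.vstack([comp, ext]) if len(ext) or len(comp) else np.empty((0, 2), np.int64)
        sp_K = np.concatenate([
            np.full(len(comp), params.KHARM),
            np.full(len(ext), params.KEXTR),
        ])
        sp_r0 = np.concatenate([
            np.full(len(comp), params.r0_harm),
            np.full(len(ext), params.r0_extr),
        ])
        return (np.ascontiguousarray(sp[:, 0]) if len(sp) else np.empty(0, np.int64),
                np.ascontiguousarray(sp[:, 1]) if len(sp) else np.empty(0, np.int64),
                sp_K, sp_r0)


@dataclass
class Trajectory:
    """Snapshots of chromatin bead positions at a fixed cadence."""

    times: np.ndarray               # τLJ since mechanisms switched on
    positions: np.ndarray           # (n_snap, n_beads, 3), σ units
    params: SimParams
    model: LocusModel | None = None
    seed: int | None = None
    box: float | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions length mismatch")

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    def retained(self) -> "Trajectory":
        """Snapshots after the discard period (t > t_discard)."""
        mask = self.times > self.params.t_discard + 1e-9
        return Trajectory(self.times[mask], self.positions[mask],
                          self.params, self.model, self.seed, self.box)

    @property
    def snapshots(self) -> np.ndarray:
        return self.positions


# ---------------------------------------------------------------------------
# system construction
# ---------------------------------------------------------------------------

def compaction_spring_pairs(open_fiber: np.ndarray) -> np.ndarray:
    """i,i+2 spring pairs where *both* endpoint beads are non-acetylated."""
    open_fiber = np.asarray(open_fiber, dtype=bool)
    n = len(open_fiber)
    idx = [
        (i, i + 2)
        for i in range(n - 2)
        if not open_fiber[i] and not open_fiber[i + 2]
    ]
    return np.asarray(idx, dtype=np.int64).reshape(-1, 2)


def _random_walk(n: int, step: float, box: float, rng: np.random.Generator) -> np.ndarray:
    """Random-walk initial chain centred in the box."""
    steps = rng.standard_normal((n - 1, 3))
    steps *= step / np.linalg.norm(steps, axis=1, keepdims=True)
    pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    pos -= pos.mean(axis=0)
    pos += box / 2.0
    return pos


def build_system(model: LocusModel, params: SimParams, hiphop_mode: bool = True,
                 rng: np.random.Generator | None = None,
                 tf_on: bool = True) -> SystemState:
    """Initialise a replicate: random-walk chain, uniformly placed TFs,
    compaction springs on non-acetylated i,i+2 pairs (heteromorphic mode),
    extruder pool (initial span i,i+3 in heteromorphic mode, i,i+2
    otherwise) and anchors realized per occupancy."""
    rng = np.random.default_rng() if rng is None else rng
    n = model.n_beads
    n_tf = params.n_tf if tf_on else 0
    density = (n + n_tf) / params.box**3
    if density > 0.5:
        raise ValueError("bead density too high for the requested box")
    if n * 0.97 > 0 and math.sqrt(n) * 3 > params.box:
        # random-walk extent ~ sqrt(N); min-image bookkeeping needs headroom
        raise ValueError("box too small for the chain length")

    chain = _random_walk(n, 0.97, params.box, rng)
    tfs = rng.uniform(0.0, params.box, size=(n_tf, 3))
    pos = np.vstack([chain, tfs])
    vel = rng.standard_normal(pos.shape) * math.sqrt(params.kBT / params.m)

    comp = (compaction_spring_pairs(model.open_fiber) if hiphop_mode
            else np.empty((0, 2), dtype=np.int64))
    gap = 3 if hiphop_mode else 2
    n_le = params.resolve_n_le(n)
    extruders = Extruders.empty(n_le, n, init_gap=gap)
    anchors = realize_anchors(model, rng)
    tf_state = (rng.random(n_tf) < 0.5).astype(np.uint8)

    return SystemState(
        pos=pos, vel=vel, n_beads=n,
        binding=model.binding.astype(np.uint8),
        open_fiber=model.open_fiber.copy(),
        tf_state=tf_state,
        compaction_pairs=comp,
        extruders=extruders,
        anchors=anchors,
        box=params.box,
    )


# ---------------------------------------------------------------------------
# stochastic updates
# ---------------------------------------------------------------------------

def tf_switch_update(state: SystemState, params: SimParams, dt_window: float,
                     rng: np.random.Generator) -> SystemState:
    """Flip each TF between binding and non-binding states as a symmetric
    Poisson process at rate ksw over ``dt_window``."""
    if state.n_tf == 0 or params.ksw == 0.0:
        return state
    p_flip = 1.0 - math.exp(-params.ksw * dt_window)
    flips = rng.random(state.n_tf) < p_flip
    state.tf_state[flips] ^= 1
    return state


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _run_chunk(state: SystemState, params: SimParams, nsteps: int,
               rng: np.random.Generator, attract_on: bool,
               fmax: float = 0.0, noise_scale: float = 1.0,
               _buffers: dict | None = None) -> None:
    sp_i, sp_j, sp_K, sp_r0 = state.spring_arrays(params)
    n = state.pos.shape[0]
    # only TF attractions reach beyond the WCA cutoff
    reach = params.rcut if (attract_on and state.n_tf > 0) else WCA_CUTOFF
    cutoff = reach + params.skin
    cap = max(4096, n * 40)
    if _buffers is not None and "pairs" in _buffers:
        pairs = _buffers["pairs"]
    else:
        pairs = np.empty((cap, 2), dtype=np.int64)
        if _buffers is not None:
            _buffers["pairs"] = pairs
    while True:
        seed = int(rng.integers(0, 2**31 - 1))
        status = _kernels.integrate_chunk(
            state.pos, state.vel, nsteps, params.dt, params.gamma, params.m,
            params.kBT, state.n_beads, state.binding, state.tf_state,
            attract_on, params.KFENE, params.R0, params.KBEND,
            params.eps_specific, params.eps_nonspecific, params.rcut,
            sp_i, sp_j, sp_K, sp_r0, state.box, cutoff,
            params.rebuild_every, fmax, seed, noise_scale, pairs)
        if status == 2:
            pairs = np.empty((pairs.shape[0] * 2, 2), dtype=np.int64)
            if _buffers is not None:
                _buffers["pairs"] = pairs
            continue  # deterministic retry: kernel reseeds itself per call
        break
    if status in _STATUS_MSG:
        raise IntegrationError(f"t={state.time:.1f}: {_STATUS_MSG[status]}")
    state.time += nsteps * params.dt


def langevin_step(state: SystemState, params: SimParams,
                  rng: np.random.Generator, attract_on: bool = True,
                  noise_scale: float = 1.0) -> SystemState:
    """One BAOAB Langevin step (friction γ, noise amplitude set by the
    fluctuation-dissipation relation; ``noise_scale=0`` disables noise)."""
    _run_chunk(state, params, 1, rng, attract_on, noise_scale=noise_scale)
    return state


def run_simulation(model: LocusModel, params: SimParams, rng_seed: int,
                   hiphop_mode: bool = True, tf_on: bool = True,
                   le_on: bool = True) -> Trajectory:
    """Full protocol: soft push-off, bare-polymer equilibration, then the
    production run with TF attraction, switching, and loop extrusion.

    Snapshots of chromatin bead positions are taken every ``t_snapshot``
    from the moment the mechanisms are switched on; ``Trajectory.retained``
    drops the first ``t_discard``.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(rng_seed)
    state = build_system(model, params, hiphop_mode, rng, tf_on=tf_on)
    halt_left, halt_right = make_halting_arrays(state.anchors, model.n_beads)
    buffers: dict = {}

    def chunk(t: float, attract: bool, fmax: float = 0.0) -> None:
        nsteps = max(1, int(round(t / params.dt)))
        _run_chunk(state, params, nsteps, rng, attract, fmax=fmax,
                   _buffers=buffers)

    # soft push-off: capped forces relax random-walk overlaps
    chunk(50.0, attract=False, fmax=200.0)
    # equilibration without TF attraction or extruders
    remaining = params.t_equil
    while remaining > 0:
        step = min(2e3, remaining)
        chunk(step, attract=False)
        remaining -= step

    # production
    state.time = 0.0
    if params.t_kinetic <= 0 or params.t_snapshot % params.t_kinetic > 1e-9:
        raise ValueError("t_kinetic must divide t_snapshot")
    n_windows = int(round(params.t_total / params.t_kinetic))
    snap_every = int(round(params.t_snapshot / params.t_kinetic))
    times, snaps = [], []
    for w in range(1, n_windows + 1):
        chunk(params.t_kinetic, attract=tf_on)
        if tf_on:
            tf_switch_update(state, params, params.t_kinetic, rng)
        if le_on:
            le_update(state.extruders, params, halt_left, halt_right,
                      params.t_kinetic, rng)
        if w % snap_every == 0:
            times.append(w * params.t_kinetic)
            snaps.append(state.pos[:model.n_beads].copy())

    return Trajectory(
        times=np.asarray(times), positions=np.asarray(snaps),
        params=params, model=model, seed=rng_seed, box=params.box)


# ---------------------------------------------------------------------------
# reference energy (oracle for force tests)
# ---------------------------------------------------------------------------

def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.rint(d / box)


def total_energy_reference(state: SystemState, params: SimParams,
                           attract_on: bool = True) -> float:
    """Total potential energy by direct all-pairs summation of the
    potentials in :mod:`hiphop.potentials`.  O(N²); tests only."""
    pos = state.pos
    n_beads = state.n_beads
    n = pos.shape[0]
    box = state.box
    e = 0.0
    for i in range(n_beads - 1):
        r = float(np.linalg.norm(_min_image(pos[i] - pos[i + 1], box)))
        e += potential_fene(r, params.KFENE, params.R0)
    for i in range(1, n_beads - 1):
        a = _min_image(pos[i] - pos[i - 1], box)
        b = _min_image(pos[i + 1] - pos[i], box)
        cth = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
        e += params.KBEND * (1.0 - np.clip(cth, -1.0, 1.0))
    sp_i, sp_j, sp_K, sp_r0 = state.spring_arrays(params)
    for s in range(len(sp_i)):
        r = float(np.linalg.norm(_min_image(pos[sp_i[s]] - pos[sp_j[s]], box)))
        e += potential_harmonic(r, sp_K[s], sp_r0[s])
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = i < n_beads, j < n_beads
            if ci and cj and j - i == 1:
                continue
            r = float(np.linalg.norm(_min_image(pos[i] - pos[j], box)))
            if attract_on and ci != cj:
                bead, tf = (i, j - n_beads) if ci else (j, i - n_beads)
                if state.tf_state[tf] == 1:
                    eps = params.eps_specific if state.binding[bead] else params.eps_nonspecific
                    e += potential_lj_shifted(r, eps, params.rcut)
                    continue
            e += potential_wca(r)
    return e


def compute_forces(state: SystemState, params: SimParams,
                   attract_on: bool = True) -> np.ndarray:
    """Forces on every particle from the simulation kernel (all-pairs list)."""
    sp_i, sp_j, sp_K, sp_r0 = state.spring_arrays(params)
    return _kernels.compute_forces_array(
        state.pos, state.n_beads, state.binding, state.tf_state, attract_on,
        params, sp_i, sp_j, sp_K, sp_r0, all_pairs_cutoff=params.box)
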