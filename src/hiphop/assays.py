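"""In-silico Capture-C, FISH, and distance/contact maps.

Capture-C profiles are generated from conformational snapshots by
stochastic sampling: for a viewpoint bead, a random chromatin bead is
accepted as "interacting" with probability f(d) = exp(−d²/d0²) of its
spatial separation d, with d0 = 3.5σ the typical interaction range; the
attempt is repeated N−1 times per snapshot.  The same number of attempts is
made for every viewpoint, so rejected attempts stand in for interactions
with chromatin outside the simulated region.  Raw per-bead counts are
collected into sliding bins (3-kbp bins fed by a 6-kbp window, so each
interior count lands in exactly two bins) and can be scaled jointly onto an
experimental total.

FISH separations are centre-of-mass distances between probe bead ranges,
one sample per retained snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Trajectory

__all__ = [
    "InteractionProfile",
    "DistanceDistribution",
    "contact_probability",
    "sample_capture_c",
    "expected_capture_c",
    "bin_profile",
    "scale_profiles",
    "directionality_index",
    "simulated_fish",
    "distance_and_contact_maps",
]

D0_DEFAULT = 3.5  # σ; typical interaction length of the acceptance kernel


@dataclass
class InteractionProfile:
    """Binned interaction counts for one viewpoint."""

    viewpoint: int                 # bead index
    counts: np.ndarray             # one value per bin
    bin_size: int = 3000           # bp
    window: int = 6000             # bp
    region_start: int = 0          # bp (bin i covers region_start + [i*bin, (i+1)*bin))
    scale: float = 1.0
    rejected_fraction: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def bin_centers_bp(self) -> np.ndarray:
        return self.region_start + (np.arange(len(self.counts)) + 0.5) * self.bin_size


@dataclass
class DistanceDistribution:
    """Samples of probe-pair separations (simulated or experimental)."""

    probe_pair: tuple
    samples: np.ndarray
    source: str = "simulated"      # or "experimental"
    units: str = "sigma"           # or "nm"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(self.samples < 0):
            raise ValueError("separations must be non-negative")


def contact_probability(d, d0: float = D0_DEFAULT):
    """Acceptance probability f(d) = exp(−d²/d0²)."""
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    p = np.exp(-(d / d0) ** 2)
    return p if p.ndim else float(p)


def _snapshot_distances(snap: np.ndarray, viewpoint: int) -> np.ndarray:
    return np.linalg.norm(snap - snap[viewpoint], axis=1)


def sample_capture_c(trajectory: Trajectory, viewpoints: list[int],
                     d0: float = D0_DEFAULT, attempts_per_snapshot: int | None = None,
                     rng: np.random.Generator | None = None,
                     repeats: int = 1):
    """Stochastic per-bead interaction counts for each viewpoint.

    ``attempts_per_snapshot`` defaults to N−1 (one pass over the locus);
    ``repeats`` runs the whole scheme multiple times per snapshot for more
    simulated reads.  Returns ``(counts, rejected_fraction)`` dicts keyed
    by viewpoint; the rejected fraction represents interactions with loci
    outside the simulated region.
    """
    rng = np.random.default_rng() if rng is None else rng
    traj = trajectory.retained()
    if traj.n_snapshots == 0:
        raise ValueError("no retained snapshots to sample")
    n = traj.positions.shape[1]
    attempts = (n - 1) if attempts_per_snapshot is None else attempts_per_snapshot
    counts = {v: np.zeros(n) for v in viewpoints}
    total_attempts = {v: 0 for v in viewpoints}
    for snap in traj.positions:
        for v in viewpoints:
            d = _snapshot_distances(snap, v)
            p = contact_probability(d, d0)
            for _ in range(repeats):
                picks = rng.integers(0, n, size=attempts)
                accept = rng.random(attempts) < p[picks]
                np.add.at(counts[v], picks[accept], 1.0)
                total_attempts[v] += attempts
    rejected = {v: 1.0 - counts[v].sum() / total_attempts[v] for v in viewpoints}
    return counts, rejected


def expected_capture_c(trajectory: Trajectory, viewpoints: list[int],
                       d0: float = D0_DEFAULT,
                       attempts_per_snapshot: int | None = None,
                       repeats: int = 1) -> dict[int, np.ndarray]:
    """Variance-free expected counts: (attempts/N)·f(d) summed over
    snapshots.  Same units as :func:`sample_capture_c`."""
    traj = trajectory.retained()
    if traj.n_snapshots == 0:
        raise ValueError("no retained snapshots to sample")
    n = traj.positions.shape[1]
    attempts = (n - 1) if attempts_per_snapshot is None else attempts_per_snapshot
    out = {}
    for v in viewpoints:
        acc = np.zeros(n)
        for snap in traj.positions:
            acc += contact_probability(_snapshot_distances(snap, v), d0)
        out[v] = acc * (attempts * repeats / n)
    return out


def bin_profile(raw_counts: np.ndarray, resolution: int, viewpoint: int,
                bin_size: int = 3000, window: int = 6000,
                region_start: int = 0) -> InteractionProfile:
    """Sliding-window binning of per-bead counts.

    Bin ``b`` covers genomic span ``[b·bin_size, (b+1)·bin_size)`` relative
    to the region start and accumulates all counts whose bead centres fall
    within a ``window`` centred on the bin centre.  With the default
    window = 2·bin_size each interior count contributes to exactly two
    bins; windows are truncated at the locus ends.
    """
    if window < bin_size:
        raise ValueError("window must be at least bin_size")
    raw_counts = np.asarray(raw_counts, dtype=float)
    n = len(raw_counts)
    locus_bp = n * resolution
    n_bins = int(np.ceil(locus_bp / bin_size))
    bead_centers = (np.arange(n) + 0.5) * resolution
    values = np.zeros(n_bins)
    half = window / 2.0
    for b in range(n_bins):
        c = (b + 0.5) * bin_size
        mask = (bead_centers >= c - half) & (bead_centers < c + half)
        values[b] = raw_counts[mask].sum()
    return InteractionProfile(viewpoint=viewpoint, counts=values,
                              bin_size=bin_size, window=window,
                              region_start=region_start)


def scale_profiles(sim_profiles: list[InteractionProfile],
                   reference_total: float) -> list[InteractionProfile]:
    """Scale all simulated profiles by one joint factor so their grand
    total matches ``reference_total`` (the experimental total over all
    targets in all cell types within the region).  A single global factor
    preserves target-to-target and cell-type variation."""
    if reference_total <= 0:
        raise ValueError("reference_total must be positive")
    sim_total = sum(p.counts.sum() for p in sim_profiles)
    if sim_total <= 0:
        raise ValueError("simulated profiles are all zero; cannot scale")
    factor = reference_total / sim_total
    out = []
    for p in sim_profiles:
        out.append(InteractionProfile(
            viewpoint=p.viewpoint, counts=p.counts * factor,
            bin_size=p.bin_size, window=p.window,
            region_start=p.region_start, scale=p.scale * factor,
            rejected_fraction=p.rejected_fraction))
    return out


def directionality_index(raw_counts: np.ndarray, viewpoint: int,
                         resolution: int, window_bp: float = 2e6) -> float:
    """(Nds − Nus)/(Nds + Nus) over reads within ``window_bp`` of the
    viewpoint; NaN when no in-window reads exist."""
    raw_counts = np.asarray(raw_counts, dtype=float)
    n = len(raw_counts)
    beads = int(window_bp // (2 * resolution))
    lo = max(0, viewpoint - beads)
    hi = min(n, viewpoint + beads + 1)
    nus = raw_counts[lo:viewpoint].sum()
    nds = raw_counts[viewpoint + 1:hi].sum()
    if nus + nds == 0:
        return float("nan")
    return float((nds - nus) / (nds + nus))


def simulated_fish(trajectory: Trajectory,
                   probes: list[tuple[int, int]] | None = None
                   ) -> dict[tuple, DistanceDistribution]:
    """Centre-of-mass separations of every probe pair, one sample per
    retained snapshot.  Probes are half-open bead ranges."""
    traj = trajectory.retained()
    if traj.n_snapshots == 0:
        raise ValueError("no retained snapshots")
    if probes is None:
        if traj.model is None or not traj.model.probes:
            raise ValueError("no probes given and none on the locus model")
        probes = traj.model.probes
    n = traj.positions.shape[1]
    for a, b in probes:
        if not (0 <= a < b <= n):
            raise ValueError(f"probe ({a}, {b}) outside the locus")
    coms = {p: traj.positions[:, p[0]:p[1], :].mean(axis=1) for p in probes}
    out = {}
    for i in range(len(probes)):
        for j in range(i + 1, len(probes)):
            pa, pb = probes[i], probes[j]
            sep = np.linalg.norm(coms[pa] - coms[pb], axis=1)
            out[(pa, pb)] = DistanceDistribution((pa, pb), sep)
    return out


def distance_and_contact_maps(trajectory: Trajectory,
                              d0: float = D0_DEFAULT,
                              bead_slice: slice | None = None):
    """Mean pairwise-distance matrix (σ) and contact map (mean f(d) over
    snapshots) for the analysis region."""
    from scipy.spatial.distance import pdist, squareform

    traj = trajectory.retained()
    if traj.n_snapshots == 0:
        raise ValueError("no retained snapshots")
    pos = traj.positions if bead_slice is None else traj.positions[:, bead_slice, :]
    n = pos.shape[1]
    dist = np.zeros((n, n))
    contact = np.zeros((n, n))
    for snap in pos:
        d = squareform(pdist(snap))
        dist += d
        contact += contact_probability(d, d0)
    dist /= len(pos)
    contact /= len(pos)
    return dist, contact
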