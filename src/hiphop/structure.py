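"""Ensemble-level structural statistics of simulated conformations.

Covers the conformation-space distance metric Γ and hierarchical
clustering, size/shape measures (radius of gyration, relative shape
anisotropy), three-probe FISH summaries (locus size S, conformation-space
variability volume), promoter-enhancer interaction grouping, the
transcriptional activity score T, mean-squared displacement, and the
worm-like-chain persistence-length estimate for the crumpled fiber.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist

__all__ = [
    "ConformationEnsemble",
    "gamma_distance",
    "gamma_matrix",
    "cluster_conformations",
    "size_and_shape",
    "locus_size",
    "variability_volume",
    "interaction_grouping",
    "activity_score",
    "mean_squared_displacement",
    "smooth_contour",
    "wlc_rg2",
    "persistence_length",
]


@dataclass
class ConformationEnsemble:
    """A set of snapshots over a shared analysis region (bead positions)."""

    positions: np.ndarray      # (n_conf, n_beads, 3)
    provenance: dict | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_conf, n_beads, 3)")

    @property
    def n_conformations(self) -> int:
        return self.positions.shape[0]

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]


def gamma_distance(conf_a: np.ndarray, conf_b: np.ndarray) -> float:
    """Conformation distance Γ = sqrt[ (1/(n(n−1))) Σ_{i≠j} (dij(A) − dij(B))² ].

    A rigid-motion-invariant metric on the vectors of internal pairwise
    separations; the sum over ordered pairs i≠j counts each unordered pair
    twice, matching the n(n−1) normalisation.
    """
    conf_a = np.asarray(conf_a, dtype=float)
    conf_b = np.asarray(conf_b, dtype=float)
    if conf_a.shape != conf_b.shape or conf_a.ndim != 2:
        raise ValueError("conformations must share shape (n, 3)")
    n = conf_a.shape[0]
    if n < 2:
        raise ValueError("need at least two beads")
    da = pdist(conf_a)
    db = pdist(conf_b)
    return float(np.sqrt(2.0 * np.sum((da - db) ** 2) / (n * (n - 1))))


def gamma_matrix(ensemble: ConformationEnsemble) -> np.ndarray:
    """Condensed Γ distance vector over all conformation pairs."""
    n = ensemble.n_beads
    dvecs = np.stack([pdist(c) for c in ensemble.positions])
    m = ensemble.n_conformations
    out = np.empty(m * (m - 1) // 2)
    k = 0
    for i in range(m):
        diff = dvecs[i + 1:] - dvecs[i]
        vals = np.sqrt(2.0 * np.sum(diff**2, axis=1) / (n * (n - 1)))
        out[k:k + len(vals)] = vals
        k += len(vals)
    return out


def cluster_conformations(ensemble: ConformationEnsemble,
                          method: str = "average",
                          cut_height: float | None = None):
    """Agglomerative clustering of conformations on the Γ metric.

    Returns ``(linkage_matrix, cophenetic_coefficient, labels)``; labels
    are flat clusters at ``cut_height`` (None → all in one cluster).
    The cophenetic correlation coefficient measures how faithfully the
    dendrogram distances reproduce the underlying Γ distances (NaN for a
    degenerate all-zero matrix).
    """
    if ensemble.n_conformations < 2:
        raise ValueError("need at least two conformations")
    condensed = gamma_matrix(ensemble)
    Z = linkage(condensed, method=method)
    if np.allclose(condensed, 0.0):
        coph = float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coph = float(cophenet(Z, condensed)[0])
    if cut_height is None:
        labels = np.ones(ensemble.n_conformations, dtype=int)
    else:
        labels = fcluster(Z, t=cut_height, criterion="distance")
    return Z, coph, labels


def size_and_shape(snapshot: np.ndarray) -> tuple[float, float]:
    """Radius of gyration and relative shape anisotropy κ² of a bead cloud.

    κ² = 1 − 3(λ1λ2 + λ2λ3 + λ3λ1)/(λ1+λ2+λ3)² for eigenvalues λ of the
    3×3 positional gyration tensor: 0 for a spherically symmetric
    arrangement, 1 for a perfectly linear one.  NaN anisotropy for
    coincident beads.
    """
    x = np.asarray(snapshot, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two beads")
    c = x - x.mean(axis=0)
    rg = float(np.sqrt(np.mean(np.sum(c**2, axis=1))))
    g = c.T @ c / len(c)
    lam = np.linalg.eigvalsh(g)
    tr = lam.sum()
    if tr <= 0:
        return 0.0, float("nan")
    kappa2 = 1.0 - 3.0 * (lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]) / tr**2
    return rg, float(kappa2)


def locus_size(triple) -> float:
    """Locus size S = (1/3)·sqrt(d12² + d23² + d31²) from three probe-pair
    separations; equals the radius of gyration of the three probe centres."""
    d = np.asarray(triple, dtype=float)
    if d.shape != (3,):
        raise ValueError("need exactly three separations")
    if np.any(d < 0):
        raise ValueError("separations must be non-negative")
    s = np.sort(d)
    if s[2] > s[0] + s[1] + 1e-9 * max(s[2], 1.0):
        warnings.warn("separations violate the triangle inequality")
    return float(np.sqrt(np.sum(d**2)) / 3.0)


def variability_volume(triples: np.ndarray) -> float:
    """Conformation-space variability of a cell population.

    ``triples`` is (N, 3): per cell the three probe-pair separations.
    The gyration tensor over the cloud,
    Gαβ = (1/2N²) ΣᵢΣⱼ (dα(i)−dα(j))(dβ(i)−dβ(j)), equals the covariance
    matrix of the triples (1/N convention); the volume measure is the
    product of its three principal moments, i.e. det G (units length⁶).
    """
    x = np.asarray(triples, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("triples must have shape (N, 3)")
    if x.shape[0] < 4:
        warnings.warn("fewer than 4 triples: gyration tensor is degenerate")
        return 0.0
    c = x - x.mean(axis=0)
    g = c.T @ c / x.shape[0]
    lam = np.linalg.eigvalsh(g)
    return float(np.prod(np.clip(lam, 0.0, None)))


GROUP_LABELS = {
    1: "no interactions",
    2: "promoter-URR",
    3: "promoter-DRR",
    4: "URR-DRR only",
    5: "all three",
}


def interaction_grouping(d_p_e1: np.ndarray, d_p_e2: np.ndarray,
                         d_e1_e2: np.ndarray, threshold: float = 6.0) -> np.ndarray:
    """Assign each conformation to one of 5 interaction groups.

    Two regions interact when their separation is below ``threshold``
    (default 6σ).  Groups: 1 promoter contacts neither enhancer; 2
    promoter-enhancer1 only; 3 promoter-enhancer2 only; 4 the enhancers
    contact each other but not the promoter; 5 all three together.
    Conformations where the promoter contacts both enhancers are counted
    as group 5 even if the enhancers are mutually apart.
    """
    a = np.asarray(d_p_e1) < threshold
    b = np.asarray(d_p_e2) < threshold
    c = np.asarray(d_e1_e2) < threshold
    groups = np.ones(len(a), dtype=int)
    groups[a & ~b] = 2
    groups[~a & b] = 3
    groups[~a & ~b & c] = 4
    groups[a & b] = 5
    return groups


def activity_score(d_enh1: np.ndarray, d_enh2: np.ndarray):
    """Transcriptional activity T = 1/d_URR + 1/d_DRR per conformation,
    assuming additive promoter-enhancer action, and the population
    heterogeneity SD(log(T/⟨T⟩)).  Returns ``(T, heterogeneity)``."""
    d1 = np.asarray(d_enh1, dtype=float)
    d2 = np.asarray(d_enh2, dtype=float)
    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise ValueError("distances must be strictly positive")
    t = 1.0 / d1 + 1.0 / d2
    het = float(np.std(np.log(t / t.mean()), ddof=0))
    return t, het


def mean_squared_displacement(positions: np.ndarray, times: np.ndarray):
    """Bead-averaged MSD(Δt) over all start times from trajectory
    snapshots (uniform cadence required).  Returns ``(lags, msd)``."""
    positions = np.asarray(positions, dtype=float)
    times = np.asarray(times, dtype=float)
    n_snap = positions.shape[0]
    if n_snap < 2:
        raise ValueError("need at least two snapshots")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0]):
        raise ValueError("snapshots must be evenly spaced")
    lags = np.arange(1, n_snap)
    msd = np.empty(len(lags))
    for k, lag in enumerate(lags):
        disp = positions[lag:] - positions[:-lag]
        msd[k] = np.mean(np.sum(disp**2, axis=2))
    return lags * dt[0], msd


# ---------------------------------------------------------------------------
# persistence length of the crumpled fiber
# ---------------------------------------------------------------------------

def smooth_contour(snapshot: np.ndarray, window: int = 5) -> np.ndarray:
    """Sliding average of ``window`` consecutive beads: turns the crumpled
    zig-zag chain into a smooth contour with measurable length."""
    x = np.asarray(snapshot, dtype=float)
    if x.shape[0] < window:
        raise ValueError("chain shorter than the smoothing window")
    kernel = np.ones(window) / window
    out = np.empty((x.shape[0] - window + 1, 3))
    for k in range(3):
        out[:, k] = np.convolve(x[:, k], kernel, mode="valid")
    return out


def wlc_rg2(L, lp):
    """Benoit–Doty worm-like-chain radius of gyration:
    Rg²(L) = L·lp/3 − lp² + 2lp³/L − (2lp⁴/L²)(1 − e^(−L/lp))."""
    L = np.asarray(L, dtype=float)
    return (L * lp / 3.0 - lp**2 + 2.0 * lp**3 / L
            - (2.0 * lp**4 / L**2) * (1.0 - np.exp(-L / lp)))


def persistence_length(snapshots: np.ndarray, window: int = 5,
                       max_subchain: int | None = None,
                       min_subchain: int = 10, n_lengths: int = 24,
                       lp0: float = 4.0):
    """Worm-like-chain persistence length of a uniform fiber, in σ.

    For each snapshot the contour is smoothed (``window``-bead sliding
    average); subchains of w smoothed points are extracted at all start
    positions, their contour length L and radius of gyration recorded, and
    the ensemble-averaged Rg²(L) curve fitted with the Benoit–Doty WLC
    expression.  Returns ``(lp, (L_values, rg2_values))``.
    """
    snapshots = np.asarray(snapshots, dtype=float)
    if snapshots.ndim == 2:
        snapshots = snapshots[None]
    n_beads = snapshots.shape[1]
    n_pts = n_beads - window + 1
    if max_subchain is None:
        max_subchain = n_pts // 2
    if max_subchain <= min_subchain + 2:
        raise ValueError("chain too short for a stable WLC fit")
    sizes = np.unique(np.linspace(min_subchain, max_subchain, n_lengths).astype(int))
    L_out, rg2_out = [], []
    for w in sizes:
        Ls, rgs = [], []
        for snap in snapshots:
            c = smooth_contour(snap, window)
            seg = np.linalg.norm(np.diff(c, axis=0), axis=1)
            # subchains at all start positions (strided)
            for s in range(0, n_pts - w, max(1, w // 4)):
                sub = c[s:s + w]
                Ls.append(seg[s:s + w - 1].sum())
                cen = sub - sub.mean(axis=0)
                rgs.append(np.mean(np.sum(cen**2, axis=1)))
        L_out.append(np.mean(Ls))
        rg2_out.append(np.mean(rgs))
    L_out = np.asarray(L_out)
    rg2_out = np.asarray(rg2_out)
    popt, _ = curve_fit(wlc_rg2, L_out, rg2_out, p0=[lp0],
                        bounds=(1e-3, 1e3), maxfev=10000)
    return float(popt[0]), (L_out, rg2_out)
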