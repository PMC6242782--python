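"""Compile epigenomic peak tracks into a bead-level locus model.

A genomic locus is discretised into beads of a fixed resolution (1 kbp by
default; 400 bp and 3 kbp are also supported).  Each bead is annotated as

* ``binding`` — a binding site for the diffusing bridging proteins (TFs),
  inferred either from H3K27ac peaks (any-overlap rule) or from
  accessibility peaks (the bead containing each peak centre);
* ``open_fiber`` — H3K27ac-marked, i.e. a de-compacted fiber region that
  receives no extra next-nearest-neighbour compaction springs;
* a loop-extrusion ``anchor`` — a CTCF/cohesin co-occupied site with a motif
  orientation (forward / reverse / both) and an occupancy probability
  derived from the relative ChIP peak height.

Coordinates are 0-based half-open throughout; bead ``i`` covers
``[start + i*r, start + (i+1)*r)`` for resolution ``r``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "GenomicInterval",
    "AnchorSite",
    "LocusModel",
    "annotate_beads",
    "orient_ctcf_sites",
    "realize_anchors",
    "scan_pwm",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an optional peak height."""

    chrom: str
    start: int
    end: int
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval [{self.start}, {self.end})")
        if self.score < 0:
            raise ValueError("peak score must be non-negative")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AnchorSite:
    """A loop-extrusion anchor bead.

    ``orientation`` is the strand of the best CTCF motif match under the
    peak: ``forward``, ``reverse``, or ``both`` when forward and reverse
    scores are within 2% of each other.  ``occupancy`` is the probability
    that the anchor is present in a given simulated cell, taken linear in
    the ChIP peak height relative to the tallest peak.
    """

    bead_index: int
    orientation: str
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse", "both"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass
class LocusModel:
    """Engine-ready per-bead annotation of a genomic region."""

    region: GenomicInterval
    resolution: int
    n_beads: int
    binding: np.ndarray          # bool per bead: TF binding site
    open_fiber: np.ndarray       # bool per bead: H3K27ac / de-compacted
    anchors: list[AnchorSite] = field(default_factory=list)
    viewpoints: list[int] = field(default_factory=list)
    probes: list[tuple[int, int]] = field(default_factory=list)  # half-open bead ranges

    def __post_init__(self) -> None:
        self.binding = np.asarray(self.binding, dtype=bool)
        self.open_fiber = np.asarray(self.open_fiber, dtype=bool)
        expected = math.ceil(len(self.region) / self.resolution)
        if self.n_beads != expected:
            raise ValueError(f"n_beads {self.n_beads} != ceil(region/resolution) {expected}")
        if self.binding.shape != (self.n_beads,) or self.open_fiber.shape != (self.n_beads,):
            raise ValueError("per-bead arrays must have length n_beads")
        for a in self.anchors:
            if not 0 <= a.bead_index < self.n_beads:
                raise ValueError(f"anchor bead {a.bead_index} outside [0, {self.n_beads})")

    # -- coordinate helpers -------------------------------------------------
    def bead_of(self, pos_bp: int) -> int:
        """Bead index containing genomic position ``pos_bp``."""
        if not self.region.start <= pos_bp < self.region.end:
            raise ValueError(f"position {pos_bp} outside region")
        return (pos_bp - self.region.start) // self.resolution

    def bead_interval(self, i: int) -> tuple[int, int]:
        """Genomic [start, end) of bead ``i`` (clipped to the region)."""
        s = self.region.start + i * self.resolution
        return s, min(s + self.resolution, self.region.end)

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "region": asdict(self.region),
            "resolution": self.resolution,
            "n_beads": self.n_beads,
            "binding": np.flatnonzero(self.binding).tolist(),
            "open_fiber": np.flatnonzero(self.open_fiber).tolist(),
            "anchors": [asdict(a) for a in self.anchors],
            "viewpoints": list(self.viewpoints),
            "probes": [list(p) for p in self.probes],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LocusModel":
        n = d["n_beads"]
        binding = np.zeros(n, dtype=bool)
        binding[d["binding"]] = True
        open_fiber = np.zeros(n, dtype=bool)
        open_fiber[d["open_fiber"]] = True
        return cls(
            region=GenomicInterval(**d["region"]),
            resolution=d["resolution"],
            n_beads=n,
            binding=binding,
            open_fiber=open_fiber,
            anchors=[AnchorSite(**a) for a in d["anchors"]],
            viewpoints=list(d.get("viewpoints", [])),
            probes=[tuple(p) for p in d.get("probes", [])],
        )


def _overlap_beads(region: GenomicInterval, resolution: int, peak: GenomicInterval) -> range:
    """Bead indices whose intervals intersect ``peak`` by >= 1 bp."""
    lo = max(peak.start, region.start)
    hi = min(peak.end, region.end)
    if lo >= hi:
        return range(0)
    first = (lo - region.start) // resolution
    last = (hi - 1 - region.start) // resolution
    return range(first, last + 1)


def annotate_beads(
    region: GenomicInterval,
    resolution: int,
    h3k27ac_peaks: list[GenomicInterval],
    atac_peaks: list[GenomicInterval] | None = None,
    mode: str = "accessibility",
) -> LocusModel:
    """Colour beads as TF-binding / open-fiber from peak tracks.

    ``mode="acetylation"`` marks any bead overlapping an H3K27ac peak as TF
    binding; ``mode="accessibility"`` marks only the bead containing the
    centre of each accessibility (ATAC/DNase) peak.  In both modes beads
    overlapping H3K27ac are flagged ``open_fiber`` (de-compacted).
    """
    if mode not in ("acetylation", "accessibility"):
        raise ValueError(f"unknown mode {mode!r}")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if resolution > len(region):
        raise ValueError("resolution larger than the region")
    n_beads = math.ceil(len(region) / resolution)

    open_fiber = np.zeros(n_beads, dtype=bool)
    for pk in h3k27ac_peaks:
        if pk.chrom != region.chrom:
            raise ValueError(f"peak on {pk.chrom} but region on {region.chrom}")
        idx = _overlap_beads(region, resolution, pk)
        open_fiber[idx.start: idx.stop] = True

    binding = np.zeros(n_beads, dtype=bool)
    if mode == "acetylation":
        binding[:] = open_fiber
    else:
        for pk in atac_peaks or []:
            if pk.chrom != region.chrom:
                raise ValueError(f"peak on {pk.chrom} but region on {region.chrom}")
            center = (pk.start + pk.end) // 2
            if region.start <= center < region.end:
                binding[(center - region.start) // resolution] = True

    return LocusModel(
        region=region,
        resolution=resolution,
        n_beads=n_beads,
        binding=binding,
        open_fiber=open_fiber,
    )


# ---------------------------------------------------------------------------
# CTCF motif orientation
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq.upper()))


def scan_pwm(seq: str, pwm: np.ndarray) -> float:
    """Best log-odds score of ``pwm`` (4 x width, rows A,C,G,T) along ``seq``.

    Positions containing non-ACGT characters are skipped.  Returns -inf when
    no admissible position exists.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape[0] != 4:
        raise ValueError("PWM must have 4 rows (A, C, G, T)")
    w = pwm.shape[1]
    seq = seq.upper()
    n = len(seq)
    if n < w:
        return float("-inf")
    codes = np.fromiter((_BASE_INDEX.get(b, -1) for b in seq), dtype=np.int64, count=n)
    best = float("-inf")
    for i in range(n - w + 1):
        win = codes[i: i + w]
        if (win < 0).any():
            continue
        score = float(pwm[win, np.arange(w)].sum())
        if score > best:
            best = score
    return best


def orient_ctcf_sites(
    ctcf_peaks: list[GenomicInterval],
    sequence: str,
    pwm: np.ndarray,
    model: LocusModel,
    window: int = 3000,
    tie_fraction: float = 0.02,
    occupancy_floor: float = 0.0,
) -> list[AnchorSite]:
    """Assign an orientation and occupancy to each CTCF/cohesin peak.

    For every peak a ``window`` (default 3 kbp) around the peak centre is
    scanned with the motif PWM on both strands; the better-matching strand
    sets the orientation unless its log-odds score is less than
    ``tie_fraction`` (relative, default 2%) better than the other strand,
    in which case the site is called ``both``.  Occupancy is the peak height
    divided by the maximum height in the set, optionally floored.

    ``sequence`` is the sequence of ``model.region`` (same coordinates).
    """
    if not ctcf_peaks:
        return []
    max_score = max(pk.score for pk in ctcf_peaks)
    if max_score <= 0:
        raise ValueError("all CTCF peak heights are zero; cannot form occupancies")
    anchors: list[AnchorSite] = []
    region = model.region
    for pk in ctcf_peaks:
        center = (pk.start + pk.end) // 2
        if not region.start <= center < region.end:
            warnings.warn(f"CTCF peak centred at {center} outside the locus; dropped")
            continue
        lo = max(center - window // 2 - region.start, 0)
        hi = min(center + window // 2 - region.start, len(region))
        subseq = sequence[lo:hi]
        fwd = scan_pwm(subseq, pwm)
        rev = scan_pwm(reverse_complement(subseq), pwm)
        if not (np.isfinite(fwd) or np.isfinite(rev)):
            warnings.warn(f"no admissible motif position under peak at {center}; dropped")
            continue
        hi_s, lo_s = max(fwd, rev), min(fwd, rev)
        if np.isfinite(lo_s) and abs(hi_s - lo_s) < tie_fraction * abs(hi_s):
            orientation = "both"
        elif fwd >= rev:
            orientation = "forward"
        else:
            orientation = "reverse"
        occ = max(pk.score / max_score, occupancy_floor)
        anchors.append(AnchorSite(model.bead_of(center), orientation, occ))
    return anchors


def realize_anchors(model: LocusModel, rng: np.random.Generator) -> list[AnchorSite]:
    """Draw the anchor set present in one simulated cell.

    Each anchor is retained independently with probability equal to its
    occupancy, modelling cell-to-cell variation of CTCF binding.
    """
    return [a for a in model.anchors if rng.random() < a.occupancy]
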