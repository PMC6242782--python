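"""Synthetic loci and pseudo-experimental data.

``generate_synthetic_locus`` builds a locus in the style of a gene flanked
by upstream and downstream regulatory regions (URR/DRR): acetylated (open)
blocks, TF-binding sites, oriented CTCF anchor sites with peak heights, and
probe/viewpoint positions — emitting both BED-style track tables and the
compiled :class:`~hiphop.annotation.LocusModel`, deterministically per spec.

``generate_pseudo_experiment`` converts a reference trajectory into
experimental-format Capture-C profiles (multiplicative noise) and FISH
separation samples at a chosen physical length unit, enabling end-to-end
Q/K scoring without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnchorSite, GenomicInterval, LocusModel, annotate_beads
from .assays import bin_profile, expected_capture_c, simulated_fish
from .engine import Trajectory

__all__ = ["SyntheticLocusSpec", "generate_synthetic_locus",
           "generate_pseudo_experiment", "random_walk_ensemble"]


@dataclass
class SyntheticLocusSpec:
    """Declarative description of a synthetic locus.

    Positions are bp offsets from the region start; anchor sites carry
    (position, orientation, height).  Defaults sketch a 300-kbp locus with
    a central gene and two flanking regulatory clusters, the layout the
    engine is exercised on in tests.
    """

    chrom: str = "chrSyn"
    length: int = 300_000
    resolution: int = 1000
    acetylated_blocks: list[tuple[int, int]] = field(
        default_factory=lambda: [(40_000, 70_000), (140_000, 165_000),
                                 (230_000, 260_000)])
    binding_sites: list[int] = field(
        default_factory=lambda: [50_000, 55_000, 62_000, 148_000, 152_000,
                                 160_000, 238_000, 245_000, 252_000])
    anchor_sites: list[tuple[int, str, float]] = field(
        default_factory=lambda: [(30_000, "forward", 10.0),
                                 (120_000, "forward", 8.0),
                                 (180_000, "reverse", 8.0),
                                 (270_000, "reverse", 10.0)])
    promoter_bp: int = 150_000
    enhancer1_bp: int = 55_000     # URR-like upstream cluster
    enhancer2_bp: int = 245_000    # DRR-like downstream cluster
    probe_halfwidth: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        for s, e in self.acetylated_blocks:
            if not 0 <= s < e <= self.length:
                raise ValueError("acetylated block outside the locus")
        for p in self.binding_sites:
            if not 0 <= p < self.length:
                raise ValueError("binding site outside the locus")
        for p, o, h in self.anchor_sites:
            if not 0 <= p < self.length:
                raise ValueError("anchor outside the locus")
            if o not in ("forward", "reverse", "both"):
                raise ValueError(f"bad anchor orientation {o!r}")
            if h <= 0:
                raise ValueError("anchor peak height must be positive")


def generate_synthetic_locus(spec: SyntheticLocusSpec):
    """Compile the spec into BED tracks plus an engine-ready LocusModel.

    Returns ``(model, tracks)`` with ``tracks`` a dict of DataFrame-backed
    BED-style tables (h3k27ac, atac, ctcf).  Re-annotating the emitted
    tracks reproduces the model exactly (round-trip property).
    """
    region = GenomicInterval(spec.chrom, 0, spec.length)
    h3k = [GenomicInterval(spec.chrom, s, e, score=1.0)
           for s, e in spec.acetylated_blocks]
    atac = [GenomicInterval(spec.chrom, max(p - 200, 0),
                            min(p + 200, spec.length), score=1.0)
            for p in spec.binding_sites]
    model = annotate_beads(region, spec.resolution, h3k, atac,
                           mode="accessibility")

    max_h = max((h for _, _, h in spec.anchor_sites), default=1.0)
    strand = {"forward": "+", "reverse": "-", "both": "."}
    ctcf = []
    for p, o, h in spec.anchor_sites:
        ctcf.append(GenomicInterval(spec.chrom, max(p - 500, 0),
                                    min(p + 500, spec.length), score=h,
                                    strand=strand[o]))
        model.anchors.append(AnchorSite(model.bead_of(p), o, h / max_h))

    r = spec.resolution
    model.viewpoints = [model.bead_of(spec.promoter_bp),
                        model.bead_of(spec.enhancer1_bp),
                        model.bead_of(spec.enhancer2_bp)]
    hw = spec.probe_halfwidth
    for center in (spec.enhancer1_bp, spec.promoter_bp, spec.enhancer2_bp):
        lo = model.bead_of(max(center - hw, 0))
        hi = model.bead_of(min(center + hw, spec.length - 1)) + 1
        model.probes.append((lo, hi))

    def frame(ivs):
        return pd.DataFrame(
            [(iv.chrom, iv.start, iv.end, f"peak{k}", iv.score, iv.strand)
             for k, iv in enumerate(ivs)],
            columns=["chrom", "start", "end", "name", "score", "strand"])

    tracks = {"h3k27ac": frame(h3k), "atac": frame(atac), "ctcf": frame(ctcf)}
    return model, tracks


def random_walk_ensemble(n_snapshots: int, n_beads: int, step: float = 1.0,
                         rng: np.random.Generator | None = None,
                         params=None, model: LocusModel | None = None) -> Trajectory:
    """A cheap reference 'trajectory' of independent random-walk
    conformations, for exercising assays and scoring without the engine."""
    from .params import SimParams

    rng = np.random.default_rng() if rng is None else rng
    steps = rng.standard_normal((n_snapshots, n_beads - 1, 3))
    steps *= step / np.linalg.norm(steps, axis=2, keepdims=True)
    pos = np.concatenate([np.zeros((n_snapshots, 1, 3)),
                          np.cumsum(steps, axis=1)], axis=1)
    params = params or SimParams(t_total=float(n_snapshots), t_discard=0.0,
                                 t_snapshot=1.0)
    times = np.arange(1, n_snapshots + 1) * params.t_snapshot
    return Trajectory(times=times, positions=pos, params=params, model=model)


def generate_pseudo_experiment(reference_trajectory: Trajectory,
                               noise: float = 0.0,
                               sigma_nm: float = 25.0,
                               rng: np.random.Generator | None = None,
                               viewpoints: list[int] | None = None,
                               probes: list[tuple[int, int]] | None = None,
                               bin_size: int = 3000, window: int = 6000):
    """Pseudo-experimental Capture-C + FISH data from a reference model.

    Capture-C: expected-value profiles per viewpoint, binned, then
    multiplied by lognormal noise of width ``noise`` per bin.  FISH:
    probe-pair separations scaled to nm by ``sigma_nm`` with multiplicative
    Gaussian jitter of relative width ``noise`` (``noise=0`` returns the
    exactly scaled samples).  Returns ``(profiles, fish)`` where
    ``profiles`` maps viewpoint -> binned value array and ``fish`` maps
    probe-pair -> nm sample array.
    """
    rng = np.random.default_rng() if rng is None else rng
    model = reference_trajectory.model
    if viewpoints is None:
        if model is None or not model.viewpoints:
            raise ValueError("no viewpoints given and none on the model")
        viewpoints = model.viewpoints
    resolution = model.resolution if model is not None else 1000

    expected = expected_capture_c(reference_trajectory, viewpoints)
    profiles = {}
    for v, raw in expected.items():
        prof = bin_profile(raw, resolution, v, bin_size, window)
        vals = prof.counts.copy()
        if noise > 0:
            vals *= rng.lognormal(mean=0.0, sigma=noise, size=len(vals))
        profiles[v] = vals

    fish = {}
    for pair, dist in simulated_fish(reference_trajectory, probes).items():
        samples = dist.samples * sigma_nm
        if noise > 0:
            samples = samples * np.abs(1.0 + noise * rng.standard_normal(len(samples)))
        fish[pair] = samples
    return profiles, fish
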