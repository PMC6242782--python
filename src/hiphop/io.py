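"""File formats: BED peaks, bedGraph profiles, FASTA, JASPAR PWMs,
LocusModel JSON, trajectory HDF5, and CSV score inputs."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .annotation import GenomicInterval, LocusModel
from .engine import Trajectory
from .params import SimParams

__all__ = [
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "read_jaspar_pwm",
    "save_locus_model",
    "load_locus_model",
    "save_trajectory",
    "load_trajectory",
    "read_fish_csv",
]


def read_bed(path) -> list[GenomicInterval]:
    """BED6+ intervals (chrom, start, end, name, score, strand); the score
    column carries the peak height."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        score = float(row[4]) if len(row) > 4 else 0.0
        strand = str(row[5]) if len(row) > 5 else "."
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]),
                                   score=score, strand=strand))
    return out


def write_bed(intervals: list[GenomicInterval], path) -> None:
    rows = [(iv.chrom, iv.start, iv.end, f"peak{k}", iv.score, iv.strand)
            for k, iv in enumerate(intervals)]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"])


def read_fasta(path, name: str | None = None) -> str:
    """First (or named) sequence from a FASTA file, as an uppercase string."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        if name is None or rec.id == name:
            return str(rec.seq).upper()
    raise ValueError(f"sequence {name!r} not found in {path}")


def read_jaspar_pwm(path, pseudocount: float = 0.5,
                    background: float = 0.25) -> np.ndarray:
    """JASPAR-format count matrix -> 4×w log-odds PWM (rows A, C, G, T)."""
    from Bio import motifs

    with open(path) as fh:
        motif = motifs.read(fh, "jaspar")
    counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float)
    counts += pseudocount
    probs = counts / counts.sum(axis=0, keepdims=True)
    return np.log2(probs / background)


def save_locus_model(model: LocusModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def load_locus_model(path) -> LocusModel:
    return LocusModel.from_dict(json.loads(Path(path).read_text()))


def save_trajectory(traj: Trajectory, path) -> None:
    """Trajectory to HDF5: positions (float64, σ units), times, and a JSON
    metadata block with parameters, seed, box, and the locus model."""
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("positions", data=traj.positions)
        meta = {
            "params": traj.params.to_dict(),
            "seed": traj.seed,
            "box": traj.box,
            "model": traj.model.to_dict() if traj.model is not None else None,
        }
        f.attrs["metadata"] = json.dumps(meta)


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        times = f["times"][:]
        positions = f["positions"][:]
        meta = json.loads(f.attrs["metadata"])
    model = (LocusModel.from_dict(meta["model"])
             if meta.get("model") is not None else None)
    return Trajectory(times=times, positions=positions,
                      params=SimParams.from_dict(meta["params"]),
                      model=model, seed=meta.get("seed"), box=meta.get("box"))


def read_fish_csv(path) -> dict[str, np.ndarray]:
    """Experimental FISH samples: CSV with one column per probe pair, in nm."""
    df = pd.read_csv(path)
    return {col: df[col].dropna().to_numpy(dtype=float) for col in df.columns}
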