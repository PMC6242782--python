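import numpy as np
import pytest

from hiphop import SimParams, SyntheticLocusSpec, generate_synthetic_locus
from hiphop.annotation import GenomicInterval, LocusModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_locus():
    """A 60-kbp synthetic locus: gene + two flanking regulatory clusters."""
    spec = SyntheticLocusSpec(
        length=60_000,
        acetylated_blocks=[(8_000, 14_000), (28_000, 33_000), (46_000, 52_000)],
        binding_sites=[10_000, 12_000, 29_500, 31_000, 48_000, 50_000],
        anchor_sites=[(5_000, "forward", 10.0), (55_000, "reverse", 8.0)],
        promoter_bp=30_000, enhancer1_bp=11_000, enhancer2_bp=49_000,
        probe_halfwidth=2_000,
    )
    model, tracks = generate_synthetic_locus(spec)
    return spec, model, tracks


@pytest.fixture(scope="session")
def uniform_compact_model():
    """A fully compacted (no H3K27ac) 100-bead chain."""
    n = 100
    return LocusModel(GenomicInterval("chrU", 0, n * 1000), 1000, n,
                      np.zeros(n, bool), np.zeros(n, bool))


@pytest.fixture
def fast_params():
    """Short-schedule parameters for engine tests."""
    return SimParams(n_tf=40, box=40.0, t_total=400.0, t_discard=100.0,
                     t_snapshot=50.0, t_equil=100.0, t_kinetic=10.0)
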