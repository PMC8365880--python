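import numpy as np
import pytest

from enhancerscape.genome_io import GenomicInterval, PeakSet, SignalTrack
from enhancerscape.synthetic import (
    SimulationConfig,
    simulate_chip_tracks,
    simulate_expression,
    simulate_genome,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def sim_bundle(default_config):
    """One full simulated study shared across read-only tests."""
    annotation, truth = simulate_genome(default_config)
    tracks = simulate_chip_tracks(truth, default_config)
    counts = simulate_expression(truth, default_config)
    return dict(config=default_config, annotation=annotation, truth=truth,
                tracks=tracks, counts=counts)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=1_000_000,
                     max_len=5_000):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        out.append(GenomicInterval(
            str(rng.choice(chroms)), start,
            start + int(rng.integers(1, max_len))))
    return out


def random_track(rng, chroms=("chr1",), n_runs=50, max_pos=100_000):
    runs = {}
    for chrom in chroms:
        edges = np.sort(rng.choice(max_pos, size=2 * n_runs, replace=False))
        starts, ends = edges[::2], edges[1::2]
        values = rng.random(n_runs) * 5
        runs[chrom] = (starts, ends, values)
    return SignalTrack(runs, library_size=float(rng.integers(1e5, 1e6)))


def reciprocal_match(called, truth_interval, min_frac=0.5):
    """Find the called enhancer reciprocally overlapping a truth span."""
    for e in called:
        iv = e.interval
        if iv.chrom == truth_interval.chrom:
            ov = min(iv.end, truth_interval.end) - max(iv.start,
                                                       truth_interval.start)
            if (ov >= min_frac * truth_interval.length
                    and ov >= min_frac * iv.length):
                return e
    return None
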