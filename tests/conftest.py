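import numpy as np
import pytest

from allelichrom.intervals import GenomicInterval
from allelichrom.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One shared synthetic cohort at the default study conditions."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_dir(default_cohort, tmp_path_factory):
    """The default cohort materialized as a file bundle."""
    d = tmp_path_factory.mktemp("cohort")
    default_cohort.write(d)
    return d


def random_intervals(rng: np.random.Generator, n: int, chroms=("chrA", "chrB"),
                     genome_length: int = 10_000, max_len: int = 400):
    """Random intervals on a toy genome, for oracle comparisons."""
    out = []
    for _ in range(n):
        chrom = str(rng.choice(chroms))
        start = int(rng.integers(0, genome_length - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def coverage_vector(intervals, chrom: str, genome_length: int = 10_000) -> np.ndarray:
    """Per-base boolean occupancy oracle for one toy chromosome."""
    vec = np.zeros(genome_length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            vec[iv.start : iv.end] = True
    return vec


def vector_to_intervals(vec: np.ndarray, chrom: str):
    """Maximal runs of True in a boolean vector, as intervals."""
    out = []
    padded = np.concatenate([[False], vec, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.where(diff == 1)[0]
    ends = np.where(diff == -1)[0]
    for s, e in zip(starts, ends):
        out.append(GenomicInterval(chrom, int(s), int(e)))
    return out
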