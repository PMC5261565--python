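import numpy as np
import pytest

from carscan.intervals import GenomicInterval, IntervalSet


def brute_force_overlap_count(peaks, instances) -> int:
    """All-pairs O(n*m) oracle for peak/instance overlap counting."""
    n = 0
    for p in peaks:
        if any(p.overlaps(i) for i in instances):
            n += 1
    return n


def random_interval_set(rng, n, chroms=("chr1", "chr2"), genome=10_000,
                        min_len=5, max_len=300) -> IntervalSet:
    out = []
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, genome - length))
        out.append(GenomicInterval(c, start, start + length,
                                   score=float(rng.uniform(0, 100))))
    return IntervalSet(out)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated cohort with planted CAR effects, shared across tests."""
    from carscan.simulate import simulate_matrices

    return simulate_matrices(
        n_cells=60, n_genes=80, n_tf_genes=24, n_motifs=6,
        car_fraction=0.34, effect_size=0.9, seed=11,
    )
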