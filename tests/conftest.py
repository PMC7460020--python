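import numpy as np
import pytest

from rohscan.genotype_io import GenotypeMatrix, GroupAssignment, MarkerMap


def make_map(positions_by_chrom: dict) -> MarkerMap:
    """Build a sorted MarkerMap from {chrom: [pos, ...]}."""
    ids, chroms, pos = [], [], []
    for c, ps in positions_by_chrom.items():
        for p in ps:
            ids.append(f"m_{c}_{p}")
            chroms.append(str(c))
            pos.append(p)
    return MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                     np.array(pos, dtype=np.int64))


def make_gm(calls, sample_ids=None) -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(calls.shape[0])]
    return GenotypeMatrix(list(sample_ids), calls)


def random_instance(rng, n_samples, n_markers, n_chrom=2, het_rate=0.2,
                    missing_rate=0.05, max_pos_step=40_000):
    """Random small genotype instance for oracle-equivalence testing."""
    per = n_markers // n_chrom
    positions = {
        str(c + 1): np.cumsum(rng.integers(1_000, max_pos_step, size=per)).tolist()
        for c in range(n_chrom)
    }
    mmap = make_map(positions)
    u = rng.random((n_samples, len(mmap)))
    calls = np.where(u < het_rate, 1, np.where(rng.random((n_samples, len(mmap))) < 0.5, 0, 2))
    miss = rng.random((n_samples, len(mmap))) < missing_rate
    calls[miss] = -1
    return make_gm(calls), mmap


@pytest.fixture
def rng():
    return np.random.default_rng(20240731)
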