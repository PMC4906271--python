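import numpy as np
import pytest

from cistarget_compare import GeneModel, GenomicInterval, Peak, SyntheticConfig, generate


def random_genes(rng, n, scaffold="chr1", span=100_000, max_len=2000):
    """Non-overlapping random gene models on one scaffold."""
    starts = np.sort(rng.choice(span, size=n, replace=False))
    genes = []
    for i, s in enumerate(starts):
        limit = starts[i + 1] - s if i + 1 < n else span - s
        if limit < 2:
            continue
        length = int(rng.integers(1, min(max_len, limit)))
        genes.append(GeneModel(f"g{i:03d}", GenomicInterval(scaffold, int(s), int(s) + length)))
    return genes


def random_peaks(rng, n, scaffold="chr1", span=100_000, max_len=1000):
    peaks = []
    for _ in range(n):
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(50, max_len))
        peaks.append(Peak(GenomicInterval(scaffold, start, start + length)))
    return peaks


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset reused across read-only tests."""
    config = SyntheticConfig(
        seed=42,
        n_scaffolds=2,
        scaffold_length_bp=250_000,
        n_genes=60,
        n_peaks=30,
        shared_target_fraction=0.3,
        de_fraction_2fold=0.1,
    )
    return generate(config)
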