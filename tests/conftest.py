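import numpy as np
import pandas as pd
import pytest

import chromdyn as cd


@pytest.fixture(scope="session")
def small_config():
    return cd.SimulationConfig(n_peaks_per_class=5, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return cd.build_truth(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_truth):
    return cd.simulate_count_matrix(small_truth)


@pytest.fixture(scope="session")
def study_truth():
    """Study-scale planted truth: 100 peaks per label, planted |log2FC| = 2,
    3 replicates, baseline mean 200, NB dispersion 0.05."""
    cfg = cd.SimulationConfig(n_peaks_per_class=100, n_chroms=8,
                              chrom_length=200_000, seed=1)
    return cd.build_truth(cfg)


@pytest.fixture(scope="session")
def study_contrasts(study_truth):
    matrix = cd.simulate_count_matrix(study_truth)
    return cd.run_four_contrasts(matrix)


def random_intervals(rng, n, chrom_pool=("chr1", "chr2"), max_pos=5000, max_len=300):
    starts = rng.integers(0, max_pos, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return pd.DataFrame({
        "chrom": rng.choice(chrom_pool, size=n),
        "start": starts,
        "end": starts + lengths,
    })


def brute_force_overlap_counts(query, subject, min_bp=1):
    out = np.zeros(len(query), dtype=int)
    for i, q in enumerate(query.itertuples(index=False)):
        for s in subject.itertuples(index=False):
            if q.chrom == s.chrom:
                ov = min(q.end, s.end) - max(q.start, s.start)
                if ov >= min_bp:
                    out[i] += 1
    return out
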