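import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pathrider import genio


def make_groups(sizes: list[int]) -> genio.PathwayGroups:
    """Non-overlapping contiguous groups over sum(sizes) columns."""
    index_lists = []
    start = 0
    for s in sizes:
        index_lists.append(np.arange(start, start + s))
        start += s
    return genio.PathwayGroups(
        group_ids=[f"g{i}" for i in range(len(sizes))],
        group_index_lists=index_lists,
        expansion_map=np.arange(start),
        n_original=start,
    )


def standardized(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genotypes():
    """6 subjects x 5 SNPs with one missing call."""
    dosage = np.array(
        [
            [0, 1, 2, 0, 1],
            [1, 0, 2, 0, 1],
            [0, 1, 1, 0, 2],
            [2, 0, 0, 0, 1],
            [1, 1, 1, 0, 0],
            [0, 2, 2, 0, 1],
        ],
        dtype=float,
    )
    mask = np.zeros_like(dosage, dtype=bool)
    mask[2, 4] = True
    dosage[2, 4] = 0.0
    return genio.GenotypeMatrix(
        subject_ids=[f"s{i}" for i in range(6)],
        snp_ids=[f"rs{j}" for j in range(5)],
        dosage=dosage,
        missing_mask=mask,
    )
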