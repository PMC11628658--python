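import numpy as np
import pytest

from fusesweep.blocks import BlockSet, Intervals
from fusesweep.coalescent import N_CONFIGS
from fusesweep.sweep import get_neutral_lengths, get_phi_table


@pytest.fixture(scope="session")
def phi_small():
    """Shared small Phi table (T_a = 0.25)."""
    return get_phi_table(0.25, M=8_000, seed=0)


@pytest.fixture(scope="session")
def neutral_lengths_small():
    return get_neutral_lengths(M=20_000, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_blockset(config_idx, distance=None, l=113, test_point=0.0):
    """Minimal BlockSet around explicit configuration indices."""
    config_idx = np.asarray(config_idx, dtype=np.int64)
    n = len(config_idx)
    if distance is None:
        distance = np.abs(np.arange(n, dtype=float) * l + l / 2)
    distance = np.asarray(distance, dtype=float)
    mid = test_point + distance
    return BlockSet(
        chrom="chrT",
        test_point=test_point,
        block_length_l=l,
        subset_id=np.zeros(n, dtype=np.int64),
        start=(mid - l / 2).astype(np.int64),
        end=(mid + l / 2).astype(np.int64),
        midpoint=mid,
        distance=distance,
        config_idx=config_idx,
    )


def sample_configs_from_probs(probs, n, rng):
    """Draw configuration indices from a 64-vector of probabilities."""
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    return rng.choice(N_CONFIGS, size=n, p=probs)


def full_mask(chrom, length):
    return Intervals.from_records([(chrom, 0, length)])
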