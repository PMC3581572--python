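import numpy as np
import pytest

from orthosim import ScenarioConfig, simulate_dataset, surrogate_tree, wag_model
from orthosim.phylo import TreeStats


@pytest.fixture(scope="session")
def model():
    return wag_model()


@pytest.fixture(scope="session")
def small_tree():
    """5-species tree, mammalia-like divergence (mean height ~15 PAM)."""
    target = TreeStats(
        n_leaves=5, total_length=40.0, min_height=12.0, max_height=18.0,
        mean_height=15.0, mean_pairwise_distance=14.0,
    )
    tree, _ = surrogate_tree(5, target, np.random.default_rng(101), match="mean_height")
    return tree


@pytest.fixture(scope="session")
def zero_rate_dataset(small_tree):
    """No duplication/loss/LGT: gene trees congruent with the species tree."""
    cfg = ScenarioConfig(n_root_families=40, seed=7)
    return simulate_dataset(small_tree, cfg, rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def dup_dataset(small_tree):
    """Moderate duplication/loss for tests needing paralogs."""
    cfg = ScenarioConfig(
        n_root_families=40, dup_rate=0.008, loss_rate=0.008, seed=11
    )
    return simulate_dataset(small_tree, cfg, rng=np.random.default_rng(11))
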