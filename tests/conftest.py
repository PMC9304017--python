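import numpy as np
import pytest

from genphy.priors import PriorConfig, sample_tree_from_prior


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def prior_config():
    return PriorConfig()


def random_trees(n_tips, count, seed=5, model="MG", mix_generations=60):
    """Valid generalized trees drawn from the prior (short mixing is fine
    for fixtures; distributional correctness is tested separately)."""
    rng = np.random.default_rng(seed)
    cfg = PriorConfig()
    labels = [f"sp{i + 1}" for i in range(n_tips)]
    return [
        sample_tree_from_prior(labels, cfg, rng, model=model,
                               mix_generations=mix_generations)
        for _ in range(count)
    ]
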