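import numpy as np
import pytest

import fitscape as fs


@pytest.fixture(scope="session")
def rugged_spec():
    """Small, strongly epistatic landscape spec used across modules."""
    return fs.SyntheticSpec(
        alphabet_size=8,
        seed=5,
        additive_sd=1.2,
        pairwise_density=0.25,
        pairwise_sd=1.5,
        threeway_density=0.3,
        threeway_sd=1.0,
        lethal_fraction=0.1,
        missing_fraction=0.0,
    )


@pytest.fixture(scope="session")
def rugged_landscape(rugged_spec):
    ls, truth = fs.generate_landscape(rugged_spec)
    return ls, truth


@pytest.fixture(scope="session")
def smooth_landscape():
    """Purely multiplicative (additive-on-log) landscape, no noise."""
    spec = fs.SyntheticSpec(
        alphabet_size=5,
        seed=11,
        pairwise_density=0.0,
        threeway_density=0.0,
        noise_sd=0.0,
        lethal_fraction=0.0,
        missing_fraction=0.0,
    )
    ls, truth = fs.generate_landscape(spec)
    return ls, truth


def random_subgraph(seed, d=4):
    """A complete diallelic subgraph with i.i.d. lognormal fitness."""
    rng = np.random.default_rng(seed)
    fitness = np.exp(rng.normal(0, 1, size=2 ** d))
    src = "A" * d
    dst = "C" * d
    return fs.DiallelicSubgraph(src, dst, tuple(range(d)), fitness)
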