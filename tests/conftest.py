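import numpy as np
import pytest

from icgh import GenomeSpec, generate_reference, make_demo

#: pinned benchmark seed used by the truth-recovery suite
DEMO_SEED = 1


@pytest.fixture(scope="session")
def demo_err():
    """Full-scale benchmark: 200 genes, depth 20, 1% substitution error."""
    return make_demo(seed=DEMO_SEED, n_genes=200, depth=20.0, sub_error_rate=0.01)


@pytest.fixture(scope="session")
def demo_clean():
    """Same benchmark with error-free reads (exact cluster recovery)."""
    return make_demo(seed=DEMO_SEED, n_genes=200, depth=20.0, sub_error_rate=0.0)


@pytest.fixture(scope="session")
def small_genome():
    return generate_reference(GenomeSpec(n_genes=40, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
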