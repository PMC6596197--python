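import numpy as np
import pytest

from seqobs import design, synth


@pytest.fixture(scope="session")
def pool():
    return design.sample_sequence_pool(123)


@pytest.fixture(scope="session")
def alloc(pool):
    return design.allocate_conditions(pool, 7)


@pytest.fixture(scope="session")
def scanning_schedule(alloc):
    return design.build_scanning_session(alloc, 11)


@pytest.fixture(scope="session")
def small_truth():
    """Ground truth on 40 voxels with correlated noise."""
    params = synth.PatternParams(n_voxels=40, noise_length_scale_mm=5.0)
    return synth.simulate_patterns(params, 99)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
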