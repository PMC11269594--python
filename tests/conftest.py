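import numpy as np
import pytest

from musclemorph import benchmark as bench
from musclemorph import synthetic as synth


@pytest.fixture(scope="session")
def myotube_bench():
    """Per-tube Dice/diameter table over the 20-field synthetic suite."""
    return bench.run_myotube_benchmark(n_fields=20, seed=0)


@pytest.fixture(scope="session")
def fiber_bench():
    """Per-fiber attribution/CSA table over four gap-free mosaics."""
    return bench.run_fiber_benchmark(n_mosaics=4, seed=0)


@pytest.fixture(scope="session")
def small_field():
    """One synthetic myotube field plus its ideal probability map and truth."""
    return synth.gen_myotube_field(seed=11)


@pytest.fixture(scope="session")
def small_mosaic():
    """A compact fiber mosaic (512 px, 26 fibers) for fast histo tests."""
    return synth.gen_fiber_mosaic(n_fibers=26, shape=(512, 512), seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
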