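import numpy as np
import pytest

from aslnet.net import NetConfig
from aslnet.phantom import CovariateModel, PhantomSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom family: 48^3 grid, tumours 6-9 mm."""
    return PhantomSpec(grid_shape=(48, 48, 48), tumor_radius_mm=(6.0, 9.0))


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec, 18, (1 / 3, 1 / 3, 1 / 3),
                           CovariateModel(), seed=11)


@pytest.fixture(scope="session")
def tiny_cfg():
    """A minimal trunk that keeps gradient/axiom tests fast."""
    return NetConfig(input_side=12, init_filters=4, blocks_per_stage=(1, 1, 1, 1),
                     norm_groups=2, n_classes=3, dropout_rate=0.0, stem_kernel=3)
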