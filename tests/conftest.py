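import numpy as np
import pytest

from plscvbm import CohortSpec, PlantedComponent, default_u_true, generate_cohort, prepare_blocks


@pytest.fixture(scope="session")
def small_cohort():
    """Modest cohort with a clearly planted component, shared across tests."""
    spec = CohortSpec(
        n_subjects=150,
        grid_shape=(12, 12, 8),
        planted_components=(PlantedComponent(default_u_true(), rho=0.6),),
        seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_blocks(small_cohort):
    c = small_cohort
    xblock, yblock, report, raw_y = prepare_blocks(
        c.table, c.gmv, c.mask_probability, c.affine
    )
    return xblock, yblock, report, raw_y


@pytest.fixture(scope="session")
def random_blocks():
    """Plain random standardized block pair (no structure)."""
    rng = np.random.default_rng(7)
    x = rng.standard_normal((60, 5))
    y = rng.standard_normal((60, 40))
    x = (x - x.mean(0)) / x.std(0, ddof=1)
    y = (y - y.mean(0)) / y.std(0, ddof=1)
    return x, y
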