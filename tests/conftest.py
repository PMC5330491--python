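import numpy as np
import pytest

from gliovol.phantoms import PhantomSpec, simulate_cohort_table


@pytest.fixture(scope="session")
def default_cohort():
    """One default 30-patient cohort, shared across tests (read-only)."""
    spec = PhantomSpec(seed=11)
    table, truth = simulate_cohort_table(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def mini_image_spec():
    """Small-tumor, small-grid spec for image-level tests."""
    return PhantomSpec(
        seed=7,
        n_patients=2,
        grid_shape=(64, 64, 64),
        cv_baseline_median_ml=2.0,
        fv_to_cv_ratio_median=10.0,
        fv_to_cv_ratio_sigma=0.3,
        cv_baseline_sigma=0.4,
        misregistration_sd=1.5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
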