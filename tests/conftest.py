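import warnings

import pytest

from hehrisk.simulate import default_config, generate_cohort


@pytest.fixture(scope="session")
def cohort2000():
    """Default synthetic cohort, n=2000 (shared read-only fixture)."""
    cohort, truth = generate_cohort(default_config(n=2000, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def cohort5000():
    """Default synthetic cohort, n=5000 (shared read-only fixture)."""
    cohort, truth = generate_cohort(default_config(n=5000, seed=7))
    return cohort, truth


@pytest.fixture(autouse=True)
def _quiet_lifelines():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning, module="lifelines")
        yield
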