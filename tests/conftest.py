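import numpy as np
import pytest

from survode import Cohort
from survode.simulate import ScenarioSpec, generate_cohort


@pytest.fixture
def toy4() -> Cohort:
    """Four subjects: cancer death at t=1, censoring at t=2, other-cause
    death at t=3, cancer death at t=4.  All hand values in the tests
    derive from dN/Y on this cohort."""
    return Cohort(time=[1.0, 2.0, 3.0, 4.0], event=[1, 0, 2, 1])


@pytest.fixture
def random_cohorts():
    """Factory for seeded random cohorts with continuous event times
    (so ties have probability zero) and mixed censoring."""

    def make(seed: int, n: int | None = None) -> Cohort:
        rng = np.random.default_rng(seed)
        n = n or int(rng.integers(10, 200))
        spec = ScenarioSpec(
            n=n,
            lambda_cancer=float(rng.uniform(0.1, 0.5)),
            lambda_other=float(rng.uniform(0.05, 0.3)),
            censoring_rate=float(rng.uniform(0.0, 0.3)),
            admin_censor_time=float(rng.uniform(5.0, 15.0)),
            seed=seed,
        )
        return generate_cohort(spec)

    return make
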