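import numpy as np
import pytest

from spectracv.synth import (
    HerdPlan,
    SpectraGenSpec,
    default_breed_specs,
    generate_dataset,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A down-scaled five-breed cohort with a short spectral grid: fast to
    generate, still exercises breeds, herds, replicates and missingness."""
    return generate_dataset(
        default_breed_specs(n_scale=0.15),
        SpectraGenSpec(n_points=120),
        HerdPlan(n_herds=4),
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
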