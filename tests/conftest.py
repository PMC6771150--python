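import numpy as np
import pytest

from arowana.simulate import DatasetShape, PriorConfig, ScenarioParams


@pytest.fixture(scope="session")
def priors() -> PriorConfig:
    return PriorConfig()


@pytest.fixture(scope="session")
def small_shape() -> DatasetShape:
    """13 haploids per deme is overkill for unit tests; keep tiny."""
    return DatasetShape(n_dip_deme1=4, n_dip_deme2=2, n_sites=60)


@pytest.fixture(scope="session")
def panmictic_params() -> ScenarioParams:
    return ScenarioParams(model_id=1, ne=1e5, dt=0.0, g=1.0, theta=5e-4, ct=0.0)


@pytest.fixture(scope="session")
def colonization_params() -> ScenarioParams:
    """Model 3 with a clear founder signal."""
    return ScenarioParams(
        model_id=3, ne=1e5, dt=2e5, g=1.0, theta=5e-4, ct=0.5,
        founder_ratio=0.05, growth_ratio=0.5,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
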