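import numpy as np
import pytest

from pdl1dyn import (
    BaseParams,
    EpsilonParams,
    ExperimentDesign,
    NoiseModel,
    generate_experiment,
)


@pytest.fixture(scope="session")
def base_params() -> BaseParams:
    return BaseParams()


@pytest.fixture(scope="session")
def eps_params() -> EpsilonParams:
    return EpsilonParams()


@pytest.fixture(scope="session")
def noiseless_dynamic_experiment(base_params, eps_params):
    """Six noiseless arms generated under the dynamic-ϵ ground truth."""
    design = ExperimentDesign(base_params=base_params, eps_params=eps_params)
    datasets, manifest = generate_experiment(design, NoiseModel(kind="none", sigma=0.0, seed=0))
    return design, datasets, manifest


@pytest.fixture(scope="session")
def noiseless_constant_experiment(base_params):
    """Six noiseless arms generated under per-arm constant-ϵ ground truth."""
    design = ExperimentDesign(variant="constant", base_params=base_params)
    datasets, manifest = generate_experiment(design, NoiseModel(kind="none", sigma=0.0, seed=0))
    return design, datasets, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
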