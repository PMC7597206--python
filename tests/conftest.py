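import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def montage():
    from hemisym.montage import deap_montage
    return deap_montage()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_lateralized_dataset():
    """A small gamma-lateralized dataset shared by pipeline-level tests.

    HAHV trials couple the left hemisphere tightly, HALV the right;
    the two low-arousal categories are symmetric.
    """
    from hemisym.synthetic import SyntheticConfig, generate_dataset
    config = SyntheticConfig(
        n_subjects=6, n_trials_per_category=2, duration=8.0,
        bands=("gamma",),
        kappa_left={"HAHV": 12.0, "LAHV": 2.0, "LALV": 2.0, "HALV": 0.5},
        kappa_right={"HAHV": 0.5, "LAHV": 2.0, "LALV": 2.0, "HALV": 12.0},
        module_coupling_ratio=0.2, seed=42,
    )
    dataset, truth = generate_dataset(config)
    return config, dataset, truth
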