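import numpy as np
import pytest

from wmring import EnvironmentPrior
from wmring.training import init_params, train_ensemble, train_noise_sweep

try:
    from hypothesis import settings
    settings.register_profile("suite", deadline=None, derandomize=True,
                              max_examples=25)
    settings.load_profile("suite")
except ImportError:
    pass


@pytest.fixture(scope="session")
def small_net():
    """An untrained but structurally valid 32-unit network."""
    return init_params(32, rng=3)


@pytest.fixture(scope="session")
def zoo():
    """Reduced-scale trained ensembles shared by the heavier tests.

    Four seeds of Uniform and Biased (sigma_s = 12.5) networks, three seeds
    each of sigma_s = 3 and 25, and a small noise sweep at sigma_s = 17.5.
    Pretrained checkpoints are shared per seed across final priors.
    """
    priors = {"uniform": EnvironmentPrior(uniform=True),
              "b12.5": EnvironmentPrior(sigma_s=12.5),
              "b3": EnvironmentPrior(sigma_s=3.0),
              "b25": EnvironmentPrior(sigma_s=25.0)}
    pools = train_ensemble(priors, 3, base_seed=0)
    extra = train_ensemble({"uniform": priors["uniform"],
                            "b12.5": priors["b12.5"]}, 1, base_seed=3)
    pools["uniform"] += extra["uniform"]
    pools["b12.5"] += extra["b12.5"]
    return pools


@pytest.fixture(scope="session")
def noise_zoo():
    """Biased (sigma_s = 17.5) ensembles trained at two noise levels."""
    return train_noise_sweep((0.1, 0.3), EnvironmentPrior(sigma_s=17.5),
                             3, base_seed=50)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
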