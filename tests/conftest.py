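import numpy as np
import pytest

from roistates.data_model import Hyperparameters, McmcSettings
from roistates.network_prior import ConnectivityNetwork
from roistates.sampler import run_chain
from roistates.synthetic_data import generate_dataset, make_network, make_truth


@pytest.fixture(scope="session")
def small_network():
    net, corr = make_network(8, avg_degree=3.0, seed=11)
    return net, corr


@pytest.fixture(scope="session")
def small_dataset(small_network):
    """n=24, R=8 dataset with 3 planted discriminatory regions."""
    net, _ = small_network
    truth = make_truth(R=8, K=2, n_discriminatory=3, effect_size=2.5,
                       network=net, seed=11, q_covariates=0)
    data, truth = generate_dataset(truth, n=24, seed=12)
    return data, truth, net


@pytest.fixture(scope="session")
def small_hyper():
    return Hyperparameters(K=2, e=-2.0, f=0.1, c_k=5.0)


@pytest.fixture(scope="session")
def fitted_chains(small_dataset, small_hyper):
    """Two short chains on the small dataset, reused across summary tests."""
    data, truth, net = small_dataset
    settings = McmcSettings(n_iter=1200, burn_in=600, n_chains=2, seed=21)
    chains = [run_chain(data, small_hyper, net, settings, chain_id=c) for c in range(2)]
    return chains, data, truth, net
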