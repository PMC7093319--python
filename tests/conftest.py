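import numpy as np
import pytest

import prsnet


@pytest.fixture(scope="session")
def small_net():
    """10 symptoms + risk node, moderate planted edges."""
    return prsnet.generate_planted_network(
        10, 0.15, (0.2, 0.4), {"S05": 0.10}, seed=1)


@pytest.fixture(scope="session")
def small_dataset(small_net):
    return prsnet.sample_dataset(small_net, n=2000, seed=2)


@pytest.fixture(scope="session")
def small_corr(small_dataset):
    return prsnet.spearman_matrix(small_dataset)


def chain_network(p: int = 6, rho: float = 0.3):
    """Planted chain V1-V2-...-Vp with constant partial correlation."""
    pcor = np.zeros((p, p))
    for i in range(p - 1):
        pcor[i, i + 1] = pcor[i + 1, i] = rho
    labels = [f"V{i+1}" for i in range(p - 1)] + ["PRS"]
    tags = ["positive"] * (p - 1) + ["risk"]
    return prsnet.planted_network_from_pcor(pcor, labels, tags)


@pytest.fixture(scope="session")
def chain_net():
    return chain_network()


def model_from_weights(W, labels=None):
    """Wrap a raw weight matrix as a NetworkModel for path analytics."""
    W = np.asarray(W, dtype=float)
    p = W.shape[0]
    if labels is None:
        labels = tuple(f"V{i}" for i in range(p))
    adj = W != 0
    np.fill_diagonal(adj, False)
    return prsnet.NetworkModel(labels=tuple(labels), weights=W, adjacency=adj,
                               loglik=0.0, k_params=p, bic=0.0,
                               estimator="fixed", n=100)
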