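"""Shared fixtures: constructed and randomly seeded networks/controllers."""

from __future__ import annotations

import numpy as np
import pytest

from softmode.controller import make_random_controller
from softmode.grn_dynamics import GeneNetwork, find_fixed_point, random_network


def make_single_gene(k: float = 2.0, K: float = 1.0, gamma: float = 1.0) -> GeneNetwork:
    return GeneNetwork(k_mat=[[k]], K_mat=[[K]], decay=[gamma])


def make_gap20_network(n_genes: int = 2) -> GeneNetwork:
    """Uncoupled self-activating genes: gene 0 slow (rate 0.025), the rest
    fast (rate 0.5), hence mode gap 20.

    For a lone self-activator, n* = k - K and J = -(1 - K/k); K/k = 0.975
    gives the slow gene, K/k = 0.5 a fast one.
    """
    k_diag = np.full(n_genes, 2.0)
    k_diag[0] = 40.0
    K_diag = np.full(n_genes, 1.0)
    K_diag[0] = 39.0
    k_mat = np.diag(k_diag)
    K_mat = np.ones((n_genes, n_genes))
    np.fill_diagonal(K_mat, K_diag)
    net = GeneNetwork(k_mat=k_mat, K_mat=K_mat, decay=np.ones(n_genes))
    find_fixed_point(net, guess=np.ones(n_genes))
    return net


@pytest.fixture
def single_gene() -> GeneNetwork:
    return make_single_gene()


@pytest.fixture
def gap20_network() -> GeneNetwork:
    return make_gap20_network()


@pytest.fixture(scope="session")
def seeded_networks():
    """Twenty random stable 6-gene networks with solved fixed points."""
    return [random_network(6, seed=1000 + i) for i in range(20)]


@pytest.fixture(scope="session")
def net8():
    return random_network(8, seed=7)


@pytest.fixture
def ctrl_k2():
    return make_random_controller(5, 2, seed=3)
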