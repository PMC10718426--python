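"""Shared fixtures and independent brute-force oracles for the test suite."""

import numpy as np
import pytest

from tugchannel.model_core import BirthDeathChain


def dense_fixation_probability(chain: BirthDeathChain) -> np.ndarray:
    """Absorption-at-N probability via the embedded jump chain (dense solve).

    Independent of the production gambler's-ruin recursion: builds the
    one-jump transition matrix of the transient states and solves the dense
    linear system (I - T) h = b.
    """
    N = chain.N
    up, down = chain.up[1:N], chain.down[1:N]
    tot = up + down
    T = np.zeros((N - 1, N - 1))
    b = np.zeros(N - 1)
    for k in range(N - 1):  # state n = k + 1
        pu, pd = up[k] / tot[k], down[k] / tot[k]
        if k + 1 <= N - 2:
            T[k, k + 1] = pu
        else:
            b[k] += pu  # jump to the absorbing state N
        if k - 1 >= 0:
            T[k, k - 1] = pd
    h = np.linalg.solve(np.eye(N - 1) - T, b)
    return np.concatenate([[0.0], h, [1.0]])


def dense_mfpt(chain: BirthDeathChain) -> np.ndarray:
    """Unconditional MFPT via the fundamental matrix of the jump chain."""
    N = chain.N
    up, down = chain.up[1:N], chain.down[1:N]
    tot = up + down
    T = np.zeros((N - 1, N - 1))
    for k in range(N - 1):
        if k + 1 <= N - 2:
            T[k, k + 1] = up[k] / tot[k]
        if k - 1 >= 0:
            T[k, k - 1] = down[k] / tot[k]
    tau = np.linalg.solve(np.eye(N - 1) - T, 1.0 / tot)
    return np.concatenate([[0.0], tau, [0.0]])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230)


def random_chain(rng, N: int, structural_zeros: bool = False) -> BirthDeathChain:
    """A random positive-rate chain, optionally with spatial-style zeros."""
    up = rng.uniform(0.1, 10.0, N + 1)
    down = rng.uniform(0.1, 10.0, N + 1)
    up[[0, N]] = 0.0
    down[[0, N]] = 0.0
    if structural_zeros:
        up[1] = 0.0
        down[N - 1] = 0.0
    return BirthDeathChain(N=N, up=up, down=down)
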