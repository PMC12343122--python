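"""Shared fixtures and independent oracles.

The exhaustive-partition oracle enumerates set partitions via restricted
growth strings and scores them with a direct (non-incremental) objective
evaluation, independent of the optimizer's code path.
"""
from __future__ import annotations

from typing import Iterator

import numpy as np
import pytest

from chasecluster import synthdata as sd
from chasecluster.chase import _objective_labels


def rgs_partitions(n: int, max_blocks: int) -> Iterator[np.ndarray]:
    """All set partitions of n items into at most max_blocks blocks, as
    restricted-growth label vectors (each new block index introduced in
    order), so every partition appears exactly once."""
    labels = np.zeros(n, dtype=np.int64)

    def rec(i: int, used: int):
        if i == n:
            yield labels.copy()
            return
        for c in range(min(used + 1, max_blocks)):
            labels[i] = c
            yield from rec(i + 1, max(used, c + 1))

    yield from rec(1, 1)


def exhaustive_best(S: np.ndarray, gamma: float, penalty: float,
                    max_blocks: int) -> tuple[float, np.ndarray]:
    """Globally best objective over all partitions into <= max_blocks blocks."""
    best_val, best_labels = -np.inf, None
    for labels in rgs_partitions(S.shape[0], max_blocks):
        v = _objective_labels(labels, S, gamma, penalty)
        if v > best_val:
            best_val, best_labels = v, labels
    return best_val, best_labels


def random_similarity(n: int, rng: np.random.Generator) -> np.ndarray:
    """A random symmetric similarity matrix with unit diagonal."""
    S = rng.random((n, n))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    return S


def block_similarity(block_sizes: list[int], within: float = 1.0,
                     between: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Perfect planted-block similarity matrix and its block labels."""
    labels = np.concatenate([np.full(s, b) for b, s in enumerate(block_sizes)])
    S = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    np.fill_diagonal(S, 1.0)
    return S, labels


@pytest.fixture(scope="session")
def planted():
    """Default planted-partition fixture: 5 regions x 12 sites."""
    return sd.simulate_sites(sd.SyntheticConfig(rng_seed=11))


@pytest.fixture(scope="session")
def nested():
    """Two-level hierarchical fixture: 2 super-regions x 3 subregions x 6 sites."""
    return sd.simulate_nested_sites(rng_seed=11)
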