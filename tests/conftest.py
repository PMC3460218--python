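"""Shared fixtures: small trained networks reused across test modules."""

import warnings
from functools import lru_cache

import numpy as np
import pytest

from dpaan import (
    PartitionLayout,
    build_vocabulary,
    calibrate_equality,
    hopfield_train,
)

SIX_SYMBOLS = ("red", "blue", "green", "square", "circle", "triangle")


@lru_cache(maxsize=16)
def small_network(seed: int, n_slots: int = 3, slot_size: int = 100,
                  symbols: tuple = SIX_SYMBOLS):
    """A 3-slot, 6-symbol trained network with calibrated equality thresholds."""
    layout = PartitionLayout((slot_size,) * n_slots)
    vocab = build_vocabulary(layout, list(symbols), seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        weights = hopfield_train(vocab)
    eqcfg = calibrate_equality(vocab, weights)
    return vocab, weights, eqcfg


@pytest.fixture(scope="session")
def net3x6():
    """(vocab, weights, eqcfg) for the canonical 3-slot / 6-symbol network."""
    return small_network(0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tiny_network(rng, n_neurons=12, n_parts=3, n_patterns=2):
    """A tiny random network for brute-force oracle comparisons."""
    sizes = np.full(n_parts, n_neurons // n_parts)
    sizes[: n_neurons % n_parts] += 1
    layout = PartitionLayout(tuple(int(s) for s in sizes))
    names = [f"s{i}" for i in range(n_patterns)]
    vocab = build_vocabulary(layout, names, seed=int(rng.integers(2**31)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        weights = hopfield_train(vocab)
    return layout, vocab, weights
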