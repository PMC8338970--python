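"""Shared fixtures: a desk-scale trained regressor and a calibrated
flicker reference curve, built once per session.

The trained model (5000 flicker series of 2^16 samples) and the reference
curve (alpha grid step 0.05, 100 realizations of 2^17 samples per point)
are the study conditions for every downstream statistical check, so unit,
property and acceptance tests all share them.
"""

import itertools
import math

import numpy as np
import pytest

from chaostoch.alpha_regressor import TrainingConfig, build_corpus, train
from chaostoch.fn_reference import calibrate_curve


_PERM_INDEX: dict[int, dict[tuple, int]] = {}


def oracle_pattern_index(window) -> int:
    """Naive per-window oracle: stable argsort rank-string, then its index
    in the lexicographically sorted list of permutations."""
    w = np.asarray(window, dtype=float)
    order = np.argsort(w, kind="stable")
    ranks = np.empty(w.size, dtype=int)
    ranks[order] = np.arange(w.size)
    if w.size not in _PERM_INDEX:
        perms = sorted(itertools.permutations(range(w.size)))
        _PERM_INDEX[w.size] = {p: i for i, p in enumerate(perms)}
    return _PERM_INDEX[w.size][tuple(ranks)]


def oracle_distribution(values, D):
    counts = np.zeros(math.factorial(D))
    for start in range(len(values) - D + 1):
        counts[oracle_pattern_index(values[start : start + D])] += 1
    return counts / counts.sum()


@pytest.fixture(scope="session")
def trained():
    """Desk-scale trained regressor and its held-out evaluation report."""
    cfg = TrainingConfig(n_series=5000, series_length=2**16, epochs=100, seed=11)
    corpus = build_corpus(cfg)
    model, report = train(corpus, cfg)
    return model, report


@pytest.fixture(scope="session")
def model(trained):
    return trained[0]


@pytest.fixture(scope="session")
def fn_curve():
    """Reference curve at the package defaults (step 0.05, 100 x 2^17)."""
    return calibrate_curve(seed=12)
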