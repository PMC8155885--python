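"""Shared fixtures: small feature spaces and planted tables."""

import numpy as np
import pytest

from implearn import FeatureSpace, gen_feature_table, informative_bits


@pytest.fixture(scope="session")
def small_space():
    return FeatureSpace(channels=("F3", "F4", "FZ"), bands=("theta", "alpha", "beta"))


@pytest.fixture(scope="session")
def small_informative():
    return (("F3", "theta"), ("F4", "alpha"), ("FZ", "beta"))


@pytest.fixture(scope="session")
def small_planted_table(small_space, small_informative):
    """60 rows/class over a 9-feature space with 3 informative features."""
    return gen_feature_table(n_per_class=60, space=small_space,
                             informative_set=small_informative,
                             gap=0.3, noise_sd=0.6, tau_max=10, seed=3)


@pytest.fixture(scope="session")
def small_informative_bits(small_space, small_informative):
    return informative_bits(small_informative, small_space)


def naive_match_counts(x, m, r):
    """Exhaustive O(N^2) enumeration of template pairs (test oracle)."""
    x = list(map(float, x))
    nt = len(x) - m
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b
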