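"""Shared fixtures and independent oracles for the test suite."""

import warnings

import numpy as np
import pytest

from pdtrial import ScenarioConfig, km_fit


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_censored():
    """Three subjects, middle one censored: times (2, 4, 6), events (1, 0, 1)."""
    return np.array([2.0, 4.0, 6.0]), np.array([1, 0, 1])


@pytest.fixture
def null_config():
    """Ideal-physician scenario of the null-utility grid, first row:
    positives do equally well on A and B (9 months), negatives better on A
    (12 vs 9), prevalence 0.25."""
    return ScenarioConfig(seed=7)


def km_functional_oracle(times, events, t, functional):
    """KM functional computed straight from the product-limit curve."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve = km_fit(np.asarray(times, float), np.asarray(events, int))
        return curve.survival_at(t) if functional == "survival" else curve.rmst(t)


def brute_force_pseudo(times, events, t, functional):
    """Leave-one-out jackknife oracle: recomputes the KM functional n + 1
    times, independent of the closed-form implementation under test."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    n = len(times)
    theta = km_functional_oracle(times, events, t, functional)
    values = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        loo = km_functional_oracle(times[mask], events[mask], t, functional)
        values[i] = n * theta - (n - 1) * loo
    return values
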