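"""Shared fixtures: synthetic cohorts with known truth and closed-form
oracles for the homogeneous illness-death model without recovery."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from cogspan.synthesis import TruthConfig, default_truth_params, generate_dataset


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # small-cohort refits may emit convergence chatter; tests assert on the
    # returned diagnostics instead
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def truth():
    return default_truth_params()


@pytest.fixture(scope="session")
def nocov_truth():
    """Default truth with no covariate effects (reference-profile model)."""
    return replace(default_truth_params(), beta=np.zeros((4, 0)),
                   covariate_names=())


@pytest.fixture(scope="session")
def small_panel():
    """Modest default-condition cohort for fit smoke tests."""
    panel, _ = generate_dataset(TruthConfig(n=400, seed=11))
    return panel


@pytest.fixture(scope="session")
def nocov_panel(nocov_truth):
    panel, _ = generate_dataset(
        TruthConfig(n=300, seed=5, params=nocov_truth, covariates=()))
    return panel


def closed_form_P(q12, q13, q23, t):
    """Analytic transition matrix of the time-homogeneous illness-death
    model without recovery (q21 = 0), used as an independent oracle."""
    a = q12 + q13
    P11 = np.exp(-a * t)
    P22 = np.exp(-q23 * t)
    if abs(q23 - a) > 1e-12:
        P12 = q12 * (np.exp(-a * t) - np.exp(-q23 * t)) / (q23 - a)
    else:
        P12 = q12 * t * np.exp(-a * t)
    return np.array([
        [P11, P12, 1 - P11 - P12],
        [0.0, P22, 1 - P22],
        [0.0, 0.0, 1.0],
    ])
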