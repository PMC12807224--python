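"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import dbltune as dt


def ap_bruteforce(scores, labels) -> float:
    """Average precision by direct threshold enumeration.

    Walks every distinct score value as a threshold, from high to low, and
    accumulates (recall increment) * precision.  Independent of both the
    package implementation and scikit-learn.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores.tolist()), reverse=True):
        called = scores >= t
        tp = int(labels[called].sum())
        precision = tp / called.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def ols_normal_equations(X, y):
    """Brute-force OLS via the normal equations (oracle only)."""
    return np.linalg.solve(X.T @ X, X.T @ y)


@pytest.fixture(scope="session")
def scdbl_space():
    return dt.scdblfinder_space()


@pytest.fixture(scope="session")
def eq_reduced_coeffs():
    return dict(dt.SCDBLFINDER_REDUCED_COEFFS)


@pytest.fixture(scope="session")
def two_type_dataset():
    """Well-separated two-cell-type dataset with 20% planted doublets."""
    params = dt.SimulationParams(
        n_droplets=800,
        n_genes=1200,
        n_cell_types=2,
        doublet_rate=0.2,
        seed=11,
        type_spread=1.0,
    )
    return dt.simulate_counts(params)


@pytest.fixture(scope="session")
def tiny_dataset():
    params = dt.SimulationParams(
        n_droplets=200, n_genes=300, n_cell_types=2, doublet_rate=0.15, seed=3
    )
    return dt.simulate_counts(params)
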