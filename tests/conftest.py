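"""Shared fixtures and tiny matrix builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mosaicweb.net_core import InteractionMatrix, NetworkUnit
from mosaicweb.synthetic_data import MosaicConfig, generate_mosaic, recovery_report


def bmat(rows, plants=None, insects=None) -> InteractionMatrix:
    """Binary matrix from a list of 0/1 rows."""
    values = np.asarray(rows, dtype=float)
    n_p, n_a = values.shape
    return InteractionMatrix(
        tuple(plants or (f"P{i}" for i in range(n_p))),
        tuple(insects or (f"A{j}" for j in range(n_a))),
        values,
        "binary",
    )


def cmat(rows, plants=None, insects=None) -> InteractionMatrix:
    """Counts matrix from a list of nonnegative integer rows."""
    values = np.asarray(rows, dtype=float)
    n_p, n_a = values.shape
    return InteractionMatrix(
        tuple(plants or (f"P{i}" for i in range(n_p))),
        tuple(insects or (f"A{j}" for j in range(n_a))),
        values,
        "counts",
    )


def unit(matrix: InteractionMatrix, unit_id="u0", altitude=2200, month=0,
         precipitation=300.0) -> NetworkUnit:
    return NetworkUnit(unit_id, altitude, month, matrix,
                       precipitation=precipitation)


def random_admitted_binary(rng: np.random.Generator, max_dim: int = 6) -> InteractionMatrix:
    """Random binary matrix with >= 2 species and >= 1 link on each side."""
    while True:
        n_p = int(rng.integers(2, max_dim + 1))
        n_a = int(rng.integers(2, max_dim + 1))
        values = (rng.random((n_p, n_a)) < rng.uniform(0.2, 0.8)).astype(float)
        if (values.sum(axis=1) > 0).all() and (values.sum(axis=0) > 0).all():
            return bmat(values)


def random_admitted_counts(rng: np.random.Generator, max_dim: int = 5,
                           max_count: int = 6) -> InteractionMatrix:
    while True:
        n_p = int(rng.integers(2, max_dim + 1))
        n_a = int(rng.integers(2, max_dim + 1))
        values = rng.integers(0, max_count + 1, size=(n_p, n_a)).astype(float)
        if (values.sum(axis=1) > 0).all() and (values.sum(axis=0) > 0).all():
            return cmat(values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250925)


@pytest.fixture(scope="session")
def default_mosaics():
    """Thirty default-configuration mosaics with their truths (seeded)."""
    return [generate_mosaic(MosaicConfig(seed=seed)) for seed in range(30)]


@pytest.fixture(scope="session")
def default_recoveries(default_mosaics):
    return [recovery_report(units, truth) for units, truth in default_mosaics]
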