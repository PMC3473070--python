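"""Shared fixtures: small synthetic arrays and fitted mixtures.

Expensive fits are session-scoped; everything is generated at test time
from fixed seeds.
"""

import numpy as np
import pytest

from snpmix import (
    PenaltyConfig,
    bspline_basis,
    build_histogram,
    call_array,
    make_grid,
    preset,
    simulate_array,
    transform_signals,
)


@pytest.fixture(scope="session")
def gauss_counts_1d():
    """Unimodal 1-D histogram: 10^4 standard-normal draws on 100 bins."""
    rng = np.random.default_rng(11)
    x = rng.normal(0.0, 1.0, 10_000)
    edges = np.linspace(-4, 4, 101)
    y, _ = np.histogram(x, edges)
    mid = (edges[:-1] + edges[1:]) / 2.0
    return y.astype(float), mid


@pytest.fixture(scope="session")
def basis_1d(gauss_counts_1d):
    _, mid = gauss_counts_1d
    return bspline_basis(mid, -4.0, 4.0, nseg=10)


@pytest.fixture(scope="session")
def cluster_counts_2d():
    """Single-cluster 20 x 20 count matrix on the unit square."""
    rng = np.random.default_rng(5)
    pts = rng.normal([0.45, 0.55], [0.12, 0.10], size=(4000, 2))
    ex = np.linspace(0, 1, 21)
    counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[ex, ex])
    mid = (ex[:-1] + ex[1:]) / 2.0
    return counts, mid


@pytest.fixture(scope="session")
def bases_2d_small(cluster_counts_2d):
    _, mid = cluster_counts_2d
    b = bspline_basis(mid, 0.0, 1.0, nseg=4)
    return b, b


@pytest.fixture(scope="session")
def affy_array():
    """A 20k-SNP well-separated array with truth labels."""
    cfg = preset("affymetrix_like", n_snps=20_000, seed=42)
    signals, truth = simulate_array(cfg)
    return signals, truth


@pytest.fixture(scope="session")
def affy_result(affy_array):
    signals, _ = affy_array
    return call_array(signals)


@pytest.fixture(scope="session")
def affy_fit(affy_result):
    return affy_result.fit


@pytest.fixture
def default_pen():
    return PenaltyConfig(order=3, lam=10.0)
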