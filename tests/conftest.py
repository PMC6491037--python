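"""Shared fixtures and helpers for the test suite.

All synthetic inputs are generated programmatically with fixed seeds;
nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from envconn import CohortDesign, ConnMatrix, EdgeMask
from envconn.bands import ALPHA
from envconn.connectome import matrix_from_upper


def make_conn(rng: np.random.Generator, n_nodes: int, subject_id="s", band="Alpha") -> ConnMatrix:
    """Random symmetric zero-diagonal connectome."""
    n_edges = n_nodes * (n_nodes - 1) // 2
    return ConnMatrix(
        subject_id=subject_id, band=band, z=matrix_from_upper(rng.standard_normal(n_edges), n_nodes)
    )


def full_mask(n_nodes: int, band="Alpha") -> EdgeMask:
    m = np.ones((n_nodes, n_nodes), dtype=bool)
    np.fill_diagonal(m, False)
    return EdgeMask(band=band, mask=m, scope="pooled")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture
def small_alpha_design() -> CohortDesign:
    """Cheap single-band design for envelope-level simulation."""
    return CohortDesign(
        n_case=10, n_control=10, n_nodes=12, duration=300.0, bands=[ALPHA], seed=7
    )
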