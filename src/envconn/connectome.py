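"""Fisher-z amplitude-correlation connectomes and rank-based edge masks.

Per subject and band, the connectome is the pairwise Pearson correlation
of the 1 Hz amplitude envelopes, Fisher-transformed (atanh) and — by
default — variance-normalized by sqrt(n-3).  The six band maps combine
into a single ``Combined`` map as the per-edge vector magnitude.  Edge
masks keep only "valid" edges: those whose across-subject mean rank of
connectivity strength lies in the top 20%, computed per cohort and
unioned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .bands import COMBINED
from .envelope import EnvelopeSet

__all__ = [
    "ConnMatrix",
    "EdgeMask",
    "amplitude_correlation_matrix",
    "zscore_connectome",
    "combined_map",
    "valid_edge_mask",
    "upper_triangle",
    "matrix_from_upper",
]


def upper_triangle(z: np.ndarray) -> np.ndarray:
    """Strict-upper-triangle values of a square matrix, row-major order."""
    i, j = np.triu_indices(z.shape[0], k=1)
    return z[i, j]


def matrix_from_upper(values: np.ndarray, n_nodes: int) -> np.ndarray:
    """Symmetric zero-diagonal matrix from strict-upper-triangle values."""
    m = np.zeros((n_nodes, n_nodes))
    i, j = np.triu_indices(n_nodes, k=1)
    m[i, j] = values
    m[j, i] = values
    return m


@dataclass
class ConnMatrix:
    """Symmetric node-by-node Fisher-z connectivity map, zero diagonal."""

    subject_id: str
    band: str  # band name or "Combined"
    z: np.ndarray
    node_labels: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("connectivity matrix contains non-finite values")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(self.z) != 0):
            raise ValueError("connectivity diagonal must be zero by convention")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]

    def upper(self) -> np.ndarray:
        return upper_triangle(self.z)


@dataclass
class EdgeMask:
    """Boolean symmetric map of valid edges for one band.

    ``scope`` records how the mask was computed: ``"pooled"`` (one
    cohort containing all subjects), ``"cohort"`` (a single group), or
    ``"union"`` (either-cohort union of two group masks).  Classifier
    feature pooling requires ``"pooled"`` scope to avoid selection bias.
    """

    band: str
    mask: np.ndarray
    scope: str = "pooled"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or self.mask.shape[0] != self.mask.shape[1]:
            raise ValueError("mask must be square")
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("mask must be symmetric")
        if np.any(np.diag(self.mask)):
            raise ValueError("mask diagonal must be False")

    @property
    def n_edges(self) -> int:
        return int(upper_triangle(self.mask).sum())

    @property
    def n_nodes(self) -> int:
        return self.mask.shape[0]

    def edge_list(self) -> list[tuple[int, int]]:
        i, j = np.triu_indices(self.n_nodes, k=1)
        keep = self.mask[i, j]
        return list(zip(i[keep].tolist(), j[keep].tolist()))


def amplitude_correlation_matrix(
    env_set: EnvelopeSet, variance_normalize: bool = True
) -> ConnMatrix:
    """Fisher-z correlation matrix of a subject's downsampled envelopes.

    Pearson correlation between every envelope pair, then atanh.  With
    ``variance_normalize`` (default), values are scaled by sqrt(n-3) so
    they are approximately standard normal under independence; since n
    is constant across edges and subjects, the scaling is inconsequential
    for all rank- and z-score-based statistics downstream.
    """
    env = env_set.env
    if env.shape[1] < 10:
        raise ValueError(f"need at least 10 envelope samples, got {env.shape[1]}")
    sd = env.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"zero-variance envelope at node(s) {bad}")
    r = np.corrcoef(env)
    off = ~np.eye(env.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1 - 1e-12):
        i, j = np.unravel_index(np.argmax(np.abs(r) * off), r.shape)
        raise ValueError(
            f"degenerate correlation |r| ~ 1 between distinct nodes ({i}, {j})"
        )
    np.fill_diagonal(r, 0.0)  # diagonal is 0 by convention; avoids atanh(1)
    z = np.arctanh(r)
    if variance_normalize:
        z = z * math.sqrt(env.shape[1] - 3)
    return ConnMatrix(
        subject_id=env_set.subject_id,
        band=env_set.band.name if hasattr(env_set.band, "name") else str(env_set.band),
        z=z,
        metadata={"n_samples": env.shape[1], "variance_normalized": variance_normalize},
    )


def zscore_connectome(conn: ConnMatrix) -> ConnMatrix:
    """Standardize a connectome to zero mean, unit SD over its edges.

    Mean and sample SD are computed over the strict upper triangle only;
    corrects for global differences in data quality across subjects.
    """
    vals = conn.upper()
    if vals.size < 2:
        raise ValueError("need more than one unique edge to z-score")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("constant connectome cannot be z-scored")
    return ConnMatrix(
        subject_id=conn.subject_id,
        band=conn.band,
        z=matrix_from_upper((vals - vals.mean()) / sd, conn.n_nodes),
        node_labels=conn.node_labels,
        metadata={**conn.metadata, "zscored": True},
    )


def combined_map(per_band: Sequence[ConnMatrix]) -> ConnMatrix:
    """Across-band vector-magnitude map: per edge, the square root of the
    sum of the six squared band values."""
    if len(per_band) != 6:
        raise ValueError(f"combined map requires exactly 6 band maps, got {len(per_band)}")
    n = per_band[0].n_nodes
    sid = per_band[0].subject_id
    for c in per_band[1:]:
        if c.n_nodes != n:
            raise ValueError("band maps have mismatched node sets")
        if c.subject_id != sid:
            raise ValueError("band maps belong to different subjects")
    stacked = np.stack([c.z for c in per_band])
    return ConnMatrix(
        subject_id=sid,
        band=COMBINED,
        z=np.sqrt((stacked**2).sum(axis=0)),
        node_labels=per_band[0].node_labels,
        metadata={"bands": [c.band for c in per_band]},
    )


def _cohort_mean_rank(conns: Sequence[ConnMatrix]) -> np.ndarray:
    """Mean across subjects of each edge's within-subject ascending rank."""
    if not conns:
        raise ValueError("cohort must contain at least one subject")
    n = conns[0].n_nodes
    ranks = np.zeros(n * (n - 1) // 2)
    for c in conns:
        if c.n_nodes != n:
            raise ValueError("connectomes have mismatched node sets")
        ranks += rankdata(c.upper(), method="average")
    return ranks / len(conns)


def valid_edge_mask(
    cohorts: Sequence[Sequence[ConnMatrix]],
    threshold_pct: float = 80.0,
    band: str | None = None,
) -> EdgeMask:
    """Rank-based valid-edge mask, unioned across cohorts.

    Within each cohort: rank every edge within each subject (ascending,
    mid-rank ties), average ranks across subjects, and retain the top
    ``100 - threshold_pct`` percent of edges (for the default 80%, the
    top 20%: floor(0.2 E) edges; ties at the boundary are all retained).
    The final mask marks edges valid in *any* cohort, so large group
    differences cannot silently remove an edge from the analysis.
    """
    if not 0 < threshold_pct < 100:
        raise ValueError("threshold_pct must lie in (0, 100)")
    if not cohorts or any(len(c) == 0 for c in cohorts):
        raise ValueError("each cohort must contain at least one subject")
    n = cohorts[0][0].n_nodes
    n_edges_total = n * (n - 1) // 2
    # floor of the retained fraction; integer-safe against 1 - 0.8 float error
    k = int(math.floor(n_edges_total * (100.0 - threshold_pct) / 100.0))
    if k < 1:
        raise ValueError("threshold retains no edges")
    union = np.zeros(n_edges_total, dtype=bool)
    for cohort in cohorts:
        mean_rank = _cohort_mean_rank(cohort)
        if mean_rank.shape[0] != n_edges_total:
            raise ValueError("cohorts have mismatched node sets")
        kth_largest = np.sort(mean_rank)[-k]
        union |= mean_rank >= kth_largest
    scope = "pooled" if len(cohorts) == 1 else "union"
    return EdgeMask(
        band=band if band is not None else cohorts[0][0].band,
        mask=matrix_from_upper(union.astype(float), n).astype(bool),
        scope=scope,
    )
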