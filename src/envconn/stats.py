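"""Permutation and resampling group statistics on masked connectomes.

Three tiers of inference on the valid edges of a two-group comparison:

1. edgewise unpaired t-tests with max-statistic (omnibus) permutation
   correction for family-wise error;
2. a network-based cluster-size test: threshold edges at uncorrected
   p < 0.05 per sign, find the largest connected component, and compare
   its edge count against the permutation null;
3. a sign-consistency confidence test: repeatedly subsample half of
   each group and keep only edges whose group-difference sign is stable
   in more than 95% of subsamples.

Plus the node-level activity contrast on envelope coefficient of
variation, a cross-experiment effect-size comparison, and a two-sample
t-test power utility (noncentral t).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import nct, pearsonr
from scipy.stats import t as t_dist

from .connectome import ConnMatrix, EdgeMask, matrix_from_upper, upper_triangle
from .envelope import ActivityProfile

__all__ = [
    "GroupStatResult",
    "ClusterResult",
    "CrossExperimentResult",
    "edgewise_ttest",
    "maxstat_correct",
    "nbs_cluster_test",
    "subsample_sign_consistency",
    "activity_contrast",
    "cross_experiment_comparison",
    "ttest_power",
    "group_stats",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ClusterResult:
    """Largest suprathreshold connected cluster for one contrast sign."""

    sign: int  # +1 or -1
    size_edges: int
    size_nodes: int
    p: float
    edges: list[tuple[int, int]]


@dataclass
class GroupStatResult:
    """All three statistical tiers for one band's group contrast."""

    band: str
    t_map: np.ndarray
    p_unc: np.ndarray
    p_corr: np.ndarray
    clusters: dict[int, ClusterResult]
    ci_edges: np.ndarray  # +1 / -1 / 0 per edge
    n_pos: int  # significant (p_unc < 0.05) increases
    n_neg: int
    params: dict = field(default_factory=dict)


def _edge_matrix(conns: Sequence[ConnMatrix], mask: EdgeMask) -> np.ndarray:
    """Subjects-by-masked-edges value matrix."""
    n = mask.n_nodes
    i, j = np.triu_indices(n, k=1)
    keep = mask.mask[i, j]
    rows = []
    for c in conns:
        if c.n_nodes != n:
            raise ValueError("connectome/mask node mismatch")
        rows.append(c.z[i, j][keep])
    return np.asarray(rows)


def _masked_to_matrix(values: np.ndarray, mask: EdgeMask, fill: float = np.nan) -> np.ndarray:
    n = mask.n_nodes
    i, j = np.triu_indices(n, k=1)
    keep = mask.mask[i, j]
    full = np.full(i.shape[0], fill)
    full[keep] = values
    m = matrix_from_upper(full, n)
    np.fill_diagonal(m, fill)
    return m


def _pooled_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized pooled-variance two-sample t, A minus B, per column.

    Columns with zero pooled variance yield NaN.
    """
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    t[denom == 0] = np.nan
    return t


def _check_groups(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if a.shape[1] == 0:
        raise ValueError("edge mask is empty")


def edgewise_ttest(
    groupA: Sequence[ConnMatrix], groupB: Sequence[ConnMatrix], mask: EdgeMask
) -> tuple[np.ndarray, np.ndarray]:
    """Unpaired pooled-variance t (A minus B) and two-tailed p per masked edge.

    Returns symmetric node-by-node maps; unmasked entries are NaN in the
    p map and 0 in the t map.  Edges with zero pooled variance are NaN
    in both and excluded from any downstream correction.
    """
    a = _edge_matrix(groupA, mask)
    b = _edge_matrix(groupB, mask)
    _check_groups(a, b)
    t = _pooled_t(a, b)
    df = a.shape[0] + b.shape[0] - 2
    p = 2 * t_dist.sf(np.abs(t), df)
    return _masked_to_matrix(t, mask, fill=0.0), _masked_to_matrix(p, mask)


def _permutation_splits(
    na: int, nb: int, n_perm: int, rng: np.random.Generator
) -> tuple[Iterator[np.ndarray], int, bool]:
    """Iterator of group-A index arrays over relabelings of n = na + nb.

    Enumerates all distinct splits exactly when there are no more of
    them than ``n_perm`` (the observed labelling is then included once);
    otherwise draws ``n_perm`` uniform random relabelings.
    """
    n = na + nb
    n_distinct = math.comb(n, na)
    if n_distinct <= n_perm:
        return (np.asarray(c) for c in combinations(range(n), na)), n_distinct, True
    def draws() -> Iterator[np.ndarray]:
        for _ in range(n_perm):
            yield rng.permutation(n)[:na]
    return draws(), n_perm, False


def maxstat_correct(
    groupA: Sequence[ConnMatrix],
    groupB: Sequence[ConnMatrix],
    mask: EdgeMask,
    n_perm: int = 5000,
    seed: int | None = None,
) -> np.ndarray:
    """Family-wise-corrected p per masked edge via the max-|t| permutation null.

    For each relabeling of the pooled subjects, the maximum |t| over
    masked edges is recorded; an edge's corrected p is the proportion of
    relabelings whose max |t| reaches its observed |t| (the "omnibus"
    single-threshold correction).  Random-permutation p values use the
    (b+1)/(m+1) convention so p > 0; exhaustively enumerable designs are
    enumerated exactly.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; corrected p is coarse", RuntimeWarning)
    a = _edge_matrix(groupA, mask)
    b = _edge_matrix(groupB, mask)
    _check_groups(a, b)
    t_obs = _pooled_t(a, b)
    valid = ~np.isnan(t_obs)
    x = np.vstack([a, b])
    na, n = a.shape[0], x.shape[0]
    rng = np.random.default_rng(seed)
    splits, total, exhaustive = _permutation_splits(na, b.shape[0], n_perm, rng)
    count = np.zeros(t_obs.shape[0])
    for idx_a in splits:
        sel = np.zeros(n, dtype=bool)
        sel[idx_a] = True
        t_perm = _pooled_t(x[sel], x[~sel])
        max_t = np.nanmax(np.abs(t_perm[valid])) if valid.any() else 0.0
        count += max_t >= np.abs(t_obs) - 1e-12
    p = count / total if exhaustive else (count + 1) / (total + 1)
    p[~valid] = np.nan
    return _masked_to_matrix(p, mask)


def _largest_component(
    edge_nodes: np.ndarray, suprathreshold: np.ndarray, n_nodes: int
) -> tuple[int, int, list[tuple[int, int]]]:
    """Largest connected component of the suprathreshold edge graph.

    Returns (edge count, node count, member edges).  ``edge_nodes`` is
    the (2, n_masked_edges) node-index array of the masked edges.
    """
    if not suprathreshold.any():
        return 0, 0, []
    ii = edge_nodes[0][suprathreshold]
    jj = edge_nodes[1][suprathreshold]
    adj = sparse.coo_matrix(
        (np.ones(ii.shape[0]), (ii, jj)), shape=(n_nodes, n_nodes)
    )
    n_comp, labels = connected_components(adj, directed=False)
    edge_labels = labels[ii]
    sizes = np.bincount(edge_labels, minlength=n_comp)
    best = int(np.argmax(sizes))
    member = edge_labels == best
    edges = list(zip(ii[member].tolist(), jj[member].tolist()))
    return int(sizes[best]), int(np.unique(np.concatenate([ii[member], jj[member]])).size), edges


def nbs_cluster_test(
    groupA: Sequence[ConnMatrix],
    groupB: Sequence[ConnMatrix],
    mask: EdgeMask,
    edge_alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int | None = None,
) -> dict[int, ClusterResult]:
    """Network-based largest-cluster test, positive and negative signs apart.

    Edges with two-tailed uncorrected p below ``edge_alpha`` form a
    graph per contrast sign; the statistic is the edge count of its
    largest connected component, referred to the permutation null of
    that same statistic.  An empty suprathreshold graph scores size 0,
    p = 1.
    """
    a = _edge_matrix(groupA, mask)
    b = _edge_matrix(groupB, mask)
    _check_groups(a, b)
    df = a.shape[0] + b.shape[0] - 2
    t_crit = t_dist.ppf(1 - edge_alpha / 2, df)
    n_nodes = mask.n_nodes
    i, j = np.triu_indices(n_nodes, k=1)
    keep = mask.mask[i, j]
    edge_nodes = np.vstack([i[keep], j[keep]])

    t_obs = _pooled_t(a, b)
    obs = {
        +1: _largest_component(edge_nodes, t_obs > t_crit, n_nodes),
        -1: _largest_component(edge_nodes, -t_obs > t_crit, n_nodes),
    }
    x = np.vstack([a, b])
    rng = np.random.default_rng(seed)
    splits, total, exhaustive = _permutation_splits(a.shape[0], b.shape[0], n_perm, rng)
    exceed = {+1: 0, -1: 0}
    for idx_a in splits:
        sel = np.zeros(x.shape[0], dtype=bool)
        sel[idx_a] = True
        t_perm = _pooled_t(x[sel], x[~sel])
        for sign in (+1, -1):
            size, _, _ = _largest_component(edge_nodes, sign * t_perm > t_crit, n_nodes)
            if size >= obs[sign][0]:
                exceed[sign] += 1
    out = {}
    for sign in (+1, -1):
        size_e, size_n, edges = obs[sign]
        if size_e == 0:
            p = 1.0
        elif exhaustive:
            p = exceed[sign] / total
        else:
            p = (exceed[sign] + 1) / (total + 1)
        out[sign] = ClusterResult(sign=sign, size_edges=size_e, size_nodes=size_n, p=p, edges=edges)
    return out


def subsample_sign_consistency(
    groupA: Sequence[ConnMatrix],
    groupB: Sequence[ConnMatrix],
    mask: EdgeMask,
    frac: float = 0.5,
    n_iter: int = 5000,
    conf: float = 0.95,
    seed: int | None = None,
) -> np.ndarray:
    """Half-cohort sign-consistency flags (+1 / -1 / 0) per masked edge.

    Each iteration draws ``frac`` of each group without replacement
    (round-half-up, e.g. 26 of 51 and 54 of 108) and records the sign of
    mean(A) - mean(B) per edge.  Edges whose sign is stable in more than
    ``conf`` of iterations are flagged with that sign; all others are 0.
    Unmasked entries are 0.
    """
    a = _edge_matrix(groupA, mask)
    b = _edge_matrix(groupB, mask)
    _check_groups(a, b)
    ka = round_half_up(frac * a.shape[0])
    kb = round_half_up(frac * b.shape[0])
    if ka < 2 or kb < 2:
        raise ValueError(
            f"subsample sizes ({ka}, {kb}) too small; need at least 2 per group"
        )
    rng = np.random.default_rng(seed)
    pos = np.zeros(a.shape[1])
    neg = np.zeros(a.shape[1])
    for _ in range(n_iter):
        da = a[rng.choice(a.shape[0], ka, replace=False)].mean(axis=0)
        db = b[rng.choice(b.shape[0], kb, replace=False)].mean(axis=0)
        diff = da - db
        pos += diff > 0
        neg += diff < 0
    flags = np.zeros(a.shape[1], dtype=int)
    flags[pos / n_iter > conf] = 1
    flags[neg / n_iter > conf] = -1
    return _masked_to_matrix(flags.astype(float), mask, fill=0.0).astype(int)


def activity_contrast(
    groupA: Sequence[ActivityProfile],
    groupB: Sequence[ActivityProfile],
    n_perm: int = 5000,
    seed: int | None = None,
    alpha: float = 0.025,
) -> dict:
    """Node-level CoV contrast with per-sign max-statistic correction.

    Unpaired t per node on the coefficient of variation, A minus B.
    Positive and negative contrasts are corrected separately against the
    permutation null of the max (resp. min) node t, each at ``alpha``
    (default 0.025, a corrected two-tailed test at 0.05 overall).
    """
    a = np.asarray([p.cov for p in groupA])
    b = np.asarray([p.cov for p in groupB])
    _check_groups(a, b)
    t_obs = _pooled_t(a, b)
    x = np.vstack([a, b])
    rng = np.random.default_rng(seed)
    splits, total, exhaustive = _permutation_splits(a.shape[0], b.shape[0], n_perm, rng)
    count_pos = np.zeros(t_obs.shape[0])
    count_neg = np.zeros(t_obs.shape[0])
    for idx_a in splits:
        sel = np.zeros(x.shape[0], dtype=bool)
        sel[idx_a] = True
        t_perm = _pooled_t(x[sel], x[~sel])
        count_pos += np.nanmax(t_perm) >= t_obs - 1e-12
        count_neg += np.nanmin(t_perm) <= t_obs + 1e-12
    if exhaustive:
        p_pos, p_neg = count_pos / total, count_neg / total
    else:
        p_pos, p_neg = (count_pos + 1) / (total + 1), (count_neg + 1) / (total + 1)
    return {
        "t": t_obs,
        "p_pos": p_pos,
        "p_neg": p_neg,
        "sig_pos": p_pos < alpha,
        "sig_neg": p_neg < alpha,
        "alpha": alpha,
    }


@dataclass
class CrossExperimentResult:
    """Comparison of two experiments' edgewise effect sizes."""

    product_map: np.ndarray  # t1 * t2, elementwise
    r: float  # Pearson r of t values over common masked edges
    p_r: float
    n_common: int
    conjunction: list[tuple[int, int, float, float]]  # (i, j, t1, t2)


def cross_experiment_comparison(
    tmap1: np.ndarray,
    tmap2: np.ndarray,
    mask1: EdgeMask,
    mask2: EdgeMask,
    sig1: np.ndarray | None = None,
    sig2: np.ndarray | None = None,
) -> CrossExperimentResult:
    """Overlap of effects between two independent group contrasts.

    The product map t1*t2 highlights edges strong in both experiments
    (negative where the effect directions disagree); the scalar summary
    is the Pearson correlation of the two t vectors over the common
    masked edges.  If boolean significance maps are supplied, the
    conjunction lists edges significant in both, with both signed t's.
    """
    if tmap1.shape != tmap2.shape:
        raise ValueError("t-maps must share a node set")
    common = mask1.mask & mask2.mask
    iu = np.triu_indices(common.shape[0], k=1)
    keep = common[iu]
    if keep.sum() < 3:
        raise ValueError(f"only {int(keep.sum())} common masked edges; need at least 3")
    t1 = np.nan_to_num(tmap1)
    t2 = np.nan_to_num(tmap2)
    r, p_r = pearsonr(t1[iu][keep], t2[iu][keep])
    conjunction = []
    if sig1 is not None and sig2 is not None:
        both = np.asarray(sig1, dtype=bool) & np.asarray(sig2, dtype=bool) & common
        for i, j in zip(*np.nonzero(np.triu(both, k=1))):
            conjunction.append((int(i), int(j), float(t1[i, j]), float(t2[i, j])))
    return CrossExperimentResult(
        product_map=t1 * t2,
        r=float(r),
        p_r=float(p_r),
        n_common=int(keep.sum()),
        conjunction=conjunction,
    )


def ttest_power(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Power of the two-sample two-tailed t-test at effect size Cohen's d.

    Uses the noncentral t distribution with noncentrality
    ``d * sqrt(n1 n2 / (n1 + n2))`` and ``n1 + n2 - 2`` degrees of
    freedom.  At d = 0 the value equals alpha (the null rejection rate).
    """
    if d < 0:
        raise ValueError("d must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 per group")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = n1 + n2 - 2
    ncp = d * math.sqrt(n1 * n2 / (n1 + n2))
    t_crit = t_dist.ppf(1 - alpha / 2, df)
    return float(nct.sf(t_crit, df, ncp) + nct.cdf(-t_crit, df, ncp))


def group_stats(
    groupA: Sequence[ConnMatrix],
    groupB: Sequence[ConnMatrix],
    mask: EdgeMask,
    band: str | None = None,
    n_perm: int = 5000,
    edge_alpha: float = 0.05,
    frac: float = 0.5,
    conf: float = 0.95,
    n_iter: int = 5000,
    seed: int | None = None,
) -> GroupStatResult:
    """Run all three statistical tiers for one band and pack the result."""
    t_map, p_unc = edgewise_ttest(groupA, groupB, mask)
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=3)
    p_corr = maxstat_correct(groupA, groupB, mask, n_perm=n_perm, seed=int(sub[0]))
    clusters = nbs_cluster_test(
        groupA, groupB, mask, edge_alpha=edge_alpha, n_perm=n_perm, seed=int(sub[1])
    )
    ci = subsample_sign_consistency(
        groupA, groupB, mask, frac=frac, n_iter=n_iter, conf=conf, seed=int(sub[2])
    )
    iu = np.triu_indices(mask.n_nodes, k=1)
    sig = (p_unc[iu] < 0.05) & ~np.isnan(p_unc[iu])
    return GroupStatResult(
        band=band or groupA[0].band,
        t_map=t_map,
        p_unc=p_unc,
        p_corr=p_corr,
        clusters=clusters,
        ci_edges=ci,
        n_pos=int((sig & (t_map[iu] > 0)).sum()),
        n_neg=int((sig & (t_map[iu] < 0)).sum()),
        params={
            "n_perm": n_perm,
            "edge_alpha": edge_alpha,
            "frac": frac,
            "conf": conf,
            "n_iter": n_iter,
            "seed": seed,
        },
    )
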