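"""Beta-diversity and richness analytics on feature-by-sample count tables.

Covers the exploratory statistics usually run on annotated metagenome
counts: depth normalization, relative-abundance filtering, analytic
rarefaction, Bray-Curtis dissimilarity, principal coordinates analysis,
UPGMA clustering and one-way PERMANOVA.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

__all__ = [
    "CountTable",
    "OrdinationResult",
    "PermanovaResult",
    "RarefactionCurve",
    "normalize_depth",
    "rarefy_counts",
    "relative_abundance",
    "abundance_filter",
    "rarefaction_curve",
    "bray_curtis_matrix",
    "pcoa",
    "upgma",
    "tree_to_newick",
    "permanova",
]

# Sequencing depth the source study normalized to.
DEFAULT_NORMALIZATION_DEPTH = 221_168


@dataclass
class CountTable:
    """Features x samples abundance matrix with per-sample group labels.

    ``counts`` is a pandas DataFrame indexed by feature id with sample-id
    columns; ``groups`` maps sample id -> group label (e.g. thrombolite /
    sediment).  Raw tables hold non-negative integers; normalized tables may
    hold non-negative reals.
    """

    counts: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.groups = {s: self.groups[s] for s in self.counts.columns}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    def group_array(self) -> np.ndarray:
        return np.array([self.groups[s] for s in self.counts.columns])


def _check_sample_totals(counts: pd.DataFrame) -> pd.Series:
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    return totals


def normalize_depth(
    table: CountTable, depth: int = DEFAULT_NORMALIZATION_DEPTH
) -> CountTable:
    """Scale every sample to a common sequencing depth (total-sum scaling).

    Deterministic alternative to random subsampling: each column is
    multiplied by depth/total so all column sums equal ``depth``.
    """
    totals = _check_sample_totals(table.counts)
    scaled = table.counts * (depth / totals)
    return CountTable(counts=scaled, groups=dict(table.groups))


def rarefy_counts(table: CountTable, depth: int, seed: int) -> CountTable:
    """Randomly subsample each sample to ``depth`` reads without replacement."""
    totals = _check_sample_totals(table.counts)
    if (totals < depth).any():
        small = list(totals[totals < depth].index)
        raise ValueError(f"depth {depth} exceeds total counts of sample(s) {small}")
    rng = np.random.default_rng(seed)
    out = {}
    for s in table.counts.columns:
        col = table.counts[s].to_numpy()
        drawn = rng.multivariate_hypergeometric(col.astype(np.int64), depth)
        out[s] = drawn
    df = pd.DataFrame(out, index=table.counts.index)
    return CountTable(counts=df, groups=dict(table.groups))


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample proportions (columns sum to one)."""
    totals = _check_sample_totals(table.counts)
    return table.counts / totals


def abundance_filter(
    proportions: pd.DataFrame, min_frac: float = 0.005, how: str = "mean"
) -> pd.DataFrame:
    """Keep features whose mean (or max) proportion strictly exceeds ``min_frac``.

    The strict inequality reproduces the usual "only taxa >0.5% shown"
    convention: a feature at exactly the threshold is dropped.
    """
    if how == "mean":
        stat = proportions.mean(axis=1)
    elif how == "max":
        stat = proportions.max(axis=1)
    else:
        raise ValueError(f"how must be 'mean' or 'max', got {how!r}")
    return proportions.loc[stat > min_frac]


@dataclass(frozen=True)
class RarefactionCurve:
    depths: np.ndarray
    expected_richness: pd.DataFrame  # depth x sample


def _expected_richness(counts: np.ndarray, depth: int) -> float:
    # E[S_n] = sum_i 1 - C(N - N_i, n)/C(N, n), hypergeometric expectation
    counts = counts[counts > 0]
    n_total = counts.sum()
    if depth > n_total:
        raise ValueError(f"subsample depth {depth} exceeds sample total {n_total}")
    # log C(N - Ni, n) - log C(N, n), with C(m, n) = 0 when m < n
    log_cn = _log_comb(n_total, depth)
    m = n_total - counts
    p_absent = np.where(m >= depth, np.exp(_log_comb(m, depth) - log_cn), 0.0)
    return float(np.sum(1.0 - p_absent))


def _log_comb(m, n):
    m = np.asarray(m, dtype=float)
    return gammaln(m + 1) - gammaln(n + 1) - gammaln(m - n + 1)


def rarefaction_curve(table: CountTable, depths: Sequence[int]) -> RarefactionCurve:
    """Analytic rarefaction: expected observed features per subsample depth.

    Uses the closed-form hypergeometric expectation rather than Monte-Carlo
    subsampling; at full depth the expectation equals observed richness.
    """
    depths = np.asarray(sorted(depths), dtype=np.int64)
    if (depths < 1).any():
        raise ValueError("depths must be >= 1")
    data = {
        s: [_expected_richness(table.counts[s].to_numpy(), int(d)) for d in depths]
        for s in table.counts.columns
    }
    return RarefactionCurve(
        depths=depths, expected_richness=pd.DataFrame(data, index=depths)
    )


def bray_curtis_matrix(table: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between samples.

    BC(u, v) = sum|u_i - v_i| / sum(u_i + v_i); 0 for identical samples, 1
    for samples with disjoint feature support.
    """
    counts = table.counts if isinstance(table, CountTable) else table
    _check_sample_totals(counts)
    mat = squareform(pdist(counts.to_numpy().T, metric="braycurtis"))
    return pd.DataFrame(mat, index=counts.columns, columns=counts.columns)


def _validate_distance_matrix(d: pd.DataFrame) -> np.ndarray:
    a = d.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(a), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return a


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives retained)
    proportion_explained: np.ndarray  # per retained axis, over positive eigenvalues


def pcoa(d: pd.DataFrame, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Gower double-centering of -d**2/2 followed by eigendecomposition;
    coordinates are eigenvectors scaled by sqrt(eigenvalue).  Axes are
    restricted to positive eigenvalues; negative eigenvalues (possible for
    semimetric inputs such as Bray-Curtis) are retained in ``eigenvalues``
    for inspection, and variance proportions are taken over the positive
    eigenvalues only.
    """
    a = _validate_distance_matrix(d)
    n = a.shape[0]
    b = -0.5 * a**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    g = centerer @ b @ centerer
    evals, evecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(1.0, float(np.abs(evals).max()))
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    prop = evals[pos] / evals[pos].sum()
    if n_axes is not None:
        coords = coords[:, :n_axes]
        prop = prop[:n_axes]
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=d.index, columns=axes),
        eigenvalues=evals,
        proportion_explained=prop,
    )


@dataclass
class _Node:
    name: str | None
    height: float
    children: list

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        return [leaf for c in self.children for leaf in c.leaves()]


def upgma(d: pd.DataFrame) -> "_Node":
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    Node heights are half the merge distance, so cophenetic distances on the
    resulting ultrametric tree equal the average-linkage merge distances.
    Ties are broken by the lexicographically smallest eligible index pair,
    making the tree deterministic.
    """
    a = _validate_distance_matrix(d)
    n = a.shape[0]
    if n < 2:
        raise ValueError("UPGMA requires at least two samples")
    nodes: dict[int, _Node] = {
        i: _Node(name=str(d.index[i]), height=0.0, children=[]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): a[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(nodes) > 1:
        (i, j), dij = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merged = _Node(name=None, height=dij / 2.0, children=[nodes[i], nodes[j]])
        ni, nj = sizes[i], sizes[j]
        del nodes[i], nodes[j]
        for k in list(nodes):
            key_ik = (min(i, k), max(i, k))
            key_jk = (min(j, k), max(j, k))
            d_new = (ni * dist.pop(key_ik) + nj * dist.pop(key_jk)) / (ni + nj)
            dist[(k, next_id)] = d_new
        del dist[(i, j)]
        nodes[next_id] = merged
        sizes[next_id] = ni + nj
        next_id += 1
    return next(iter(nodes.values()))


def tree_to_newick(node: "_Node") -> str:
    """Serialize a UPGMA tree to newick with branch lengths."""

    def fmt(n: _Node, parent_height: float) -> str:
        bl = parent_height - n.height
        if not n.children:
            return f"{n.name}:{bl:.10g}"
        inner = ",".join(fmt(c, n.height) for c in n.children)
        return f"({inner}):{bl:.10g}"

    if not node.children:
        return f"{node.name}:0;"
    inner = ",".join(fmt(c, node.height) for c in node.children)
    return f"({inner});"


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None


def _permanova_ss(a2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group labels."""
    n = a2.shape[0]
    ss_total = a2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = a2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def _pseudo_f(a2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    n = a2.shape[0]
    groups = np.unique(labels)
    a = len(groups)
    ss_total, ss_within = _permanova_ss(a2, labels)
    ss_between = ss_total - ss_within
    if ss_total <= 0:
        return 0.0, 0.0
    f = (ss_between / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else math.inf
    return f, ss_between / ss_total


def permanova(
    d: pd.DataFrame,
    groups: Mapping[str, str] | Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Partitions the squared-distance sum of squares between and within
    groups; significance by permuting group labels.  With random
    permutations p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so the
    smallest attainable p is 1/(n_perm + 1).  With ``exact=True`` all
    distinct label permutations are enumerated (small designs only) and
    p = #{F_perm >= F_obs}/n_total with the identity included.
    """
    a = _validate_distance_matrix(d)
    if isinstance(groups, Mapping):
        labels = np.array([groups[s] for s in d.index])
    else:
        labels = np.asarray(list(groups))
    if len(labels) != a.shape[0]:
        raise ValueError("label count does not match distance matrix size")
    if len(np.unique(labels)) < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a2 = a**2
    f_obs, r2 = _pseudo_f(a2, labels)
    if f_obs == 0.0 and r2 == 0.0 and a2.max() == 0:
        return PermanovaResult(0.0, 0.0, 1.0, n_perm, seed)

    if exact:
        perms = {tuple(p) for p in itertools.permutations(labels)}
        f_all = [_pseudo_f(a2, np.array(p))[0] for p in perms]
        count = sum(1 for f in f_all if f >= f_obs - 1e-12)
        return PermanovaResult(f_obs, r2, count / len(f_all), len(f_all), seed)

    n_distinct = math.factorial(len(labels))
    if n_perm > n_distinct:
        warnings.warn(
            f"n_perm={n_perm} exceeds the {n_distinct} distinct label orderings; "
            "p-value resolution is limited",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_perm, _ = _pseudo_f(a2, rng.permutation(labels))
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(f_obs, r2, p, n_perm, seed)
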