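"""Negative-binomial Wald differential abundance between two sample groups.

A deliberately transparent reimplementation of the count-based testing
framework popularized by RNA-seq tools: median-of-ratios size factors,
per-feature method-of-moments dispersion, maximum-likelihood group means
under a negative binomial with fixed dispersion, a Wald test on the log2
fold change, Benjamini-Hochberg correction, and the enrichment filters used
for metagenomic mat comparisons (padj < 0.05, |log2FC| > 1, baseMean > 2000).

Simplifications relative to the full framework: no empirical-Bayes
dispersion shrinkage, no fold-change shrinkage, no independent filtering,
no outlier handling.  Only the fields the downstream filters consume are
produced: baseMean, log2FC, its standard error, the Wald statistic, p and
adjusted p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ecology import CountTable

__all__ = [
    "size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "bh_adjust",
    "enrichment_filter",
    "differential_abundance",
]

DISPERSION_FLOOR = 1e-8
LN2 = math.log(2.0)


def size_factors(table: CountTable) -> pd.Series:
    """Median-of-ratios size factors, rescaled to unit geometric mean.

    For each feature positive in every sample, compute its geometric mean
    across samples; a sample's factor is the median over those features of
    count / geometric mean.  Features with any zero are excluded from the
    reference, as is conventional for sparse count tables.
    """
    k = table.counts.to_numpy(dtype=float)
    all_positive = (k > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has non-zero counts in every sample; a pseudo-reference "
            "(e.g. geometric mean over positive samples only) would be required"
        )
    logs = np.log(k[all_positive])
    log_geo = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geo, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))  # unit geometric mean
    return pd.Series(sf, index=table.counts.columns, name="size_factor")


def estimate_dispersions(table: CountTable, sf: pd.Series) -> pd.Series:
    """Per-feature NB dispersion alpha by method of moments on normalized counts.

    Within-group sample variances are pooled, and
    alpha = max((pooled_var - mean)/mean**2, floor) with the grand mean of
    normalized counts; Poisson-like or constant features land on the floor.
    """
    q = table.counts.to_numpy(dtype=float) / sf.to_numpy()
    labels = table.group_array()
    groups = np.unique(labels)
    n_j = np.array([(labels == g).sum() for g in groups])
    if (n_j < 2).any():
        raise ValueError("each group needs at least two samples to estimate dispersion")
    var_pool = np.zeros(q.shape[0])
    dof = 0
    for g, n in zip(groups, n_j):
        sub = q[:, labels == g]
        var_pool += sub.var(axis=1, ddof=1) * (n - 1)
        dof += n - 1
    var_pool /= dof
    mean = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_pool - mean) / mean**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=table.counts.index, name="dispersion")


def _fit_group_mean(
    k: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 50
) -> np.ndarray:
    """Vectorized ML estimate of mu per feature for counts K_j ~ NB(s_j*mu, alpha).

    Newton iteration on log(mu); the score is
    dl/dlog(mu) = sum_j (K_j - s_j*mu) / (1 + alpha*s_j*mu)
    and the expected information is
    I = sum_j s_j*mu / (1 + alpha*s_j*mu).
    Moment start mu0 = mean(K_j/s_j); features with all-zero counts stay 0.
    """
    mu = (k / s).mean(axis=1)
    nonzero = mu > 0
    log_mu = np.log(np.where(nonzero, mu, 1.0))
    for _ in range(n_iter):
        m = np.exp(log_mu)[:, None] * s
        denom = 1.0 + alpha[:, None] * m
        score = ((k - m) / denom).sum(axis=1)
        info = (m / denom).sum(axis=1)
        step = np.where(nonzero & (info > 0), score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        log_mu = log_mu + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return np.where(nonzero, np.exp(log_mu), 0.0)


def _information(mu: np.ndarray, s: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    m = mu[:, None] * s
    denom = 1.0 + alpha[:, None] * m
    return (m / denom).sum(axis=1)


def nb_wald_test(
    table: CountTable,
    sf: pd.Series,
    dispersions: pd.Series,
    focal_group: str,
) -> pd.DataFrame:
    """Per-feature Wald test of focal vs other group mean.

    Group means are fit by NB maximum likelihood at fixed dispersion;
    log2FC = log2(mu_focal / mu_other) with a 0.5 pseudo-count applied to a
    group mean only when that group's counts are all zero.  The standard
    error of log2FC comes from the inverse observed (= expected, log link)
    information of each group mean, and p is the two-sided normal tail of
    wald = log2FC / se.  Features with zero counts in both groups are
    reported with log2FC = 0, p = 1.

    Returns a DataFrame with columns baseMean, log2fc, se, wald, p, padj,
    enriched_in (padj from BH over all tested features; ``enriched_in`` is
    'focal'/'other' at padj < 0.05, else 'none').
    """
    labels = table.group_array()
    groups = list(np.unique(labels))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    if focal_group not in groups:
        raise ValueError(f"focal group {focal_group!r} not among {groups}")
    other_group = [g for g in groups if g != focal_group][0]
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than two samples")

    k = table.counts.to_numpy(dtype=float)
    s = sf.loc[table.counts.columns].to_numpy()
    alpha = dispersions.loc[table.counts.index].to_numpy()

    base_mean = (k / s).mean(axis=1)

    idx_f = labels == focal_group
    idx_o = labels == other_group
    mu_f = _fit_group_mean(k[:, idx_f], s[idx_f], alpha)
    mu_o = _fit_group_mean(k[:, idx_o], s[idx_o], alpha)

    # 0.5 pseudo-count only where a group is entirely zero
    mu_f_adj = np.where(mu_f == 0, 0.5, mu_f)
    mu_o_adj = np.where(mu_o == 0, 0.5, mu_o)

    both_zero = (mu_f == 0) & (mu_o == 0)
    log2fc = np.where(both_zero, 0.0, np.log2(mu_f_adj / mu_o_adj))

    info_f = _information(mu_f_adj, s[idx_f], alpha)
    info_o = _information(mu_o_adj, s[idx_o], alpha)
    with np.errstate(divide="ignore"):
        var_log = 1.0 / info_f + 1.0 / info_o
    se = np.sqrt(var_log) / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.where(both_zero, 1.0, p)
    wald = np.where(both_zero, 0.0, wald)
    se = np.where(both_zero, np.nan, se)

    padj = bh_adjust(p)
    enriched = np.where(
        padj < 0.05, np.where(log2fc > 0, "focal", "other"), "none"
    )

    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald": wald,
            "p": p,
            "padj": padj,
            "enriched_in": enriched,
        },
        index=table.counts.index,
    )


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def enrichment_filter(
    records: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    min_base_mean: float = 2000.0,
) -> pd.DataFrame:
    """Keep features passing the stringent enrichment criteria.

    padj < alpha AND |log2FC| strictly > min_abs_log2fc AND baseMean
    strictly > min_base_mean; a feature at exactly a magnitude threshold is
    dropped.  The returned frame carries a ``direction`` column (focal /
    other by log2FC sign).
    """
    required = {"padj", "log2fc", "baseMean"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    keep = (
        (records["padj"] < alpha)
        & (records["log2fc"].abs() > min_abs_log2fc)
        & (records["baseMean"] > min_base_mean)
    )
    out = records.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "focal", "other")
    return out


def differential_abundance(
    table: CountTable,
    focal_group: str,
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    min_base_mean: float = 2000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full stage: size factors -> dispersions -> Wald test -> filter.

    Returns (all records, filtered records).
    """
    sf = size_factors(table)
    disp = estimate_dispersions(table, sf)
    records = nb_wald_test(table, sf, disp, focal_group)
    return records, enrichment_filter(records, alpha, min_abs_log2fc, min_base_mean)
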