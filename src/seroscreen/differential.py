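"""Label-free differential screening of log2 LFQ intensities.

The chain mirrors the standard proteomics workflow for low-replicate
label-free data: missing values (left-censored, low-abundance) are imputed
from a Gaussian shifted down from each sample's observed distribution;
group differences are tested with a two-sample Student t-statistic whose
null distribution is estimated by permuting group labels, yielding a
permutation-based false discovery rate in the SAM family; candidates must
clear both the FDR threshold and an absolute log2 fold-change threshold.
Row-wise z-scored hierarchical clustering and sample-space PCA support the
visual structure checks.

All matrices are proteins x samples pandas DataFrames on the log2 scale;
NaN marks a missing quantification.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import t as t_dist

__all__ = [
    "impute_downshift",
    "permutation_fdr_ttest",
    "select_candidates",
    "zscore_cluster",
    "pca",
    "ClusterResult",
    "PCAResult",
]


def impute_downshift(
    matrix: pd.DataFrame,
    width: float = 0.3,
    shift: float = 1.8,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Impute missing cells from a down-shifted normal distribution.

    For each sample (column) with observed mean ``m`` and SD ``s``,
    missing cells are drawn from ``Normal(m - shift*s, (width*s)^2)`` —
    the model appropriate for intensities missing because they fell below
    the detection limit.  Observed cells are never touched.

    Raises if any column has fewer than 2 observed values (its SD would be
    undefined).
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    n_obs = out.notna().sum(axis=0)
    bad = n_obs[n_obs < 2]
    if len(bad):
        raise ValueError(
            f"cannot impute: sample(s) {list(bad.index)} have fewer than 2 "
            "observed values"
        )
    for col in out.columns:
        vals = out[col]
        miss = vals.isna()
        if not miss.any():
            continue
        m, s = vals.mean(), vals.std(ddof=1)
        out.loc[miss, col] = rng.normal(m - shift * s, width * s, size=int(miss.sum()))
    return out


def _t_stats(
    data: np.ndarray, idx1: np.ndarray, idx2: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sample t per row; returns (t, difference)."""
    x1, x2 = data[:, idx1], data[:, idx2]
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    denom = sp * np.sqrt(1.0 / n1 + 1.0 / n2) + s0
    diff = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, 0.0)
    return t, diff


def _label_permutations(
    n1: int, n2: int, n_permutations: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Distinct assignments of n1 pooled columns to group 1.

    All of them when there are at most ``n_permutations``; otherwise a
    uniform random sample without replacement.
    """
    from math import comb

    total = comb(n1 + n2, n1)
    if total <= n_permutations:
        return [np.array(c) for c in combinations(range(n1 + n2), n1)]
    seen: set[tuple[int, ...]] = set()
    out: list[np.ndarray] = []
    while len(out) < n_permutations:
        perm = tuple(sorted(rng.choice(n1 + n2, size=n1, replace=False).tolist()))
        if perm not in seen:
            seen.add(perm)
            out.append(np.array(perm))
    return out


def permutation_fdr_ttest(
    matrix: pd.DataFrame,
    labels: pd.Series | Sequence[str],
    group1: str,
    group2: str,
    n_permutations: int = 250,
    seed: int = 0,
    s0: float = 0.0,
) -> pd.DataFrame:
    """Two-sample t-test with permutation-estimated FDR (SAM family).

    ``labels`` maps the matrix's sample columns to group names.  The
    difference is reported as ``mean(group2) - mean(group1)``.  The
    q-value of a protein is the median over label permutations of the
    number of null |t| values at least as large as its |t|, divided by the
    observed count of |t| values that large, clipped to [0, 1] and
    monotonized so that q never decreases as |t| decreases.

    Requires a complete (imputed) matrix and >= 2 samples per group.
    """
    labels = pd.Series(np.asarray(labels), index=matrix.columns) if not isinstance(
        labels, pd.Series
    ) else labels
    cols1 = [c for c in matrix.columns if labels[c] == group1]
    cols2 = [c for c in matrix.columns if labels[c] == group2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("both groups need at least 2 samples")
    data = matrix[cols1 + cols2].to_numpy(dtype=float)
    if np.isnan(data).any():
        raise ValueError("matrix contains missing values; impute first")

    n1, n2 = len(cols1), len(cols2)
    rng = np.random.default_rng(seed)
    idx1 = np.arange(n1)
    idx2 = np.arange(n1, n1 + n2)
    t_obs, diff = _t_stats(data, idx1, idx2, s0)
    abs_obs = np.abs(t_obs)

    pooled = np.arange(n1 + n2)
    perms = _label_permutations(n1, n2, n_permutations, rng)
    # per-permutation counts of null |t| >= each observed |t|
    order = np.argsort(abs_obs)  # ascending
    sorted_abs = abs_obs[order]
    null_counts = np.empty((len(perms), len(abs_obs)))
    for b, p1 in enumerate(perms):
        p2 = np.setdiff1d(pooled, p1, assume_unique=True)
        t_null, _ = _t_stats(data, p1, p2, s0)
        null_sorted = np.sort(np.abs(t_null))
        # count of null values >= threshold, for thresholds sorted_abs
        geq = len(null_sorted) - np.searchsorted(null_sorted, sorted_abs, side="left")
        null_counts[b, order] = geq

    obs_sorted = np.sort(abs_obs)
    obs_counts = len(abs_obs) - np.searchsorted(obs_sorted, abs_obs, side="left")
    med_null = np.median(null_counts, axis=0)
    q = np.clip(med_null / obs_counts, 0.0, 1.0)

    # monotonize: a protein can never have a smaller q than one with larger |t|
    desc = np.argsort(-abs_obs, kind="stable")
    q[desc] = np.maximum.accumulate(q[desc])

    df = n1 + n2 - 2
    p = 2.0 * t_dist.sf(abs_obs, df)
    return pd.DataFrame(
        {
            "protein_id": matrix.index,
            "difference": diff,
            "t_stat": t_obs,
            "p_value": np.clip(p, np.finfo(float).tiny, 1.0),
            "q_value": q,
        }
    ).set_index("protein_id")


def select_candidates(
    results: pd.DataFrame,
    fdr_threshold: float = 0.01,
    fc_threshold: float = 2.0,
) -> list[str]:
    """Candidates passing ``q < fdr_threshold`` and ``|difference| >
    fc_threshold`` (both tails)."""
    if results.empty:
        return []
    mask = (results["q_value"] < fdr_threshold) & (
        results["difference"].abs() > fc_threshold
    )
    return list(results.index[mask])


@dataclass
class ClusterResult:
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None
    dropped: list


def zscore_cluster(
    matrix: pd.DataFrame, selected_ids: Sequence[str] | None = None
) -> ClusterResult:
    """Hierarchical clustering of z-scored rows (Euclidean, average link).

    Each protein row is standardized to mean 0, SD 1 across samples.
    Constant rows (SD 0) are dropped with a warning.  Columns are
    clustered on the same z-scored submatrix.  Tie-breaks follow input
    order, so the result is deterministic.
    """
    sub = matrix.loc[list(selected_ids)] if selected_ids is not None else matrix
    sd = sub.std(axis=1, ddof=0)
    constant = list(sub.index[sd == 0])
    if constant:
        warnings.warn(f"dropping {len(constant)} constant row(s): z-score undefined")
        sub = sub.loc[sd > 0]
    if len(sub) < 2:
        raise ValueError("need at least 2 non-constant rows to cluster")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
    row_link = linkage(z.to_numpy(), method="average", metric="euclidean")
    col_link = None
    col_order = list(z.columns)
    if z.shape[1] >= 2:
        col_link = linkage(z.to_numpy().T, method="average", metric="euclidean")
        col_order = [z.columns[i] for i in leaves_list(col_link)]
    return ClusterResult(
        row_order=[z.index[i] for i in leaves_list(row_link)],
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
        dropped=constant,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray  # fractions, nonincreasing, sums to 1


def pca(matrix: pd.DataFrame) -> PCAResult:
    """Centred PCA of the samples (columns are observations).

    Returns per-sample scores and the fraction of variance along each
    component (nonincreasing, summing to 1 over all components).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples for PCA")
    X = matrix.to_numpy(dtype=float).T  # samples x proteins
    X = X - X.mean(axis=0, keepdims=True)
    if not np.any(X):
        raise ValueError("zero-variance data: PCA undefined")
    u, s, _vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    scores = u * s
    k = scores.shape[1]
    return PCAResult(
        scores=pd.DataFrame(
            scores,
            index=matrix.columns,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        variance_explained=var / var.sum(),
    )
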