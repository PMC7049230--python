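"""Nonparametric validation statistics for serological array data.

Autoantibody intensity distributions are heavy-tailed, so group
comparisons use the Mann-Whitney U test.  The reporting convention
matches classic biostatistics output: rank sums per group, U as
min(U1, U2), a normal-approximation Z whose sign follows group 1's rank
sum (without continuity correction), and a tie-corrected "Z adjusted".
Spearman rank correlations carry a t-statistic on N-2 degrees of freedom;
multi-group comparisons use the tie-corrected Kruskal-Wallis H; the
Shapiro-Wilk test documents the parametric/nonparametric routing
decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankTestResult",
    "CorrelationResult",
    "mann_whitney",
    "u_z_from_rank_sums",
    "spearman",
    "t_from_correlation",
    "kruskal_wallis",
    "normality_check",
    "rank_test_table",
    "spearman_table",
]


@dataclass
class RankTestResult:
    rank_sum_group1: float
    rank_sum_group2: float
    U: float  # min(U1, U2)
    z: float  # sign follows U1 - n1*n2/2
    z_adjusted: float
    p_value: float
    p_adjusted: float
    n1: int
    n2: int


@dataclass
class CorrelationResult:
    R: float
    N: int
    t: float
    p_value: float


def _tie_spectrum(pooled: np.ndarray) -> np.ndarray:
    _vals, counts = np.unique(pooled, return_counts=True)
    return counts[counts > 1]


def _z_pair(
    u1: float, n1: int, n2: int, tie_spectrum: np.ndarray | None
) -> tuple[float, float | None]:
    """Normal-approximation z from U1, untied and tie-corrected."""
    mean_u = n1 * n2 / 2.0
    var_untied = n1 * n2 * (n1 + n2 + 1) / 12.0
    z = (u1 - mean_u) / np.sqrt(var_untied)
    z_adj = None
    if tie_spectrum is not None:
        N = n1 + n2
        correction = 0.0
        if len(tie_spectrum):
            t = np.asarray(tie_spectrum, dtype=float)
            correction = float(np.sum(t**3 - t)) / (N * (N - 1))
        var_tied = n1 * n2 / 12.0 * ((N + 1) - correction)
        if var_tied <= 0:
            raise ValueError("all pooled values tied: rank variance is zero")
        z_adj = (u1 - mean_u) / np.sqrt(var_tied)
    return float(z), None if z_adj is None else float(z_adj)


def _two_sided_normal_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney U test with midranks and tie correction.

    ``x`` is group 1 (e.g. POAG), ``y`` group 2 (e.g. CTRL).  U is
    reported as min(U1, U2); z is computed from U1, so its sign says
    which direction group 1 shifted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical: rank variance is zero")
    ranks = stats.rankdata(pooled)  # midranks
    r1 = float(ranks[:n1].sum())
    r2 = float(ranks[n1:].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    ties = _tie_spectrum(pooled)
    z, z_adj = _z_pair(u1, n1, n2, ties)
    return RankTestResult(
        rank_sum_group1=r1,
        rank_sum_group2=r2,
        U=float(min(u1, u2)),
        z=z,
        z_adjusted=z_adj,
        p_value=_two_sided_normal_p(z),
        p_adjusted=_two_sided_normal_p(z_adj),
        n1=n1,
        n2=n2,
    )


def u_z_from_rank_sums(
    rank_sum1: float,
    n1: int,
    n2: int,
    tie_spectrum: Sequence[int] | None = None,
) -> tuple[float, float, float | None]:
    """Recover (U, z, z_adjusted) from group 1's rank sum alone.

    Useful when only published rank sums are available.  ``z_adjusted``
    is None unless a tie spectrum (sizes of tie groups in the pooled
    data) is supplied.
    """
    lo = n1 * (n1 + 1) / 2.0
    hi = n1 * n2 + lo
    if not lo <= rank_sum1 <= hi:
        raise ValueError(
            f"rank sum {rank_sum1} outside the feasible range [{lo}, {hi}] "
            f"for n1={n1}, n2={n2}"
        )
    u1 = rank_sum1 - lo
    u = min(u1, n1 * n2 - u1)
    z, z_adj = _z_pair(
        u1, n1, n2, None if tie_spectrum is None else np.asarray(tie_spectrum)
    )
    return float(u), z, z_adj


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with t-statistic on N-2 df.

    Pairs with a missing member are dropped (pairwise deletion, so the
    valid N varies by covariate).  rho is the Pearson correlation of
    midranks; ``t = R * sqrt((N-2)/(1-R^2))``, two-sided p from the t
    distribution.  |R| = 1 yields an infinite t and p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if abs(r) > 1.0 - 1e-12:  # exact monotone up to floating error
        return CorrelationResult(R=float(np.sign(r)), N=n, t=float(np.sign(r)) * np.inf, p_value=0.0)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(min(1.0, 2.0 * stats.t.sf(abs(t), n - 2)))
    return CorrelationResult(R=r, N=n, t=float(t), p_value=p)


def t_from_correlation(r: float, n: int) -> float:
    """t-statistic on n-2 df implied by a correlation coefficient.

    ``t = r * sqrt((n-2) / (1-r^2))`` — the arithmetic used to recompute
    published t values from printed (R, N) pairs.
    """
    if not -1.0 < r < 1.0:
        raise ValueError("|r| must be < 1 for a finite t")
    if n < 3:
        raise ValueError("need n >= 3")
    return float(r * np.sqrt((n - 2) / (1.0 - r * r)))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (g-1 df).

    For two groups use :func:`mann_whitney` instead.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups (use mann_whitney for 2)")
    clean = [np.asarray(g, dtype=float) for g in groups]
    clean = [g[~np.isnan(g)] for g in clean]
    if any(len(g) < 2 for g in clean):
        raise ValueError("each group needs at least 2 values")
    h, p = stats.kruskal(*clean)
    return float(h), float(p)


def normality_check(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p; requires 3 <= n <= 5000."""
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if not 3 <= len(vals) <= 5000:
        raise ValueError("Shapiro-Wilk supported for 3 <= n <= 5000")
    w, p = stats.shapiro(vals)
    return float(w), float(p)


def rank_test_table(
    nfi: pd.DataFrame,
    cohort: pd.DataFrame,
    group1: str = "POAG",
    group2: str = "CTRL",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-target Mann-Whitney results, one row per NFI column.

    Columns mirror a classic validation report: rank sums, U, Z, p,
    tie-adjusted Z and its p.  ``adjust="bh"`` optionally adds
    Benjamini-Hochberg-corrected p-values (off by default: raw p-values
    are reported across the small validation panel).
    """
    labels = cohort.set_index("sample_id")["group"].reindex(nfi.index)
    rows = []
    for target in nfi.columns:
        x = nfi.loc[labels == group1, target]
        y = nfi.loc[labels == group2, target]
        res = mann_whitney(x, y)
        rows.append(
            {
                "target": target,
                f"rank_sum_{group1.lower()}": res.rank_sum_group1,
                f"rank_sum_{group2.lower()}": res.rank_sum_group2,
                "U": res.U,
                "Z": res.z,
                "p_value": res.p_value,
                "Z_adjusted": res.z_adjusted,
                "p_adjusted": res.p_adjusted,
            }
        )
    out = pd.DataFrame(rows)
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p_adjusted"], method="fdr_bh")[1]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def spearman_table(
    nfi: pd.DataFrame,
    cohort: pd.DataFrame,
    parameters: Sequence[str],
    group: str | None = "POAG",
) -> pd.DataFrame:
    """Spearman correlations of each target's NFI with clinical
    parameters, by default within the patient group only."""
    meta = cohort.set_index("sample_id").reindex(nfi.index)
    if group is not None:
        keep = meta["group"] == group
        nfi = nfi.loc[keep]
        meta = meta.loc[keep]
    rows = []
    for param in parameters:
        for target in nfi.columns:
            res = spearman(nfi[target], meta[param])
            rows.append(
                {
                    "parameter": param,
                    "target": target,
                    "valid_n": res.N,
                    "spearman_r": res.R,
                    "t": res.t,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(rows)
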