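"""Antigen-microarray pre-processing: spot records -> normalized matrix.

The chain, in fixed order:

1. ``net_signal`` — foreground minus local background; strictly negative
   nets become missing.
2. ``subtract_negative_control`` — the mean net PBS (buffer-only) signal
   of the serum's subarray is subtracted from every antigen and IgG spot,
   removing unspecific binding of the secondary detection antibody;
   results below zero become missing.
3. ``average_replicates`` — triplicate spots collapse to one mean
   fluorescence intensity per (sample, target), missing-aware.
4. ``igg_median_centring`` — each subarray's intensities are divided by
   (its IgG-control median / the global IgG median), aligning the
   positive-control level across subarrays and removing per-subarray
   batch scale.  Output: the normalized fluorescence intensity (NFI)
   matrix, samples x targets.
5. ``winsorize_to_missing`` — per target, values outside the 5th-95th
   percentile band become missing (outliers are removed, not clamped).
6. ``missingness_filter`` — targets with strictly more than 25% missing
   values are dropped from analysis.
7. ``knn_impute`` — remaining missing cells are filled from the k nearest
   target columns.

Spot tables are long-format DataFrames with columns ``sample_id, slide,
subarray, block, row, column, target, role, replicate, foreground,
background, flag`` (see ``seroscreen.io.SPOT_COLUMNS``); roles are
``antigen``, ``igg_control`` and ``negative_control``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "net_signal",
    "subtract_negative_control",
    "average_replicates",
    "igg_median_centring",
    "winsorize_to_missing",
    "missingness_filter",
    "knn_impute",
    "preprocess_pipeline",
    "NFIMatrix",
]

IGG_ROLE = "igg_control"
NEG_ROLE = "negative_control"


def drop_flagged(spots: pd.DataFrame, good_flag: str = "ok") -> pd.DataFrame:
    """Remove manually flagged poor-quality spots."""
    if "flag" not in spots.columns:
        return spots.copy()
    return spots[spots["flag"] == good_flag].copy()


def net_signal(spots: pd.DataFrame) -> pd.DataFrame:
    """Foreground minus local background; strictly negative -> missing.

    A net of exactly 0 is kept: only signals *reaching* negative values
    are treated as missing.
    """
    out = spots.copy()
    net = out["foreground"].astype(float) - out["background"].astype(float)
    out["net"] = net.where(net >= 0)
    return out


def subtract_negative_control(
    spots: pd.DataFrame, scope: str = "subarray"
) -> pd.DataFrame:
    """Subtract the mean net negative-control signal from every antigen
    and IgG spot; results below 0 become missing.

    ``scope`` selects the unit over which the control mean is taken:
    ``"subarray"`` (default — unspecific secondary binding is
    serum-specific, and each serum occupies one subarray) or ``"slide"``.
    """
    if "net" not in spots.columns:
        raise ValueError("net signals not computed; run net_signal first")
    if scope not in ("subarray", "slide"):
        raise ValueError(f"unknown scope {scope!r}")
    keys = ["slide", "subarray"] if scope == "subarray" else ["slide"]
    out = spots.copy()
    neg = out[out["role"] == NEG_ROLE]
    means = neg.groupby(keys)["net"].mean()
    units = {
        tuple(int(v) for v in u) for u in out[keys].drop_duplicates().to_numpy()
    }
    have = (
        {tuple(int(v) for v in u) for u in means.index}
        if len(keys) > 1
        else {(int(i),) for i in means.index}
    )
    missing_units = units - have
    if missing_units:
        raise ValueError(
            f"no negative-control spots in {scope}(s): {sorted(missing_units)}"
        )
    offsets = out[keys].apply(tuple, axis=1).map(
        means if len(keys) > 1 else {(i,): v for i, v in means.items()}
    )
    adj = out["net"] - offsets
    mask = out["role"] != NEG_ROLE
    out.loc[mask, "net"] = adj.where(adj >= 0)[mask]
    return out


def average_replicates(spots: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate spots to one mean intensity per (sample, target).

    The mean is over nonmissing replicates; if all replicates of a spot
    group are missing, the mean is missing.  Returns a long table with
    columns ``sample_id, slide, subarray, target, role, intensity``.
    """
    if "net" not in spots.columns:
        raise ValueError("net signals not computed; run net_signal first")
    grouped = (
        spots.groupby(["sample_id", "slide", "subarray", "target", "role"], sort=False)[
            "net"
        ]
        .mean()
        .reset_index()
        .rename(columns={"net": "intensity"})
    )
    return grouped


@dataclass
class NFIMatrix:
    """Samples x targets normalized fluorescence intensities.

    ``values`` holds the matrix (NaN = missing); ``factors`` the
    per-subarray normalization factor applied; ``audit`` per-stage record
    counts accumulated by the pipeline.
    """

    values: pd.DataFrame
    factors: pd.Series
    audit: list = field(default_factory=list)


def igg_median_centring(averaged: pd.DataFrame) -> NFIMatrix:
    """Median-centre each subarray to its IgG positive-control spots.

    The normalization factor of subarray s is ``median(IgG_s) /
    median(all IgG)``; every intensity of s is divided by it, so that
    afterwards every subarray's IgG median equals the global IgG median.
    """
    igg = averaged[averaged["role"] == IGG_ROLE]
    per_sample = igg.groupby("sample_id")["intensity"].median()
    missing = set(averaged["sample_id"].unique()) - set(per_sample.dropna().index)
    if missing:
        raise ValueError(f"sample(s) without observed IgG control: {sorted(missing)}")
    if (per_sample <= 0).any():
        bad = list(per_sample.index[per_sample <= 0])
        raise ValueError(f"nonpositive IgG median for sample(s): {bad}")
    global_median = float(per_sample.median())
    factors = per_sample / global_median

    antigens = averaged[averaged["role"] == "antigen"]
    wide = antigens.pivot(index="sample_id", columns="target", values="intensity")
    wide = wide.div(factors.reindex(wide.index), axis=0)
    wide.columns.name = None
    return NFIMatrix(values=wide, factors=factors)


def winsorize_to_missing(
    matrix: pd.DataFrame, lower_pct: float = 5.0, upper_pct: float = 95.0
) -> pd.DataFrame:
    """Per target, set values strictly outside the [lower, upper]
    percentile band to missing (linear-interpolation quantiles)."""
    out = matrix.copy()
    for col in out.columns:
        vals = out[col]
        if vals.notna().sum() == 0:
            continue
        lo = vals.quantile(lower_pct / 100.0, interpolation="linear")
        hi = vals.quantile(upper_pct / 100.0, interpolation="linear")
        out[col] = vals.where((vals >= lo) & (vals <= hi))
    return out


def missingness_filter(matrix: pd.DataFrame, max_missing: float = 0.25) -> pd.DataFrame:
    """Drop targets whose missing fraction is strictly above the cap."""
    frac = matrix.isna().mean(axis=0)
    return matrix.loc[:, frac <= max_missing].copy()


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing cells from the k nearest target columns.

    Distance between two targets is the mean squared difference over
    co-observed samples (fair across differing co-observation counts).
    A missing cell of target j at sample i is filled with the unweighted
    average of the neighbours' values at i, each rescaled by the ratio of
    the two columns' means over their co-observed samples — the right
    adjustment for positive fluorescence intensities, and exact when a
    neighbour duplicates the target.  (If a pair mean is nonpositive the
    rescaling falls back to an additive mean offset.)

    Columns with fewer than k usable neighbours fall back to all
    available; a cell with no observed neighbour value raises.
    Observed cells are never altered.
    """
    out = matrix.copy()
    X = out.to_numpy(dtype=float)
    n, m = X.shape
    obs = ~np.isnan(X)

    # pairwise distances and co-observed column means
    dist = np.full((m, m), np.inf)
    pair_mean = np.full((m, m), np.nan)  # pair_mean[j, l]: mean of col j on co(j,l)
    for j in range(m):
        for l in range(j + 1, m):
            co = obs[:, j] & obs[:, l]
            if co.sum() >= 2:
                d = X[co, j] - X[co, l]
                dist[j, l] = dist[l, j] = float(np.mean(d * d))
                pair_mean[j, l] = float(X[co, j].mean())
                pair_mean[l, j] = float(X[co, l].mean())

    for j in range(m):
        rows = np.where(~obs[:, j])[0]
        if rows.size == 0:
            continue
        order = np.argsort(dist[j])
        neighbours = [l for l in order if np.isfinite(dist[j, l]) and l != j]
        if not neighbours:
            raise ValueError(
                f"no neighbour shares observations with target {out.columns[j]!r}"
            )
        for i in rows:
            avail = [l for l in neighbours if obs[i, l]][:k]
            if not avail:
                raise ValueError(
                    f"no neighbour observed at sample {out.index[i]!r} for "
                    f"target {out.columns[j]!r}"
                )
            vals = []
            for l in avail:
                mj, ml = pair_mean[j, l], pair_mean[l, j]
                if ml > 0 and mj > 0:
                    vals.append(X[i, l] * mj / ml)
                else:
                    vals.append(X[i, l] - ml + mj)
            X[i, j] = float(np.mean(vals))
    return pd.DataFrame(X, index=out.index, columns=out.columns)


def preprocess_pipeline(
    spots: pd.DataFrame,
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
    max_missing: float = 0.25,
    k: int = 10,
    negctrl_scope: str = "subarray",
) -> NFIMatrix:
    """Run the full chain and record per-stage counts.

    Returns an :class:`NFIMatrix` whose ``audit`` lists, per stage, the
    number of usable records (spots, then matrix cells) after the stage.
    """
    audit: list[tuple[str, int]] = [("input_spots", len(spots))]
    spots = drop_flagged(spots)
    audit.append(("after_flag_removal", len(spots)))
    spots = net_signal(spots)
    audit.append(("nonmissing_net", int(spots["net"].notna().sum())))
    spots = subtract_negative_control(spots, scope=negctrl_scope)
    audit.append(("nonmissing_after_negctrl", int(spots["net"].notna().sum())))
    averaged = average_replicates(spots)
    audit.append(("averaged_records", int(averaged["intensity"].notna().sum())))
    nfi = igg_median_centring(averaged)
    audit.append(("nfi_cells_observed", int(nfi.values.notna().sum().sum())))
    values = winsorize_to_missing(nfi.values, lower_pct, upper_pct)
    audit.append(("after_winsorization", int(values.notna().sum().sum())))
    values = missingness_filter(values, max_missing)
    audit.append(("targets_retained", values.shape[1]))
    values = knn_impute(values, k=k)
    audit.append(("imputed_cells", int(values.notna().sum().sum())))
    return NFIMatrix(values=values, factors=nfi.factors, audit=audit)
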