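"""Identification-level filtering of IP-MS protein tables and iBAQ summaries.

The screening logic nominates candidate autoantigens from an
immunoprecipitation experiment: decoy/contaminant rows are dropped, a
protein must be quantified in every replicate of at least one serum x
lysate group ("reproducibly identified"), and anything that also shows up
in bead-only negative controls or lysate-free mock controls is discarded
as background binding.  iBAQ intensities, which are proportional to molar
amount, are summarized per group as percent of the group total.

"Identified" means a nonmissing, nonzero LFQ intensity; MaxQuant writes 0
for not-quantified, so 0 and absent both count as missing.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MAXQUANT_COLUMNS

__all__ = [
    "qc_flag_filter",
    "replicate_presence_filter",
    "control_exclusion_filter",
    "group_antigen_list",
    "ibaq_fractions",
    "filter_pipeline",
    "lfq_matrix",
    "ibaq_matrix",
]

_FLAG_KEYS = ("reverse", "contaminant", "only_by_site")


def _columns(columns: Mapping[str, str] | None) -> dict[str, str]:
    return dict(MAXQUANT_COLUMNS, **(columns or {}))


def _intensity(table: pd.DataFrame, prefix: str) -> pd.DataFrame:
    """Per-sample intensity block, indexed by protein id; 0 -> NaN."""
    cols = [c for c in table.columns if c.startswith(prefix)]
    mat = table[cols].copy()
    mat.columns = [c[len(prefix):] for c in cols]
    mat.index = table[MAXQUANT_COLUMNS["protein_id"]].to_numpy()
    return mat.replace(0, np.nan).astype(float)


def lfq_matrix(table: pd.DataFrame, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    return _intensity(table, _columns(columns)["lfq_prefix"])


def ibaq_matrix(table: pd.DataFrame, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    return _intensity(table, _columns(columns)["ibaq_prefix"])


def _flag_set(series: pd.Series) -> pd.Series:
    """MaxQuant marks flags with '+'; accept booleans and 0/1 too."""
    return series.map(
        lambda v: v is True or v == 1 or (isinstance(v, str) and v.strip() == "+")
    )


def qc_flag_filter(
    table: pd.DataFrame, columns: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Drop reverse (decoy) hits, potential contaminants and
    only-identified-by-site rows.  Row order is preserved.

    Flag columns absent from the table are treated as all-unset, with a
    warning.
    """
    cols = _columns(columns)
    keep = pd.Series(True, index=table.index)
    for key in _FLAG_KEYS:
        name = cols[key]
        if name not in table.columns:
            warnings.warn(f"flag column {name!r} absent; treating as unset")
            continue
        keep &= ~_flag_set(table[name]).fillna(False)
    return table.loc[keep]


def _group_samples(design: pd.DataFrame, exclude_controls: bool) -> dict[str, list[str]]:
    sub = design[~design["is_control"]] if exclude_controls else design
    groups = {
        g: list(d["sample_id"]) for g, d in sub.groupby("group_id", sort=False)
    }
    if any(len(s) == 0 for s in groups.values()):
        raise ValueError("group with zero replicates in the design")
    return groups


def replicate_presence_filter(
    table: pd.DataFrame,
    design: pd.DataFrame,
    columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Keep proteins quantified in *every* replicate of at least one
    non-control group."""
    lfq = lfq_matrix(table, columns)
    keep = pd.Series(False, index=lfq.index)
    for _g, samples in _group_samples(design, exclude_controls=True).items():
        keep |= lfq[samples].notna().all(axis=1)
    return table.loc[keep.to_numpy()]


def control_exclusion_filter(
    table: pd.DataFrame,
    design: pd.DataFrame,
    columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Remove proteins detected in any negative/mock-control sample."""
    lfq = lfq_matrix(table, columns)
    control_samples = list(design.loc[design["is_control"], "sample_id"])
    if not control_samples:
        return table
    present = lfq[control_samples].notna().any(axis=1)
    return table.loc[~present.to_numpy()]


def group_antigen_list(
    table: pd.DataFrame,
    design: pd.DataFrame,
    group_id: str,
    columns: Mapping[str, str] | None = None,
) -> list[str]:
    """Proteins completely quantified in all replicates of ``group_id``,
    sorted by descending mean LFQ intensity (ties broken by accession)."""
    samples = list(design.loc[design["group_id"] == group_id, "sample_id"])
    if not samples:
        raise ValueError(f"unknown group: {group_id!r}")
    lfq = lfq_matrix(table, columns)[samples]
    complete = lfq.notna().all(axis=1)
    means = lfq.loc[complete].mean(axis=1)
    order = sorted(means.index, key=lambda pid: (-means[pid], pid))
    return order


def ibaq_fractions(
    table: pd.DataFrame,
    design: pd.DataFrame,
    group_id: str,
    columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Relative molar abundance per antigen of a group, as percent.

    For each protein of the group (complete LFQ quantification in all of
    the group's replicates), the mean iBAQ over the group's replicates is
    taken (ignoring missing replicates) and expressed as percent of the
    summed means.  Fractions sum to 100.
    """
    proteins = group_antigen_list(table, design, group_id, columns)
    samples = list(design.loc[design["group_id"] == group_id, "sample_id"])
    ibaq = ibaq_matrix(table, columns).loc[proteins, samples]
    means = ibaq.mean(axis=1)
    total = means.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError(f"group {group_id!r} has no positive iBAQ intensities")
    out = pd.DataFrame(
        {"protein_id": means.index, "ibaq_fraction": 100.0 * means.to_numpy() / total}
    )
    return out.sort_values("ibaq_fraction", ascending=False, kind="stable").reset_index(
        drop=True
    )


def filter_pipeline(
    table: pd.DataFrame,
    design: pd.DataFrame,
    columns: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Canonical filter order: QC flags -> replicate presence -> control
    exclusion.  Returns the filtered table and a per-stage audit."""
    stages: list[tuple[str, int]] = [("input", len(table))]
    table = qc_flag_filter(table, columns)
    stages.append(("qc_flag_filter", len(table)))
    table = replicate_presence_filter(table, design, columns)
    stages.append(("replicate_presence_filter", len(table)))
    table = control_exclusion_filter(table, design, columns)
    stages.append(("control_exclusion_filter", len(table)))
    audit = pd.DataFrame(stages, columns=["stage", "n_proteins"])
    return table, audit
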