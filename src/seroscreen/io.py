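"""Readers and writers for the pipeline's text formats.

Two dialects are supported out of the box:

* MaxQuant-style ``proteinGroups.txt`` tables (tab-separated; per-sample
  ``LFQ intensity <sample>`` and ``iBAQ <sample>`` columns; ``+`` marks in
  the ``Reverse`` / ``Potential contaminant`` / ``Only identified by site``
  flag columns; 0 means "not quantified").
* GenePix/ImaGene-like spot exports: an ``ATF``-style ``Key=Value`` header
  block followed by one tab-separated row per spot.

Column names are configurable through a mapping so other software dialects
can be parsed without code changes.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

#: canonical -> MaxQuant proteinGroups column names
MAXQUANT_COLUMNS: dict[str, str] = {
    "protein_id": "Majority protein IDs",
    "entry_name": "Entry name",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "only_by_site": "Only identified by site",
    "lfq_prefix": "LFQ intensity ",
    "ibaq_prefix": "iBAQ ",
}

SPOT_COLUMNS = [
    "sample_id",
    "slide",
    "subarray",
    "block",
    "row",
    "column",
    "target",
    "role",
    "replicate",
    "foreground",
    "background",
    "flag",
]


def write_protein_groups(table: pd.DataFrame, path: str | Path) -> None:
    """Write a quantification table as MaxQuant-dialect TSV.

    Missing intensities are written as 0, the convention downstream
    readers map back to "not quantified".
    """
    out = table.copy()
    value_cols = [
        c
        for c in out.columns
        if c.startswith(MAXQUANT_COLUMNS["lfq_prefix"])
        or c.startswith(MAXQUANT_COLUMNS["ibaq_prefix"])
    ]
    out[value_cols] = out[value_cols].fillna(0.0)
    out.to_csv(path, sep="\t", index=False)


def read_protein_groups(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a proteinGroups-style TSV; zero intensities become NaN."""
    columns = dict(MAXQUANT_COLUMNS, **(columns or {}))
    table = pd.read_csv(path, sep="\t")
    value_cols = [
        c
        for c in table.columns
        if c.startswith(columns["lfq_prefix"]) or c.startswith(columns["ibaq_prefix"])
    ]
    table[value_cols] = table[value_cols].replace(0, np.nan)
    return table


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_spot_table(spots: pd.DataFrame, path: str | Path, **header: object) -> None:
    """Write a spot table with a GPR-like ``Key=Value`` header block."""
    path = Path(path)
    meta = {"Type": "seroscreen spot export", **header}
    with path.open("w") as fh:
        fh.write("ATF\t1.0\n")
        fh.write(f"{len(meta)}\t{spots.shape[1]}\n")
        for key, val in meta.items():
            fh.write(f'"{key}={val}"\n')
        spots.to_csv(fh, sep="\t", index=False)


def read_spot_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a GPR-like spot table, skipping the header block."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("ATF"):
            fh.seek(0)
            n_header = 0
        else:
            counts = fh.readline().split("\t")
            n_header = int(counts[0])
            for _ in range(n_header):
                fh.readline()
        spots = pd.read_csv(fh, sep="\t")
    if columns:
        spots = spots.rename(columns={v: k for k, v in columns.items()})
    return spots


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label="sample_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(config: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def config_hash(config: Mapping) -> str:
    """Stable short hash of a config mapping, for provenance records."""
    canonical = yaml.safe_dump(dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
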