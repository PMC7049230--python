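import pandas as pd
import pytest

from seroscreen import msfilter, synthetic
from seroscreen.io import MAXQUANT_COLUMNS


@pytest.fixture(scope="session")
def ms_dataset():
    """Default-scale IP-MS simulation (157 proteins, 8-group design)."""
    cfg = synthetic.MsSimConfig(seed=11)
    return synthetic.generate_ms_dataset(cfg)


@pytest.fixture(scope="session")
def array_dataset():
    """Small microarray simulation: 4 slides, 32 POAG vs 32 CTRL."""
    cfg = synthetic.ArraySimConfig(n_slides=4, cohort_sizes=(32, 32), seed=5)
    return synthetic.generate_array_dataset(cfg)


@pytest.fixture(scope="session")
def panel_quant_table():
    """Quant table reconstructed from the bundled 66-antigen reference
    panel: complete LFQ in the three CH replicates, iBAQ equal to the
    published percent values."""
    ref = pd.read_csv(
        __import__("importlib.resources", fromlist=["files"])
        .files("seroscreen.data")
        .joinpath("ch_antigen_abundance.tsv"),
        sep="\t",
    )
    n = len(ref)
    cols = {
        MAXQUANT_COLUMNS["protein_id"]: ref["accession"],
        MAXQUANT_COLUMNS["entry_name"]: ref["entry_name"],
        MAXQUANT_COLUMNS["reverse"]: [""] * n,
        MAXQUANT_COLUMNS["contaminant"]: [""] * n,
        MAXQUANT_COLUMNS["only_by_site"]: [""] * n,
    }
    for rep in (1, 2, 3):
        cols[f"{MAXQUANT_COLUMNS['lfq_prefix']}CH_{rep}"] = 1e6 * ref["ibaq_pct"]
        cols[f"{MAXQUANT_COLUMNS['ibaq_prefix']}CH_{rep}"] = ref["ibaq_pct"]
    table = pd.DataFrame(cols)
    design = pd.DataFrame(
        {
            "sample_id": ["CH_1", "CH_2", "CH_3"],
            "group_id": ["CH"] * 3,
            "replicate_index": [1, 2, 3],
            "igg_source": ["CTRL"] * 3,
            "protein_source": ["HTM"] * 3,
            "is_control": [False] * 3,
        }
    )
    return table, design


def lfq_missing_mask(table):
    return msfilter.lfq_matrix(table).isna()
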