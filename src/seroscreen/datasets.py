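"""Bundled reference tables from the POAG autoantibody screening study.

These are the published *summary* tables of a serological biomarker study
in primary open-angle glaucoma (POAG): the natural-autoantigen panel
captured from healthy trabecular-meshwork cells with its iBAQ relative
abundances, the Mann-Whitney rank sums of the 120-vs-120 microarray
validation, the Spearman correlations of autoantibody levels with clinical
covariates, and the 21 candidate biomarkers nominated by the label-free
differential screen.  The underlying raw spectra and spot intensities were
never deposited; these printed summaries are the only quantitative anchor
available, and they are what the worked examples and the acceptance checks
recompute from.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_ch_antigen_abundance",
    "load_validation_rank_sums",
    "load_clinical_spearman",
    "load_candidate_biomarkers",
]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("seroscreen.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_ch_antigen_abundance() -> pd.DataFrame:
    """66 autoantigens captured from healthy TM cells by control-serum IgG.

    Columns: ``entry_name``, ``accession``, ``ibaq_pct`` (percent of the
    group's summed iBAQ intensity; the column sums to ~100 up to the
    printed rounding).
    """
    return _read("ch_antigen_abundance.tsv")


def load_validation_rank_sums() -> pd.DataFrame:
    """Mann-Whitney rank sums for the six quantifiable microarray targets.

    POAG vs CTRL, n = 120 per group.  ``u_printed``/``z_printed`` carry the
    published statistics for cross-checking recomputation from the rank
    sums alone.
    """
    return _read("validation_rank_sums.tsv")


def load_clinical_spearman() -> pd.DataFrame:
    """Spearman R, valid N and t for autoantibody level vs CDR / MD / IOP."""
    return _read("clinical_spearman.tsv")


def load_candidate_biomarkers() -> pd.DataFrame:
    """The 21 differential candidates with -log10 p and log2 difference."""
    return _read("candidate_biomarkers.tsv")
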