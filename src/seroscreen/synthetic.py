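"""Synthetic IP-MS and antigen-microarray data with known ground truth.

Both generators emulate the structure of an autoantigen-discovery study in
primary open-angle glaucoma (POAG):

* ``generate_ms_dataset`` produces a MaxQuant-style protein-group table for
  the eight-group immunoprecipitation design (two bead-only negative
  controls, two lysate-free mock controls, and four serum x lysate groups
  in triplicate), with intensity-dependent (left-censored) missingness —
  the mechanism that motivates down-shifted-normal imputation — and iBAQ
  columns derived from LFQ by per-protein size factors.
* ``generate_array_dataset`` produces spot-level microarray records for a
  16-subarray-per-slide layout (one serum per subarray), with triplicate
  antigen spots, human-IgG positive-control and PBS negative-control
  spots, multiplicative per-subarray batch factors, and heavy-tailed
  (Student-t) spot noise so that normality genuinely fails at cohort size.

Ground truth (which proteins/targets are differential, the batch factors,
the censoring thresholds) is returned alongside so downstream stages can
be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MAXQUANT_COLUMNS

__all__ = [
    "GroupSpec",
    "MsSimConfig",
    "ArraySimConfig",
    "GroundTruth",
    "DEFAULT_MS_GROUPS",
    "generate_ms_dataset",
    "generate_array_dataset",
]


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group of the IP-MS design."""

    label: str
    n_replicates: int
    igg_source: str  # POAG | CTRL | none
    protein_source: str  # HTM | GTM | buffer
    is_control: bool  # exclusion group (bead-only or mock)


#: the canonical 8-group design: NC1/NC2 bead-only controls (single runs),
#: MA/MB lysate-free mocks, and the four serum x trabecular-meshwork-lysate
#: groups, each in triplicate.
DEFAULT_MS_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("NC1", 1, "none", "HTM", True),
    GroupSpec("NC2", 1, "none", "GTM", True),
    GroupSpec("MA", 3, "POAG", "buffer", True),
    GroupSpec("MB", 3, "CTRL", "buffer", True),
    GroupSpec("PH", 3, "POAG", "HTM", False),
    GroupSpec("PG", 3, "POAG", "GTM", False),
    GroupSpec("CH", 3, "CTRL", "HTM", False),
    GroupSpec("CG", 3, "CTRL", "GTM", False),
)


@dataclass
class MsSimConfig:
    """Configuration of the IP-MS simulator.

    Parameters
    ----------
    n_proteins
        Total proteins that pass replicate-presence in at least one
        non-control group (default 157, the discovery-scale screen).
    n_background_shared
        Proteins also detected in negative/mock control samples, i.e.
        bead- or buffer-binding background (default 51).
    groups
        Experimental groups; defaults to the canonical 8-group design.
    n_differential
        Proteins whose abundance differs between glaucomatous-lysate (GTM)
        and healthy-lysate (HTM) groups.
    effect_log2
        True |log2| mean difference for differential proteins (sign
        alternates so both tails are populated).
    noise_sd_log2
        Replicate noise SD on the log2 scale.
    censor_quantile
        Per-sample quantile below which log-intensities are censored to
        missing (intensity-dependent missingness).
    """

    n_proteins: int = 157
    n_background_shared: int = 51
    groups: Sequence[GroupSpec] = DEFAULT_MS_GROUPS
    n_differential: int = 20
    effect_log2: float = 4.0
    noise_sd_log2: float = 0.3  # ~23% CV, typical LFQ replicate scatter
    censor_quantile: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_background_shared > self.n_proteins:
            raise ValueError(
                "invalid MsSimConfig: n_background_shared exceeds n_proteins"
            )
        if self.n_differential > self.n_proteins - self.n_background_shared:
            raise ValueError(
                "invalid MsSimConfig: n_differential exceeds the number of "
                "non-background proteins (n_proteins - n_background_shared)"
            )
        if any(g.n_replicates < 1 for g in self.groups):
            raise ValueError("invalid MsSimConfig: replicate counts must be >= 1")
        if not 0 <= self.censor_quantile < 1:
            raise ValueError("invalid MsSimConfig: censor_quantile must be in [0, 1)")
        if self.noise_sd_log2 <= 0 or self.effect_log2 < 0:
            raise ValueError(
                "invalid MsSimConfig: noise_sd_log2 must be > 0 and effect_log2 >= 0"
            )


@dataclass
class ArraySimConfig:
    """Configuration of the antigen-microarray simulator.

    One serum sample occupies one subarray (16-well incubation chambers,
    so 16 samples per slide).  Antigens are spotted in triplicate; a human
    IgG mix and PBS serve as positive and negative control spots.
    ``noise_df`` sets the Student-t degrees of freedom of the multiplicative
    spot noise — small values give the heavy tails that make Shapiro-Wilk
    reject normality on real array data.
    """

    n_slides: int = 15
    subarrays_per_slide: int = 16
    n_targets: int = 9
    n_replicate_spots: int = 3
    n_igg_spots: int = 3
    n_negctrl_spots: int = 3
    cohort_sizes: tuple[int, int] = (120, 120)  # (POAG, CTRL)
    differential_targets: Sequence[tuple[str, float]] = (
        ("AG1", 0.6),
        ("AG2", 0.55),
        ("AG3", 0.45),
        ("AG4", 0.35),
    )
    subarray_scale_sd: float = 0.25
    bio_sd_log2: float = 0.8
    reactivity_sd_log2: float = 0.6
    spot_noise_log2: float = 0.15
    noise_df: float = 4.0
    igg_level: float = 20000.0
    negctrl_level: float = 150.0
    background_level: float = 300.0
    clinical_corr: float = 0.35
    flag_poor_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.cohort_sizes) < 2:
            raise ValueError("invalid ArraySimConfig: cohort sizes must be >= 2")
        capacity = self.n_slides * self.subarrays_per_slide
        if sum(self.cohort_sizes) > capacity:
            raise ValueError(
                "invalid ArraySimConfig: cohort does not fit on "
                f"{self.n_slides} slides x {self.subarrays_per_slide} subarrays"
            )
        known = {f"AG{i + 1}" for i in range(self.n_targets)}
        unknown = [t for t, _ in self.differential_targets if t not in known]
        if unknown:
            raise ValueError(
                f"invalid ArraySimConfig: differential targets {unknown} are not "
                "among the generated targets"
            )
        if self.noise_df <= 0 or self.subarray_scale_sd < 0:
            raise ValueError(
                "invalid ArraySimConfig: noise_df must be > 0 and "
                "subarray_scale_sd >= 0"
            )
        if self.n_replicate_spots < 1 or self.n_igg_spots < 1 or self.n_negctrl_spots < 1:
            raise ValueError(
                "invalid ArraySimConfig: every subarray needs antigen, IgG and "
                "negative-control spots"
            )


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery assertions."""

    differential_protein_ids: dict[str, float] = field(default_factory=dict)
    differential_target_ids: dict[str, float] = field(default_factory=dict)
    subarray_scale_factors: dict[tuple[int, int], float] = field(default_factory=dict)
    censor_thresholds: dict[str, float] = field(default_factory=dict)
    background_shared_ids: tuple[str, ...] = ()


def _sample_ids(groups: Sequence[GroupSpec]) -> list[tuple[str, GroupSpec, int]]:
    out = []
    for g in groups:
        for r in range(1, g.n_replicates + 1):
            out.append((f"{g.label}_{r}", g, r))
    return out


def generate_ms_dataset(
    config: MsSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a protein-group quantification table plus its design.

    Returns ``(table, design, truth)`` where ``table`` is MaxQuant-dialect
    (flag columns empty, per-sample LFQ/iBAQ columns, NaN = not
    quantified) and ``design`` maps samples to groups.

    Construction guarantees: every protein is completely observed in one
    designated non-control "home" group (so the presence filter retains
    exactly ``n_proteins`` rows); only the ``n_background_shared`` proteins
    carry signal in control/mock samples; everywhere else, log-intensities
    below the per-sample ``censor_quantile`` are censored to missing.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_proteins
    width = len(str(n))
    protein_ids = [f"SIM{i + 1:0{width}d}" for i in range(n)]
    samples = _sample_ids(config.groups)
    noncontrol = [g for g in config.groups if not g.is_control]
    if not noncontrol:
        raise ValueError("invalid MsSimConfig: at least one non-control group required")

    order = rng.permutation(n)
    shared = set(order[: config.n_background_shared])
    specific = [i for i in order if i not in shared]
    diff_idx = specific[: config.n_differential]
    signs = rng.choice([-1.0, 1.0], size=len(diff_idx))
    shift = np.zeros(n)
    for i, s in zip(diff_idx, signs):
        shift[i] = s * config.effect_log2

    base = rng.uniform(22.0, 30.0, size=n)
    home = rng.integers(0, len(noncontrol), size=n)  # guaranteed-complete group
    ibaq_size = rng.uniform(5.0, 60.0, size=n)  # theoretical-peptide scale

    log2 = {}
    for sample_id, g, _r in samples:
        mu = base.copy()
        if g.protein_source == "GTM":
            mu = mu + shift
        vals = mu + rng.normal(0.0, config.noise_sd_log2, size=n)
        if g.is_control:
            mask = np.ones(n, dtype=bool)
            mask[list(shared)] = False
            vals[mask] = np.nan
        log2[sample_id] = vals

    truth = GroundTruth(
        differential_protein_ids={
            protein_ids[i]: shift[i] for i in diff_idx
        },
        background_shared_ids=tuple(protein_ids[i] for i in sorted(shared)),
    )

    # intensity-dependent left-censoring, except in each protein's home group
    exempt = {g.label: np.zeros(n, dtype=bool) for g in noncontrol}
    for i in range(n):
        exempt[noncontrol[home[i]].label][i] = True
    for sample_id, g, _r in samples:
        vals = log2[sample_id]
        observed = ~np.isnan(vals)
        # control/mock samples are exempt: background binders are robustly
        # (re-)detected there, which keeps exclusion counts well defined
        if config.censor_quantile > 0 and observed.any() and not g.is_control:
            thr = float(np.nanquantile(vals, config.censor_quantile))
            censor = observed & (vals < thr) & ~exempt[g.label]
            vals[censor] = np.nan
            truth.censor_thresholds[sample_id] = thr
        else:
            truth.censor_thresholds[sample_id] = -np.inf

    cols = {
        MAXQUANT_COLUMNS["protein_id"]: protein_ids,
        MAXQUANT_COLUMNS["entry_name"]: [f"AG{pid[3:]}_HUMAN" for pid in protein_ids],
        MAXQUANT_COLUMNS["reverse"]: [""] * n,
        MAXQUANT_COLUMNS["contaminant"]: [""] * n,
        MAXQUANT_COLUMNS["only_by_site"]: [""] * n,
    }
    for sample_id, _g, _r in samples:
        lfq = np.power(2.0, log2[sample_id])
        cols[f"{MAXQUANT_COLUMNS['lfq_prefix']}{sample_id}"] = lfq
        cols[f"{MAXQUANT_COLUMNS['ibaq_prefix']}{sample_id}"] = lfq / ibaq_size
    table = pd.DataFrame(cols)

    design = pd.DataFrame(
        {
            "sample_id": [s for s, _g, _r in samples],
            "group_id": [g.label for _s, g, _r in samples],
            "replicate_index": [r for _s, _g, r in samples],
            "igg_source": [g.igg_source for _s, g, _r in samples],
            "protein_source": [g.protein_source for _s, g, _r in samples],
            "is_control": [g.is_control for _s, g, _r in samples],
        }
    )
    return table, design, truth


def _clinical_from_level(
    rng: np.random.Generator, level_z: np.ndarray, corr: float
) -> dict[str, np.ndarray]:
    """Clinical covariates rank-correlated with an autoantibody level."""
    n = level_z.size

    def mix(sign: float) -> np.ndarray:
        return sign * corr * level_z + np.sqrt(1 - corr**2) * rng.normal(size=n)

    cdr = 1 / (1 + np.exp(-mix(-1.0)))  # cup-disc ratio in (0, 1)
    md = -5.0 + 4.0 * mix(1.0)  # visual-field mean deviation (dB)
    iop = 16.0 + 4.0 * rng.normal(size=n)  # uncorrelated by design
    return {"CDR": np.round(cdr, 2), "MD": np.round(md, 1), "IOP": np.round(iop, 1)}


def generate_array_dataset(
    config: ArraySimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate spot-level microarray records plus the cohort table.

    Returns ``(spots, cohort, truth)``.  ``spots`` holds one row per spot
    (slide, subarray, grid position, target, role, replicate, foreground,
    local background, quality flag); ``cohort`` maps each serum sample to
    its subarray, POAG/CTRL label and clinical covariates (CDR/MD/IOP,
    with realistic missingness).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    targets = [f"AG{i + 1}" for i in range(config.n_targets)]
    shifts = dict(config.differential_targets)
    n_poag, n_ctrl = config.cohort_sizes
    n_samples = n_poag + n_ctrl

    labels = np.array(["POAG"] * n_poag + ["CTRL"] * n_ctrl)
    rng.shuffle(labels)  # random plate layout: no slide/group confounding

    wells = [
        (s + 1, w + 1)
        for s in range(config.n_slides)
        for w in range(config.subarrays_per_slide)
    ][:n_samples]

    level_base = np.exp(rng.normal(np.log(3000.0), 0.5, size=config.n_targets))
    t_scale = np.sqrt(config.noise_df / (config.noise_df - 2)) if config.noise_df > 2 else 1.0

    truth = GroundTruth(differential_target_ids=dict(shifts))
    records: list[tuple] = []
    sample_rows = []
    spots_per_sub = (
        config.n_targets * config.n_replicate_spots
        + config.n_igg_spots
        + config.n_negctrl_spots
    )
    n_cols_grid = int(np.ceil(np.sqrt(spots_per_sub)))

    first_diff = config.differential_targets[0][0] if config.differential_targets else None
    diff_level_z = np.zeros(n_samples)

    for i, ((slide, sub), label) in enumerate(zip(wells, labels)):
        sample_id = f"S{i + 1:03d}"
        scale = float(np.exp(rng.normal(0.0, config.subarray_scale_sd)))
        truth.subarray_scale_factors[(slide, sub)] = scale
        secondary = config.negctrl_level * float(
            np.exp(rng.normal(0.0, 0.2))
        )  # serum-specific unspecific binding of the secondary antibody

        # per-serum global reactivity (shared across antigen targets) plus
        # independent per-target biological variation
        reactivity = rng.normal(0.0, config.reactivity_sd_log2)
        bio = rng.normal(0.0, config.bio_sd_log2, size=config.n_targets)
        levels = level_base * np.power(2.0, reactivity + bio)
        for j, t in enumerate(targets):
            if label == "POAG" and t in shifts:
                levels[j] *= 2.0 ** shifts[t]
        if first_diff is not None:
            diff_level_z[i] = bio[targets.index(first_diff)] / config.bio_sd_log2

        spot_specs = (
            [(t, "antigen", r + 1, levels[k]) for k, t in enumerate(targets)
             for r in range(config.n_replicate_spots)]
            + [("IGG", "igg_control", r + 1, config.igg_level)
               for r in range(config.n_igg_spots)]
            + [("PBS", "negative_control", r + 1, 0.0)
               for r in range(config.n_negctrl_spots)]
        )
        for pos, (target, role, rep, level) in enumerate(spot_specs):
            bg = max(0.0, rng.normal(config.background_level, 30.0))
            noise = 2.0 ** (
                config.spot_noise_log2 * rng.standard_t(config.noise_df) / t_scale
            )
            signal = scale * level * noise + scale * secondary + bg
            fg = float(np.clip(round(signal), 0, 65535))
            flag = "poor" if rng.random() < config.flag_poor_fraction else "ok"
            records.append(
                (
                    sample_id,
                    slide,
                    sub,
                    1,
                    pos // n_cols_grid + 1,
                    pos % n_cols_grid + 1,
                    target,
                    role,
                    rep,
                    fg,
                    round(bg),
                    flag,
                )
            )
        sample_rows.append((sample_id, slide, sub, label))

    spots = pd.DataFrame(
        records,
        columns=[
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
        ],
    )
    cohort = pd.DataFrame(
        sample_rows, columns=["sample_id", "slide", "subarray", "group"]
    )

    clin = _clinical_from_level(rng, diff_level_z, config.clinical_corr)
    for name, frac_missing in (("CDR", 0.3), ("MD", 0.55), ("IOP", 0.05)):
        vals = clin[name].astype(float)
        vals[rng.random(n_samples) < frac_missing] = np.nan
        cohort[name] = vals

    return spots, cohort, truth


def null_ms_config(seed: int = 0, **overrides) -> MsSimConfig:
    """Convenience: a no-differential-signal configuration."""
    return replace(MsSimConfig(seed=seed, n_differential=0), **overrides)
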