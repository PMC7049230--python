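# Methods

## Scope and data model

`seroscreen` models a two-arm serological biomarker workflow. The
discovery arm is an immunoprecipitation mass-spectrometry screen: serum
IgG pools are cross-linked to beads, incubated with trabecular-meshwork
(TM) cell lysate, and captured proteins are identified and quantified
label-free. Its data object is a MaxQuant-style protein-group table —
one row per protein group, per-sample `LFQ intensity` and `iBAQ`
columns, `+`-marked flag columns for decoy ("reverse"), contaminant and
only-identified-by-site rows — together with a design table mapping
samples to the eight groups of the canonical layout: two bead-only
negative controls (single runs), two lysate-free mock controls, and four
serum × lysate groups (patient/control IgG × healthy/glaucomatous TM
lysate), each in triplicate. A value of 0 in the quantification columns
means "not quantified"; 0 and absent are both treated as missing
throughout.

The validation arm is a custom antigen microarray: candidate antigens
printed in triplicate on 16-subarray slides, one serum per subarray,
with human-IgG positive-control and PBS (buffer-only) negative-control
spots on every subarray. Its data object is a long spot table (slide,
subarray, grid position, target, role, replicate, foreground, local
background, quality flag) plus a cohort table (sample → subarray, POAG
or CTRL label, and optional clinical covariates: cup-disc ratio CDR,
visual-field mean deviation MD, intraocular pressure IOP).

## MS filtering

Filters run in a fixed canonical order, each shrinking the row set:

1. **QC flags** — any flagged row is removed. Missing flag columns are
   treated as all-unset with a warning.
2. **Replicate presence** — a protein is kept iff some non-control group
   quantifies it in *every* replicate ("reproducibly identified").
3. **Control exclusion** — a protein with any quantification in any
   negative/mock-control sample is removed as bead/buffer background.
   Mock groups count as exclusion groups alongside the bead-only
   controls.

The composition is idempotent and order-stable; an audit table records
the row count after each stage.

iBAQ relative abundance of a group is computed over the group's
reproducibly identified proteins: mean iBAQ across the group's
replicates (missing replicates ignored), expressed as percent of the
summed means. The group summary uses the mean rather than the sum of
replicates; because the fraction normalizes by the same statistic, the
two choices give identical fractions — the choice is inert and recorded
here for completeness.

## Differential screening

Carried out on log2 LFQ intensities of two groups.

* **Imputation.** Missing values are drawn per sample from
  `N(mean − 1.8·sd, (0.3·sd)²)`, where mean and sd are the sample's
  observed statistics. This is the standard down-shift model for
  left-censored label-free data: values are missing mostly because they
  fell below detection, so they are replaced by draws from the lower
  tail. Width 0.3 and shift 1.8 are the field's conventional defaults;
  both are exposed. A sample with fewer than two observed values is an
  error (its sd is undefined).
* **Test.** Pooled-variance two-sample t per protein, with an optional
  SAM-style fudge constant `s0` added to the denominator (default 0).
  The null distribution is built from balanced label permutations: all
  distinct assignments when their number is at most `n_permutations`
  (default 250; 20 exist for 3 vs 3), otherwise a uniform sample without
  replacement. The identity assignment is included — a conservative
  choice that slightly inflates the null in the presence of signal.
* **FDR.** For protein i, `q_i = median_b #{null |t| ≥ |t_i|} / #{obs
  |t| ≥ |t_i|}`, clipped to [0, 1] and monotonized along decreasing
  |t|. q-values are invariant to row order; adding a protein changes
  other proteins' q only through the shared null pool (inherent to this
  FDR family).
* **Selection.** Candidates must satisfy `q < 0.01` **and**
  `|log2 difference| > 2` (both tails). Both thresholds are exposed;
  the selection is monotone in each.
* **Structure checks.** Hierarchical clustering of per-protein z-scored
  rows (Euclidean distance, average linkage; constant rows are dropped
  with a warning) and centred PCA over samples with variance fractions
  that are nonincreasing and sum to 1. Average linkage is a choice —
  only the distance metric is fixed by convention — and is exposed
  implicitly through the returned linkage matrices.

## Microarray pre-processing

The chain runs in this fixed order; stage counts are logged.

1. Net = foreground − local background; *strictly* negative nets become
   missing (a net of exactly 0 is kept — only signals reaching negative
   values are discarded).
2. The mean net negative-control signal is subtracted from every antigen
   and IgG spot. The default unit is the subarray (each serum occupies
   one subarray and unspecific secondary-antibody binding is
   serum-specific); per-slide subtraction is available
   (`negctrl_scope="slide"`).
3. Triplicates collapse to a missing-aware mean; all-missing triplicates
   stay missing.
4. IgG median-centring: factor_s = median(IgG_s) / median of the
   per-subarray IgG medians; every intensity of subarray s is *divided*
   by factor_s, so high-IgG subarrays are scaled down and afterwards
   every subarray's IgG median equals the global median exactly. This
   removes per-subarray multiplicative batch scale: multiplying all
   spots of one subarray (IgG included) by c > 0 leaves its NFIs
   unchanged, provided the global median (an order statistic) is not
   crossed.
5. Winsorize-to-missing: per target across samples, values strictly
   outside the 5th–95th percentile band (linear-interpolation quantiles)
   become missing. The per-target axis is the reading that keeps
   cross-sample comparisons meaningful; the axis and percentiles are
   configurable.
6. Targets missing in strictly more than 25% of samples are dropped.
7. KNN imputation over *target columns*: distance between two targets is
   the mean squared difference over co-observed samples (fair when
   co-observation counts differ); a missing cell is the unweighted mean
   of the k = 10 nearest observed neighbours, each rescaled by the ratio
   of the pair's co-observed column means (the right adjustment for
   positive fluorescence intensities; an additive offset is the fallback
   for nonpositive means). Observed cells are never altered; a cell with
   no observed neighbour is an error.

Rank-based tests are invariant to monotone transforms, so no log
transform is applied before testing; log2 is used for reporting and in
the imputation-error metric.

## Validation statistics

Mann-Whitney U with midranks: U is reported as min(U1, U2), while the
normal-approximation Z is computed from U1 so its sign indicates the
direction of group 1's shift, without continuity correction. The
tie-adjusted Z uses the tie-corrected rank variance and always satisfies
|Z_adj| ≥ |Z|. `u_z_from_rank_sums` rebuilds (U, Z) from a published
rank sum alone — the tie spectrum behind a published adjusted Z is
generally not recoverable, so Z_adj is only computed when a spectrum is
supplied. Spearman correlations use midrank Pearson with
`t = R·sqrt((N−2)/(1−R²))` on N−2 df and pairwise deletion (valid N
varies by covariate). Kruskal-Wallis (tie-corrected, χ² with g−1 df)
handles ≥3 groups; Shapiro-Wilk documents the parametric/nonparametric
routing decision. No multiple-testing adjustment is applied across the
small validation panel by default (raw p-values are reported);
Benjamini-Hochberg is available as an option.

## Classification

A single stratified train/test split (defaults 165/75, matching the
published protocol for a 240-serum cohort) followed by a random forest
(500 trees, √p features per split — conventional defaults, the study
does not state its hyperparameters) and confusion metrics reported as
rounded percents with exact fractions retained. All panel targets that
survive pre-processing enter the classifier. No cross-validation or
calibration is performed — the single-split protocol is mirrored
deliberately and is a known methodological limitation (test-set metrics
carry the variance of one 75-sample draw).

## Synthetic data

The MS generator plants per-protein base log2 intensities (uniform
22–30), group effects on the glaucomatous-lysate groups for
`n_differential` proteins (|shift| = 4 log2 units by default, sign
alternating), replicate noise of 0.3 log2 units (~23% CV, typical LFQ
triplicate scatter), and intensity-dependent missingness: values below
the per-sample 15% quantile are censored. Each protein has a designated
non-control "home" group exempt from censoring, so presence-filter
counts are exact by construction; only background-shared proteins
(default 51 of 157) carry signal in control/mock samples, and controls
are exempt from censoring so exclusion counts are exact as well. iBAQ
columns are LFQ divided by a per-protein size factor (theoretical
peptide count surrogate).

The array generator draws a multiplicative batch factor per subarray
(log-normal, sd 0.25 on the ln scale), a per-serum global reactivity
factor shared across antigen targets (0.6 log2 units — overall serum
reactivity differs between individuals and makes targets mutually
informative), independent per-target biological variation (0.8 log2
units), and heavy-tailed multiplicative spot noise (Student-t with 4 df,
scaled to 0.15 log2 units) — the heavy tails are what makes
Shapiro-Wilk reject normality at cohort size, as observed on real array
data. Planted POAG shifts default to 0.6/0.55/0.45/0.35 log2 units on
four targets; at 120 vs 120 these produce Mann-Whitney Z values in the
2–4.5 range, the magnitude reported for real validated autoantibodies.
IgG spots share one global level so median-centring is identifiable;
negative-control spots carry only background plus a serum-specific
secondary-antibody component. Clinical covariates are generated with a
Gaussian-copula rank correlation (0.35) to the first planted target's
biological level and realistic missingness (CDR 30%, MD 55%, IOP 5%),
so pairwise-deletion valid-N behavior is exercised.

What the generators do **not** emulate: spot morphology and spatial
artifacts, saturation beyond a hard 16-bit clip, plate-layout
confounding (layout is randomized), antigen cross-reactivity,
age/sex structure, and any real biological covariance between specific
antigens. Passing tests therefore demonstrate correctness of the
computational chain and its statistical calibration under these
conditions, not clinical performance on real sera; in particular the
synthetic random-forest accuracy (~60–65%) reflects the planted effect
sizes and is not a reproduction of the published 84%, which depended on
the real cohort's feature structure.

## Numerical choices and degenerate inputs

Quantiles are linear-interpolation throughout (configurable dialects
exist). Ranking uses midranks. Spearman |R| within 1e-12 of 1 is
treated as exactly ±1 (infinite t, p = 0). Ties in hierarchical
clustering and candidate ordering break by input order / accession, so
all outputs are deterministic for a fixed seed. Degenerate inputs raise
with messages naming the violated precondition: all-tied rank tests,
sub-minimal group sizes, samples without observed IgG controls or with
nonpositive IgG medians, subarrays without negative-control spots,
all-missing imputation columns, zero-variance PCA input, single-class
training sets, label sets beyond the two cohort classes.

## Problem sizes used in the checks

The bundled reference tables drive exact worked examples (six rank-sum
rows at n = 120 + 120, the 66-antigen panel, 21 candidate rows, the
published confusion counts). Simulation-based checks use: 50 seeds ×
500 proteins (3 vs 3) for null FDR calibration, 20 seeds × 200 proteins
for power, 200 simulated cohorts of 240 sera for rank-test power, and
single default-scale runs (157 proteins; 240 sera × 9 targets) for
end-to-end recovery — sizes chosen to make the Monte-Carlo assertions
stable while keeping the whole suite in the tens of seconds.
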