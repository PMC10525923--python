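# Methods

This note documents the statistical procedures, their assumptions, the
package's own design choices where the analysis design was genuinely open,
and the limits of what the test suite demonstrates.

## Data model

A study is a compounds × samples matrix of non-negative instrument
intensities with three sample roles: `control`, `case`, and `qc` (repeated
injections of a pooled sample made from aliquots of every biological
sample). Missing measurements are represented as missing (NaN) throughout
and are never imputed; every statistic uses pairwise-complete values. The
single exception is the PCA stage, which mean-fills missing cells per lipid
internally and never writes the filled values back.

Compound annotations carry the shorthand-parsed main class, total acyl
carbons and double bonds, optional per-chain composition, an annotation
confidence level (1, 2a, 2b, 3), and an `is_biological` flag. Isotope
labelled names (a `(dN)` tag, e.g. "15:0-18:1(d7)PC") are internal
standards: they parse with `is_biological = False` because they are QC
spike-ins, not analytes.

## Class curation

Compounds that are non-biological, unclassified, or annotated at level 3
(accurate mass only) are dropped before any analysis. Among the retained
lipids, every main class with fewer than `min_group_size = 4` members is
pooled into a single "small group collection"; all other classes map to
themselves. The merge is a *rule*, not a fixed group count: how many groups
result depends on the data. The parser's class registry (abbreviation →
canonical name) ships with the common glycerophospholipid, sphingolipid,
glycerolipid, sterol and amide classes and is user-extensible
(`register_lipid_class`).

## Outlier screening and sample exclusion

Per compound and per biological cohort, a two-sided Smirnov–Grubbs test at
α = 0.05 is iterated: the most extreme value (max studentized deviation) is
removed while it exceeds

  G_crit(n, α) = ((n−1)/√n) · sqrt( t² / (n−2 + t²) ),

with t the upper α/(2n) quantile of Student's t on n−2 df, recomputing mean
and sd after each removal, stopping below n = 3 or at zero variance.
Iteration-until-clean is the standard practice when more than one outlier
per series is plausible; a per-compound cap is available
(`max_outliers_per_compound`).

Screening operates on **log-transformed intensities by default**
(`grubbs_log_scale = True`). Intensities carry multiplicative noise — the
same assumption that makes geometric-mean normalization coherent — so the
Grubbs normality assumption is only tenable on the log scale. On the raw
scale a value suppressed by a large factor is numerically close to zero and
nearly undetectable, while the same factor upward is flagged easily; the
log scale treats both directions symmetrically. Raw-scale screening remains
available for comparison.

Each biological sample's outlier fraction is its flagged count divided by
its evaluable compounds (those with ≥ 3 non-missing values in the sample's
cohort; a test that cannot run counts neither way). Samples whose fraction
*strictly exceeds* 20 % are excluded from the entire analysis. QC samples
are never screened or excluded. Two application modes exist:
`drop_samples` (exclusion only) and `mask_cells` (exclusion plus setting
flagged cells to missing — the "without outliers" surface used by the
per-lipid and per-class statistics).

Screening runs on raw (pre-normalization) abundances by default, matching
the stage order curate → screen → normalize; `screen_normalized = True`
switches the order for sensitivity analyses. Whichever order is used is
stamped in the run manifest.

## Pooled-QC normalization and descriptive power

Each compound row is divided by exp(mean(log x)) over its positive,
non-missing QC values. Zeros and missing QC entries are omitted rather than
pseudocounted: omission preserves the exact unit-geomean invariant (the
normalized QC geometric mean is 1 wherever all QC values are present),
which a pseudocount would distort. Compounds with no usable QC value cannot
be normalized and are dropped with a logged list.

Descriptive power is DP = sd(normalized control + case values) /
sd(normalized QC values), with sample standard deviations (n−1 denominator)
on the arithmetic normalized scale. Compounds with DP below 2.5 are
excluded from the statistical comparisons; DP exactly 2.5 is **retained**
(the exclusion rule is "less than 2.5"). Zero QC sd yields DP = +inf
(maximal signal relative to technical noise); fewer than two values on
either side yields undefined DP, and such compounds are dropped by the
filter with a log message. DP is computed after sample exclusion and before
cell masking.

## Enrichment summaries

Count enrichment reports each group's member count and its percentage of
all classified lipids; abundance enrichment sums each group's normalized
values per sample, averages over a cohort, and reports each group's share
of the summed means. Shares are rounded half-up to one decimal for
reporting (e.g. 43/244 → 17.6 %); unrounded values are kept internally.
Per-subject group totals treat missing (including masked) cells as zero
contributions, with the skipped count logged. Age trajectories average
subjects sharing an age (recording the subject count) and order points by
age; no smoothing or interpolation is applied.

## Ordination

PCA is a full SVD of the samples × lipids matrix of normalized values,
centered by default and optionally unit-variance scaled (`pca_center`,
`pca_scale`; default center-only, since normalized abundances already share
a scale). Components are deterministic up to sign; the convention "largest
magnitude loading positive" makes output reproducible across runs and
sample orderings. At full rank, scores × loadingsᵀ plus the removed means
reconstructs the input to numerical precision.

Which component pair best displays cohort separation is data-dependent and
is therefore *searched and scored*, never hard-coded: for each candidate
component k (2 … min(6, rank)), the silhouette of the cohort labels on that
component's scores is compared with a permutation baseline (the
1 − α/n_candidates quantile of the silhouette under 200 random relabelings;
Bonferroni across candidates, α = 0.05). A raw silhouette has no meaningful
zero under random labels — the maximum over several components is almost
always positive by chance — so the permutation calibration is what makes
"non-separating" a usable verdict. If no component beats its baseline the
default display pair (1, 2) is used and the selection is flagged.

## Differential abundance

Per-lipid and per-class comparisons use Welch's t-test (unequal variances,
Satterthwaite df) on normalized values; two-sided p-values; fold changes
are log₂ of the ratio of cohort arithmetic means (`fold_change_means =
"geometric"` switches to geometric means). Units where both cohorts are
constant with equal means give p = 1; with unequal means p = 0 with a
degenerate-data warning. Units with fewer than two values on a side, or a
non-positive cohort mean for the fold change, are reported with missing
statistics and logged rather than silently dropped.

Multiple testing uses Benjamini–Hochberg step-up adjustment. The BH family
is always logged: the volcano adjusts across all descriptive-power-passing
lipids in one family; the within-class analysis adjusts each class's
members against each other only; the class-total comparison adjusts across
the groups. Significance is strict: adjusted p < q with q = 0.1. A
"suggestive" flag marks raw p < 0.05 without surviving adjustment. Cohort
demographics (age, BMI) use the classical pooled-variance Student's t-test,
which is the convention for such tables and coincides with Welch for equal
group sizes and variances.

Welch and Student tests are computed by scipy, BH by statsmodels, and PCA
by scikit-learn; the test suite checks each against independent brute-force
oracles (the explicit Welch formula, the literal step-up definition, SVD
reconstruction), so the wrappers' degenerate-case and missing-value
handling is what this package owns.

## Synthetic data generator

The generator emulates the study design the analysis assumes:

- **Cohort sizes**: 9 control, 12 case, 15 QC injections by default (the
  post-exclusion cohort sizes of the targeted design).
- **Intensities**: per compound, a baseline log-intensity drawn uniformly
  from (ln 10⁴, ln 10⁷) and lognormal multiplicative noise with biological
  CV 0.4. Lognormality is the model under which geometric-mean
  normalization is coherent.
- **Pooled QC**: each compound's QC level is the geometric mean of its
  biological samples (mirroring the pooled-aliquot construction), with
  technical CV 0.08.
- **Perturbations (all opt-in, defaults off)**: case-cohort fold changes on
  chosen compounds; outlier cells multiplied by exp(±8 σ_log); missing
  cells; a per-(class, sample) shared log-scale factor
  (`class_effect_sd`) for intra-class correlation.
- `seed_sample_outlier_burden` injects outliers into ⌈fraction · m⌉
  distinct compounds of one biological sample, for testing the exclusion
  rule.

Every table ships with its ground truth (differential compounds and their
fold changes, perturbed cells, burden-seeded samples).

What the generator does **not** emulate: retention time, m/z, adducts,
isotope patterns, injection-order drift, heteroscedastic per-compound CVs,
and (by default) any covariance between lipids. Passing recovery tests
therefore demonstrate that the pipeline's inference is correct *under its
own model assumptions* — lognormal noise, independent compounds, honest
QC pools — not that real CSF data satisfy those assumptions. The default
CVs are generator conventions chosen to represent a well-behaved untargeted
platform (technical noise ~5× smaller than biological spread), not measured
values.

## Numerical conventions

- Grubbs critical values are cached per (n, α); the screening loop is exact
  arithmetic on the remaining values, no approximation.
- Percentage shares round half-up (not banker's) to one decimal in reports.
- CSV round trips write floats at 17 significant digits and parse them with
  correctly-rounded conversion, so write→read reproduces values bit-exactly
  and preserves missingness.
- Pipeline runs are deterministic given config + seed; CSV outputs are
  byte-identical across repeats.
- Simulation-based tests and the acceptance script use modest problem sizes
  (250 compounds, the default cohorts, 50–200 replicates), chosen so the
  Monte-Carlo margins comfortably cover the assertions.

## Known limitations

- Iterated Grubbs is not exactly α-level, and symmetric pairs of extreme
  values can mask each other (an inherent property of the statistic; the
  suite contains a demonstration). Robust alternatives (MAD, generalized
  ESD) are deliberately out of scope.
- The merge rule can produce different group counts on different data; no
  particular printed group count is asserted anywhere.
- BH controls FDR in expectation under independence/PRDS; a single run at
  q = 0.1 can still contain a false discovery, as the worked example shows.
- The shorthand parser covers class-prefix grammars ("PC 34:1",
  "plasmenyl-PE 36:1 (18:0/18:1)", "FA 20:4", "amide C18") and trailing
  class tokens of labelled standards; exotic vendor formats fall back to
  "unclassified" (total function, never an exception) and are excluded by
  curation.
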