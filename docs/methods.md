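# Methods

This document describes the statistical model behind `phenoproteo`, the
synthetic-cohort generator used to test it, the meaning and defaults of
every tunable parameter, and the package's numerical choices and known
limitations. All problem sizes quoted here (cohort size, panel width,
resampling counts) are the package's own reference choices for a study
that runs in minutes on a single CPU; every one of them is configurable.

## 1. Data model

The primary object is a samples × features matrix of positive protein
abundances (relative fluorescence–style units), wrapped in
`ProteinMatrix` with unique sample and feature identifiers and optional
feature metadata. Clinical covariates and survival records
(`sample_id`, `time_years`, `event`) are separate tables keyed by sample
identifier; every stage checks alignment explicitly rather than relying
on positional order.

Analysis operates on `log2` abundances. Protein abundance distributions
are right-skewed and multiplicative technical noise becomes additive on
the log scale, so all variability statistics (MAD, correlations,
standardization) are computed after `log2`. Before clustering, each
feature is z-scored (mean 0, SD 1, population SD with `ddof=0`) so that
no protein dominates the Euclidean geometry merely by having a wider
dynamic range. The fitted transform (per-feature means and SDs) is
frozen and can be re-applied to new samples (`apply_transform`), which
is what `assign_new` uses to phenotype out-of-study patients.

## 2. Quality control

Two QC instruments are provided.

**Replicate precision.** `compute_feature_cv` takes repeated
measurements of control samples and reports the per-feature coefficient
of variation, CV% = 100 · SD/mean computed within each replicate group
(sample SD, `ddof=1`) and averaged across groups, plus the median and
interquartile range across features. This quantifies assay precision; it
does not gate features by default, because high-CV features are often
low-abundance proteins that are still biologically informative.

**Sample scale factors.** For each sample, total signal divided by the
cohort median total signal (`sample_scale_factors`). Samples outside
`scale_factor_bounds` (default 0.4–2.5) are excluded with a recorded
reason. The asymmetric bounds reflect that hybridization/dilution
failures usually depress total signal more often and more severely than
they inflate it, while still catching gross over-signal. Factors are
computed on the input matrix as given, so applying the rule twice is
idempotent. Removing every sample is an error, not an empty result.

## 3. Dimension reduction

Wide affinity panels are redundant: many aptamers track the same protein
complex or pathway. Clustering on the raw panel would implicitly weight
each biological signal by how many times the panel happens to measure
it. Reduction proceeds in two steps on log2 (pre-z-score) values:

1. **Variability filter.** Keep the top `mad_fraction` (default 0.3) of
   features by median absolute deviation. MAD rather than SD because it
   is robust to the heavy-tailed outliers typical of affinity assays.
   The count kept is `ceil(fraction · p)`; ties in MAD are broken
   lexicographically by feature id so the selection is deterministic.
2. **Module collapse.** Build a graph on the retained features with an
   edge where |correlation| ≥ `corr_threshold` (default 0.7, Spearman by
   default — again for robustness; Pearson is available). Connected
   components of this graph are the correlated modules. Each module is
   replaced by one representative "hub":
   - `max_connectivity` (default): the member with the most
     within-module edges — the feature most central to the module;
   - `max_mad`: the most variable member;
   - `random`: a seeded uniform draw, used by the sensitivity analyses
     to check that conclusions do not hinge on hub identity.

   Singleton components are their own hubs. `n_reduction_rounds` can
   repeat the module/hub step (modules can merge after collapsing), but
   one round is the default and is a fixed point in typical data.

With the reference generator defaults (1000-plex, 40 modules), this
yields a few-hundred-feature clustering space, consistent with keeping
roughly the top 30% variable features and one representative per module.

## 4. Consensus clustering and choice of k

### Consensus matrix

For each candidate k in `k_range` (inclusive, default 2–8), the package
repeats `n_resamples` times (default 1000): draw a subsample of
`subsample_fraction` = 0.8 of samples without replacement, run k-means
(k-means++ initialization, `inner_n_init` restarts, default 10), and
record which pairs of co-sampled patients land in the same cluster. The
consensus value for a pair is

    consensus(i, j) = (# resamples clustering i and j together)
                      / (# resamples containing both i and j),

i.e. normalized by co-occurrence, so pairs drawn less often are not
biased low. Pairs never co-sampled are left undefined and excluded from
downstream summaries (with the default fraction and resample counts this
is vanishingly rare).

### PAC and the k-selection rule

If the data truly contain k groups, consensus values should concentrate
near 0 and 1. The proportion of ambiguous clustering summarizes the
middle mass:

    PAC(k) = F(0.9) − F(0.1),

the fraction of defined off-diagonal consensus values strictly above 0.1
and at most 0.9 (empirical CDF, `searchsorted` side `right`).

The selection rule is:

1. `stable_ks` = all k with PAC(k) ≤ 0.2 (`PAC_STABLE_THRESHOLD`).
2. If `stable_ks` is non-empty, choose the **largest** stable k whose
   PAC is within `PAC_MARGIN` = 0.1 of the best stable PAC.
3. If no k is stable, the result carries a null-structure flag
   (`stable_ks` empty) and falls back to the argmin-PAC k (smaller k on
   ties) so downstream stages still run — but the flag, not the
   fallback k, is the scientific conclusion.

Rationale for the margin step: when a k-group structure is real, k−1 is
often also "stable" because merging two true groups still yields
near-binary consensus values, so pure argmin-PAC systematically
under-splits. Among partitions that are all essentially unambiguous
(PAC within a small margin of the best), the finest one carries the most
information. The margin (0.1) is half the stability threshold; PAC
differences below it are within the resampling noise observed at the
default resample counts.

`inner_n_init` defaults to 10 rather than scikit-learn's 10-for-full-fit
convention being applied once: with fewer restarts per subsample, a
measurable share of PAC at the true k comes from k-means landing in
local optima rather than from genuine assignment ambiguity, which
inflates PAC(k_true) relative to neighbouring k and destabilizes the
rule near the 0.2 threshold.

### Final assignment

The reported partition re-runs k-means at the chosen k on the full
standardized matrix with `n_init` restarts (default 50). Phenogroups are
renumbered 1..k by **descending size** (1 = largest), which makes the
largest group the natural Cox reference and makes labels comparable
across runs. `assign_by_centroid` assigns new samples to the nearest
final centroid; it requires the exact ordered feature set of the fit.

## 5. Cluster validation

**Partition agreement.** `concordance` reports three statistics: the
Rand index (fraction of sample pairs on which two partitions agree),
the adjusted Rand index (chance-corrected; 0 expected under independent
random labellings), and optimal-matching concordance — the fraction of
samples assigned identically after the label permutation that maximizes
agreement (solved by linear assignment on the contingency table). All
are invariant to label names; inputs with identifiers must cover the
same sample set.

**In-group proportion (IGP).** For a group g, the fraction of its
members whose nearest neighbour (Euclidean, in the clustering feature
space) also belongs to g. `internal_validation` splits the cohort
(default 50/50, seeded), re-derives centroids on the training half,
assigns the validation half by nearest centroid, and reports IGP on
both. High validation IGP (the reference generator yields ≳ 0.7–0.8 per
group at default effect sizes) indicates the phenogroups are compact and
reproducible rather than an artifact of a single fit. Groups with fewer
than two members make IGP undefined and raise an error.

**Sensitivity analyses.** Three resampling checks quantify how much the
partition depends on pipeline choices: `hub_randomization_sensitivity`
(re-reduce with random hubs many times and measure concordance with the
primary partition), `threshold_grid_sensitivity` (re-run over a grid of
`mad_fraction` × `corr_threshold`), and `feature_exclusion_sensitivity`
(drop random subsets of selected features). Each returns a distribution
with median and IQR.

## 6. Permutation variable importance

Importance of a feature is defined **relative to a fixed partition and
its centroids**: the mean fraction of samples whose nearest-centroid
assignment changes when that feature's column is permuted across
samples (default 50 permutations). Features that carry the group
separation produce large label churn; features irrelevant to the
geometry produce none.

Implementation: since permuting one column j changes each sample's
squared distance to centroid g only through that column, the
nearest-centroid argmin is updated from cached cross-products
(`argmin_g ||c_g||² − 2(x·c_g + (x'_j − x_j)·c_{g,j})`) instead of
recomputing full distance matrices — an O(nk) update per permutation
instead of O(nkp). This is exactly equal (not approximately) to the
brute-force recomputation; the test suite verifies equality against an
independent full-recompute oracle. Constant columns get importance
exactly 0, with their permutation draws still consumed so other
features' scores do not depend on which columns happen to be constant.
Samples are put in canonical (sorted-id) order first, making scores
exactly invariant to joint reordering of matrix and assignment. Ranks
break ties lexicographically by feature id.

`cluster_on_top` re-clusters on the top-m features (default m = 10) and
reports agreement with the primary partition — the "can a small panel
reproduce the phenomap?" question. `feature_covariate_correlations` and
`phenogroup_expression_profile` support interpretation.

## 7. Survival analysis

**Kaplan–Meier.** `km_curve` (via `lifelines.KaplanMeierFitter`) with
exponential-Greenwood 95% confidence intervals, evaluated per
phenogroup, overall, or per phenogroup × stratum cell
(`survival_by_strata`; cells partition the cohort). Median follow-up
uses the reverse Kaplan–Meier estimator (censoring treated as the
event); if the reverse-KM curve never reaches 0.5 the median is
reported as not reached rather than extrapolated.

**Cox regression.** `cox_fit` (via `lifelines.CoxPHFitter`, Efron tie
handling) with phenogroup indicator variables using the smallest label
(= largest group) as reference. Model presets:

| preset | covariates |
| --- | --- |
| `M0` | phenogroup only |
| `M1` | + age, sex, eGFR |
| `M2` | + log NT-proBNP |
| `M3` | + MAGGIC risk score |
| `M2_afib` | M2 + atrial fibrillation |
| `M2_hfdur` | M2 + HF duration ≥ 18 months |

NT-proBNP enters as its natural log (`log_nt_probnp = ln(nt_probnp)`).
A constant covariate in the design is a `SurvivalError` (it would be
silently dropped or unidentifiable otherwise), as are fits with fewer
than 10 events. `interaction_test` compares the preset model with and
without phenogroup × factor product terms by likelihood-ratio chi-square
((k−1) × (levels−1) df) and reports per-term Wald p-values.

## 8. Synthetic-cohort generator

The generator exists so that every stage can be tested against known
ground truth; it is not a biophysical simulation. Its scope is: planted
block-correlation structure, planted group mean shifts, realistic
multiplicative noise, clinical covariates with monotone per-group
trends, and phenogroup-graded right-censored survival.

**Expression.** Features are partitioned into `n_modules` modules with
sizes uniform on `module_size_range`; leftover features are
independent. On the log2 scale, module members share a latent factor:
member = √ρ · factor + √(1−ρ) · noise, giving exact equicorrelation ρ
(`within_module_corr`, default 0.8) within a module and independence
across modules. `n_informative_modules` of the modules are informative
under a cyclic design: module m is elevated in group (m mod k) and
baseline elsewhere, so every group is marked by its own module subset.
The factor shift is `effect_size / √ρ`, so the realized member-level
shift equals `effect_size` marginal within-group SDs (default 2.0 — a
strong but not trivially separable signature). Values are mapped to the
positive raw scale by exponentiation around a feature-specific baseline
and multiplied by log-normal technical noise with σ² = ln(1 + cv²) and
mean 1 (the −σ²/2 offset), so `technical_cv` (default 0.09) is the
noise CV on the raw scale — matching the replicate-CV QC statistic.

**Clinical covariates.** Continuous covariates are Gaussian with a
linear trend across group index (e.g. age +3 y per step, eGFR −10
mL/min/1.73 m² per step, log NT-proBNP +0.6 per step); atrial
fibrillation prevalence trends upward; sex, EF < 40% and HF duration
are trend-free. The defaults describe an elderly HF cohort (age 76 ± 10,
eGFR 60 ± 18, median NT-proBNP ≈ 1500 pg/mL).

**Survival.** Event times are Weibull with per-group scale
(`hazard_scale_per_group`, default (0.10, 0.15, 0.22) events/year) and
shape 1 by default (exponential). Censoring is exponential with rate
`censoring_rate` (default 0.02/year), truncated administratively at
`followup_horizon` (default 14 years). The default hazards give roughly
graded 5-year survival in the 0.35–0.65 range across groups.

**QC failures.** `inject_qc_failures` (or `n_qc_fail_samples` in the
config) multiplies or divides a sample's entire row by 8, pushing its
scale factor far outside the default bounds; the truth manifest records
which samples were corrupted so QC recall is testable.

Every cohort carries a truth manifest (labels, modules, informative
modules, hubs, group shifts, generating config) and round-trips through
`write_cohort`/file readers.

## 9. Reference parameter defaults

| parameter | default | unit | rationale |
| --- | --- | --- | --- |
| `n_samples` | 1351 | samples | population-cohort scale; large enough for 3-group survival contrasts |
| `n_features` | 1000 | features | wide-panel regime at single-CPU-minutes cost |
| `group_proportions` | (0.45, 0.245, 0.305) | — | unequal sizes; tests size-based renumbering |
| `within_module_corr` | 0.8 | correlation | strong module structure, typical of co-regulated panels |
| `effect_size` | 2.0 | marginal SD | separable but not trivial group signature |
| `technical_cv` | 0.09 | CV | high-quality affinity assay precision |
| `mad_fraction` | 0.3 | fraction | keep the variable third of the panel |
| `corr_threshold` | 0.7 | abs. correlation | module edge; below it features add information |
| `subsample_fraction` | 0.8 | fraction | consensus-clustering convention; enough overlap for pair coverage |
| `n_resamples` | 1000 | resamples | PAC Monte-Carlo error well below the 0.1 margin |
| `inner_n_init` | 10 | restarts | suppress optimizer-noise inflation of PAC (see §4) |
| `n_init` | 50 | restarts | final fit should not depend on initialization |
| `PAC_STABLE_THRESHOLD` | 0.2 | PAC | ≤ 20% ambiguous pairs treated as stable |
| `PAC_MARGIN` | 0.1 | PAC | prefer finest stable partition within noise of best |
| `scale_factor_bounds` | (0.4, 2.5) | ratio | asymmetric assay-failure bounds (see §2) |
| `hazard_scale_per_group` | (0.10, 0.15, 0.22) | events/year | graded mortality, ~2× spread |
| `censoring_rate` | 0.02 | events/year | light loss to follow-up plus 14-year horizon |

## 10. Numerical choices

- All computation is float64; no stochastic step uses global RNG state.
  Every stochastic function takes a seed and uses
  `numpy.random.default_rng`; derived seeds are drawn below 2³¹.
  Repeated runs with the same seed are bit-identical, which the test
  suite asserts for the generator, consensus clustering, final k-means,
  splits, importance and random-hub reduction.
- Established libraries are used for standard components — scikit-learn
  `KMeans`, `lifelines` for KM/Cox, `scipy` for linear assignment,
  distances and distributions, pandas for alignment — while the
  methodological pieces (consensus/PAC machinery and selection rule,
  agreement statistics, IGP, MAD/module reduction, permutation
  importance, generator) are implemented and tested here against
  independent hand-computed or brute-force oracles.
- Ties are broken deterministically everywhere they can occur (MAD
  selection, importance ranks: lexicographic by feature id; k-selection
  fallback: smaller k).

## 11. Limitations

- **Low-dimensional over-splitting.** In very low-dimensional, tightly
  separated toy data (e.g. 2-D blobs), k-means can split one true blob
  reproducibly across subsamples, making PAC small at k+1; the margin
  rule then legitimately chooses the finer partition. This is a property
  of consensus stability itself, not a bug: stability measures
  reproducibility, not truth. In realistic high-dimensional panels the
  effect is not observed; claims about the *number* of phenogroups
  should always be read together with the sensitivity analyses.
- PAC thresholds (0.2 stability, 0.1 margin) are conventions, not
  estimated quantities; cohorts whose PAC profile hovers at the
  threshold deserve manual inspection of the consensus CDFs.
- The generator uses exact equicorrelation within modules, independence
  across modules, cyclic one-module-per-group elevation, and (by
  default) exponential survival — all simplifications. It validates the
  pipeline's machinery, not biological realism.
- Cox models assume proportional hazards; the package provides the
  interaction test but no time-varying-effect diagnostics.
- IGP is undefined for singleton groups, and its absolute level depends
  on dimensionality; compare within a study, not across feature spaces.
- Importance is defined relative to a fixed partition and centroids; it
  measures each feature's role in the discovered geometry, not marginal
  predictive value for outcomes.
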