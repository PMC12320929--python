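# phenoproteo

Molecular phenomapping of heart-failure cohorts from large-scale plasma
proteomics: unsupervised discovery of patient phenogroups, cluster
validation, protein importance ranking, and survival contrasts.

## Scientific problem

Heart failure — particularly heart failure with preserved ejection
fraction — is clinically heterogeneous, and trials treating it as one
disease have repeatedly failed. One proposed way forward is *molecular
phenomapping*: profile each patient's plasma on a multi-thousand-plex
affinity proteomics panel, cluster patients on their protein profiles,
and ask whether the resulting phenogroups differ in biology and
prognosis. The analysis has to solve several coupled problems:

1. **Quality control.** Remove samples whose per-sample scale factors
   indicate assay failure, and quantify technical precision from
   replicate measurements.
2. **Dimension reduction.** A ~1000–7000-plex panel is highly redundant:
   many proteins move together in correlated modules. The pipeline keeps
   the most variable proteins (median absolute deviation, MAD) and then
   collapses each correlated module to a single representative ("hub")
   so that clustering is not dominated by one pathway measured many
   times.
3. **Cluster discovery with honest model selection.** Consensus k-means
   over many subsamples yields, for each candidate k, a consensus matrix
   whose ambiguity is summarized by the proportion of ambiguous
   clustering (PAC). The package selects k from the PAC profile and
   flags cohorts with no stable structure.
4. **Validation and interpretation.** In-group proportion (IGP) on
   train/validation splits, sensitivity of the partition to pipeline
   choices, permutation-based protein importance against the k-means
   objective, and Kaplan–Meier / Cox survival contrasts across
   phenogroups with preset covariate adjustment models.

Because real cohorts have no ground truth, the package ships a
synthetic-cohort generator with planted module structure, planted
phenogroups, clinical covariates with per-group trends, and
phenogroup-graded survival — so every stage can be tested against known
truth.

## Worked example

Generate a synthetic cohort with three planted phenogroups, fit the full
pipeline, and examine survival by phenogroup:

```python
from phenoproteo import CohortConfig, PhenomapModel, PipelineParams, generate_cohort

config = CohortConfig(
    n_samples=300, n_features=600,
    n_groups=3, group_proportions=(0.45, 0.245, 0.305),
    n_modules=30, module_size_range=(5, 15),
    n_informative_modules=10, effect_size=2.0,
    seed=42,
)
cohort = generate_cohort(config)

params = PipelineParams(k_range=(2, 6), n_resamples=150, n_init=20)
model = PhenomapModel.from_cohort(cohort, params=params)
results = model.fit(seed=0)
print(results.summary())
```

Output:

```
Phenomapping results
====================
samples (post-QC):      300 (excluded 0)
features selected:      89 of 600 (MAD fraction 0.3, |r| >= 0.7)
chosen k (PAC rule):    3 (stable ks: [2, 3])
PAC by k:               2: 0.064, 3: 0.079, 4: 0.340, 5: 0.425, 6: 0.442
phenogroup sizes:       1: n=137, 2: n=90, 3: n=73
```

Both k = 2 and k = 3 are stable (PAC ≤ 0.2); the selection rule prefers
the finer partition when its PAC is within a small margin of the best,
so k = 3 is chosen — matching the planted structure. Survival separates
across phenogroups:

```python
for (group, _), curve in sorted(results.km_by_phenogroup().items()):
    print(f"phenogroup {group}: n={curve.n}, "
          f"5-year survival {curve.survival_at(5.0):.3f}")

fit = results.cox("M1")   # adjusted for age, sex, eGFR
print(fit.hr.round(3))
```

```
phenogroup 1: n=137, 5-year survival 0.634
phenogroup 2: n=90, 5-year survival 0.290
phenogroup 3: n=73, 5-year survival 0.532

                 hr  ci_lower  ci_upper      p
covariate
phenogroup_2  2.493     1.777     3.497  0.000
phenogroup_3  1.136     0.803     1.606  0.472
age           1.002     0.989     1.015  0.740
sex           1.019     0.784     1.325  0.888
egfr          0.999     0.991     1.006  0.750
```

Phenogroups are numbered by descending size (1 = largest), so the
highest-risk planted group here surfaces as phenogroup 2 with a ~2.5×
adjusted hazard relative to phenogroup 1.

Other result methods: `results.igp()`, `results.internal_validation()`,
`results.importance()`, `results.expression_profile()`,
`results.assign_new(matrix)`, `results.write(out_dir)`.

## Command line

The `phenoproteo` entry point exposes each stage and an end-to-end run:

```bash
phenoproteo simulate --config cohort.yaml --seed 0 --out-dir data/
phenoproteo qc       --matrix data/matrix.tsv --out-dir qc/
phenoproteo reduce   --matrix qc/matrix_qc.tsv --out-dir reduced/
phenoproteo cluster  --matrix reduced/matrix_selected.tsv --k-min 2 --k-max 6 --out-dir clusters/
phenoproteo run-all  --matrix data/matrix.tsv --clinical data/clinical.tsv \
                     --survival data/survival.tsv --seed 0 --out-dir results/
```

`run-all` writes phenogroup assignments, selected features, consensus
diagnostics, KM curves and Cox tables as CSV/JSON artifacts.

## Documentation

See [docs/methods.md](docs/methods.md) for the statistical model, the
synthetic generator, parameter defaults and their rationale, numerical
choices, and known limitations.
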