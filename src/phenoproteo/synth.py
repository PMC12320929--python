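"""Synthetic proteomics cohorts with known phenogroup structure.

The generator produces the statistical structure the phenomapping pipeline
assumes, with a full truth manifest so every downstream stage can be tested
against known ground truth:

* log2 abundances are Gaussian with block (module) correlation induced by a
  shared latent factor per module (equicorrelation within module);
* a subset of modules is *informative*: each group shifts that module's
  latent factor by a group-specific amount drawn with SD ``effect_size``,
  so every member of an informative module carries group signal (attenuated
  by ``sqrt(within_module_corr)``) and hub choice does not destroy it;
* abundances are exponentiated to a strictly positive RFU-like scale and
  multiplied by log-normal technical noise with a given coefficient of
  variation;
* survival times are Weibull (exponential by default) with per-group
  hazard scale, independently censored by an exponential time truncated at
  the follow-up horizon;
* clinical covariates follow group-graded trends (the worst group is older,
  with lower eGFR and higher NT-proBNP and risk score).

Everything is deterministic for a fixed config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .config import CohortConfig, ConfigurationError
from .io import write_matrix, _jsonable
from .matrix import ProteinMatrix

QC_FAIL_SCALE = 8.0  # multiplicative distortion applied to injected QC failures


@dataclass
class SyntheticCohort:
    """A generated cohort: matrix + clinical + survival + ground truth."""

    matrix: ProteinMatrix
    clinical: pd.DataFrame
    survival: pd.DataFrame
    true_labels: pd.Series  # sample_id -> 0-based latent group
    truth_manifest: dict

    def validate(self) -> None:
        ids = self.matrix.sample_ids
        assert list(self.clinical["sample_id"]) == ids
        assert list(self.survival["sample_id"]) == ids
        assert list(self.true_labels.index) == ids


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:05d}" for i in range(n)]


def _feature_ids(p: int) -> list[str]:
    return [f"SOMA{i:05d}" for i in range(p)]


def _plan_modules(cfg: CohortConfig, rng: np.random.Generator) -> list[list[int]]:
    """Assign feature indices to modules; leftovers remain singleton noise."""
    lo, hi = cfg.module_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_modules)
    while sizes.sum() > cfg.n_features:
        # shrink the largest module; guaranteed feasible by config validation
        j = int(np.argmax(sizes))
        if sizes[j] <= lo:
            raise ConfigurationError("module packing infeasible")
        sizes[j] -= 1
    modules, start = [], 0
    for s in sizes:
        modules.append(list(range(start, start + int(s))))
        start += int(s)
    return modules


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from ``config``.

    Returns a :class:`SyntheticCohort` whose tables share one ordered
    sample-ID set and whose truth manifest records module memberships,
    informative modules and hubs, group shifts and generating parameters.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p, k = config.n_samples, config.n_features, config.n_groups
    sample_ids = _sample_ids(n)
    feature_ids = _feature_ids(p)

    # latent group memberships
    labels = rng.choice(k, size=n, p=np.asarray(config.group_proportions))
    # guarantee every group is represented
    for g in range(k):
        if not (labels == g).any():
            labels[rng.integers(n)] = g

    modules = _plan_modules(config, rng)
    informative = list(range(config.n_informative_modules))

    # per-feature marginal parameters on the log2 scale
    baseline = rng.normal(10.0, 1.5, size=p)
    scale = rng.uniform(0.6, 1.4, size=p)

    rho = config.within_module_corr
    sq_rho, sq_res = np.sqrt(rho), np.sqrt(1.0 - rho)

    # Cyclic elevated-group design: informative module m is shifted up by
    # effect_size within-group SDs in group (m mod k) and unshifted in the
    # others, so all group pairs are equidistant in the informative hub
    # space. The factor shift is divided by sqrt(rho) so that the realized
    # member-level shift equals effect_size marginal (within-group) SDs.
    shifts = np.zeros((k, len(modules)))
    factor_shift = config.effect_size / (sq_rho if rho > 0 else 1.0)
    for i, m in enumerate(informative):
        shifts[i % k, m] = factor_shift

    z = rng.standard_normal((n, p))
    log2_vals = np.empty((n, p))
    in_module = np.zeros(p, dtype=bool)
    for m, members in enumerate(modules):
        factor = rng.standard_normal(n) + shifts[labels, m]
        for j in members:
            in_module[j] = True
            log2_vals[:, j] = sq_rho * factor + sq_res * z[:, j]
    log2_vals[:, ~in_module] = z[:, ~in_module]
    log2_vals = baseline + scale * log2_vals

    values = np.exp2(log2_vals)
    if config.technical_cv > 0:
        sigma2 = np.log1p(config.technical_cv**2)
        noise = rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=(n, p))
        values = values * np.exp(noise)

    matrix = ProteinMatrix(
        values=pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                            columns=feature_ids),
        feature_meta=pd.DataFrame(
            {"target_name": [f"protein_{i}" for i in range(p)]},
            index=pd.Index(feature_ids, name="feature_id"),
        ),
    )

    clinical = _generate_clinical(config, rng, sample_ids, labels)
    survival = _generate_survival(config, rng, sample_ids, labels)

    module_map = {
        f"M{m:04d}": [feature_ids[j] for j in members]
        for m, members in enumerate(modules)
    }
    manifest = {
        "modules": module_map,
        "informative_modules": [f"M{m:04d}" for m in informative],
        "informative_hubs": [feature_ids[modules[m][0]] for m in informative],
        "group_shifts": {f"M{m:04d}": shifts[:, m].tolist() for m in informative},
        "config": config.to_dict(),
        "qc_fail_samples": [],
    }

    cohort = SyntheticCohort(
        matrix=matrix,
        clinical=clinical,
        survival=survival,
        true_labels=pd.Series(labels, index=pd.Index(sample_ids, name="sample_id"),
                              name="true_group"),
        truth_manifest=manifest,
    )
    if config.n_qc_fail_samples > 0:
        cohort = inject_qc_failures(
            cohort, config.n_qc_fail_samples, seed=config.seed + 1
        )
    return cohort


def _trend_shift(trend: float, labels: np.ndarray, k: int) -> np.ndarray:
    return trend * (labels - (k - 1) / 2.0)


def _generate_clinical(
    config: CohortConfig, rng: np.random.Generator,
    sample_ids: list[str], labels: np.ndarray,
) -> pd.DataFrame:
    cs = config.covariate_spec
    k = config.n_groups
    n = len(sample_ids)
    age = rng.normal(cs.age_mean, cs.age_sd, n) + _trend_shift(cs.age_trend, labels, k)
    egfr = rng.normal(cs.egfr_mean, cs.egfr_sd, n) + _trend_shift(
        cs.egfr_trend, labels, k
    )
    egfr = np.clip(egfr, 5.0, None)
    log_bnp = rng.normal(cs.log_ntprobnp_mean, cs.log_ntprobnp_sd, n) + _trend_shift(
        cs.log_ntprobnp_trend, labels, k
    )
    maggic = np.rint(
        rng.normal(cs.maggic_mean, cs.maggic_sd, n)
        + _trend_shift(cs.maggic_trend, labels, k)
    ).astype(int)
    afib_p = np.clip(cs.afib_p + _trend_shift(cs.afib_trend, labels, k), 0.01, 0.99)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": np.clip(age, 18.0, None).round(1),
            "sex": rng.binomial(1, cs.sex_p_female, n),
            "egfr": egfr.round(1),
            "nt_probnp": np.exp(log_bnp).round(1),
            "maggic": np.clip(maggic, 0, 50),
            "ef_lt40": rng.binomial(1, cs.ef_lt40_p, n),
            "afib": rng.binomial(1, afib_p),
            "hf_duration_ge18mo": rng.binomial(1, cs.hf_duration_ge18mo_p, n),
        }
    )


def _generate_survival(
    config: CohortConfig, rng: np.random.Generator,
    sample_ids: list[str], labels: np.ndarray,
) -> pd.DataFrame:
    n = len(sample_ids)
    lam = np.asarray(config.hazard_scale_per_group)[labels]
    shape = config.weibull_shape
    # S(t) = exp(-(lam*t)^shape); exponential when shape == 1
    t_event = np.power(rng.exponential(1.0, n), 1.0 / shape) / lam
    if config.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / config.censoring_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, config.followup_horizon)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.clip(time, 1e-6, None)
    return pd.DataFrame({"sample_id": sample_ids, "time_years": time, "event": event})


def inject_qc_failures(
    cohort: SyntheticCohort, n_fail: int, seed: int
) -> SyntheticCohort:
    """Flag ``n_fail`` random samples and distort their total signal.

    Each chosen sample's abundances are multiplied by an extreme scale
    factor (alternately high/low around :data:`QC_FAIL_SCALE`) so that a
    total-signal scale-factor QC rule detects them. Flags are recorded both
    on the matrix and in the truth manifest. ``n_fail == 0`` returns the
    cohort unchanged.
    """
    n = cohort.matrix.n_samples
    if n_fail >= n:
        raise ConfigurationError(f"n_fail={n_fail} must be < n_samples={n}")
    if n_fail == 0:
        return cohort
    rng = np.random.default_rng(seed)
    ids = np.asarray(cohort.matrix.sample_ids)
    fail_ids = rng.choice(ids, size=n_fail, replace=False)
    values = cohort.matrix.values.copy()
    flags = dict(cohort.matrix.sample_flags)
    for i, sid in enumerate(fail_ids):
        factor = QC_FAIL_SCALE if i % 2 == 0 else 1.0 / QC_FAIL_SCALE
        values.loc[sid] = values.loc[sid] * factor
        flags[sid] = "injected_qc_failure"
    manifest = dict(cohort.truth_manifest)
    manifest["qc_fail_samples"] = sorted(str(s) for s in fail_ids)
    matrix = ProteinMatrix(
        values=values,
        feature_meta=cohort.matrix.feature_meta,
        sample_flags=flags,
        transform_state=cohort.matrix.transform_state,
    )
    return replace(cohort, matrix=matrix, truth_manifest=manifest)


def simulate_replicates(
    config: CohortConfig, n_replicates: int, n_features: int | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate repeated measurements of single specimens for CV estimation.

    Draws one underlying abundance profile per replicate group (one group
    per base sample of a small cohort) and re-measures it ``n_replicates``
    times with independent technical noise. Returns the stacked replicate
    matrix and a replicate-group Series aligned to its rows.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per group")
    p = n_features or min(config.n_features, 50)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n_groups = 20
    base = np.exp2(rng.normal(10.0, 1.5, size=(n_groups, p)))
    sigma2 = np.log1p(config.technical_cv**2)
    rows, group_ids, row_ids = [], [], []
    for g in range(n_groups):
        noise = rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=(n_replicates, p))
        rows.append(base[g] * np.exp(noise))
        group_ids += [f"R{g:03d}"] * n_replicates
        row_ids += [f"R{g:03d}_rep{i}" for i in range(n_replicates)]
    values = pd.DataFrame(np.vstack(rows), index=row_ids, columns=_feature_ids(p))
    return values, pd.Series(group_ids, index=values.index, name="replicate_group")


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write matrix TSV, clinical/survival CSVs and the truth manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "abundance_matrix.tsv",
        "clinical": out / "clinical.csv",
        "survival": out / "survival.csv",
        "true_labels": out / "true_labels.csv",
        "truth_manifest": out / "truth_manifest.json",
    }
    write_matrix(cohort.matrix, paths["matrix"])
    cohort.clinical.to_csv(paths["clinical"], index=False)
    cohort.survival.to_csv(paths["survival"], index=False)
    cohort.true_labels.rename("true_group").to_csv(paths["true_labels"])
    with open(paths["truth_manifest"], "w") as fh:
        json.dump(_jsonable(cohort.truth_manifest), fh, indent=2)
    return paths
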