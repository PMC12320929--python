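"""Kaplan-Meier and Cox proportional-hazards analysis of phenogroups.

Kaplan-Meier curves carry pointwise 95% confidence intervals computed on
the log(-log) scale (exponential Greenwood), which keeps the bounds inside
[0, 1]. Median follow-up uses the reverse Kaplan-Meier method (censoring
treated as the event). Cox models use Efron tie handling and come in staged
presets mirroring incremental clinical adjustment:

* ``M1``: phenogroup + age + sex + eGFR
* ``M2``: M1 + log(NT-proBNP) + MAGGIC risk score
* ``M3``: M2 + EF category (<40% vs >= 40%)
* ``M2_afib`` / ``M2_hfdur``: M2 + atrial fibrillation / HF duration flag

Phenogroup enters as a categorical with phenogroup 1 (the largest group)
as reference. Interaction with a binary factor is tested by a likelihood-
ratio chi-square comparing models with and without the product terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats

from .cluster import PhenogroupAssignment


class SurvivalError(ValueError):
    pass


MODEL_PRESETS: dict[str, list[str]] = {
    "M0": [],
    "M1": ["age", "sex", "egfr"],
    "M2": ["age", "sex", "egfr", "log_nt_probnp", "maggic"],
    "M3": ["age", "sex", "egfr", "log_nt_probnp", "maggic", "ef_lt40"],
    "M2_afib": ["age", "sex", "egfr", "log_nt_probnp", "maggic", "afib"],
    "M2_hfdur": ["age", "sex", "egfr", "log_nt_probnp", "maggic",
                 "hf_duration_ge18mo"],
}


@dataclass
class KMCurve:
    """A fitted product-limit curve with CI and at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    group_label: str = ""
    n: int = 0
    n_events: int = 0
    ci_defined: bool = True

    def survival_at(self, t: float) -> float:
        """Step-function value at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def ci_at(self, t: float) -> tuple[float, float]:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return (1.0, 1.0)
        return float(self.ci_lower[idx]), float(self.ci_upper[idx])


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"time_years", "event"}
    missing = required - set(records.columns)
    if missing:
        raise SurvivalError(f"records missing columns {sorted(missing)}")
    if (records["time_years"] <= 0).any():
        raise SurvivalError("all survival times must be > 0")
    if not records["event"].isin([0, 1]).all():
        raise SurvivalError("event indicator must be 0/1")
    return records


def km_estimate(records: pd.DataFrame, group_label: str = "") -> KMCurve:
    """Product-limit survival estimate with exponential-Greenwood 95% CI."""
    records = _check_records(records)
    t = records["time_years"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(t, e)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    lo = ci.iloc[:, 0].to_numpy(dtype=float)
    hi = ci.iloc[:, 1].to_numpy(dtype=float)
    at_risk = np.array([(t >= u).sum() for u in times])
    n_events = int(e.sum())
    return KMCurve(
        times=times,
        survival=surv,
        ci_lower=lo,
        ci_upper=hi,
        n_at_risk=at_risk,
        group_label=group_label,
        n=len(t),
        n_events=n_events,
        ci_defined=n_events > 0,
    )


def reverse_km_followup(records: pd.DataFrame) -> dict:
    """Median follow-up (years) by the reverse Kaplan-Meier method.

    The censoring indicator is inverted so that censoring becomes the
    event; the median of that curve estimates the follow-up distribution's
    median. Returns the median with a 95% CI; an unreached median is
    reported as such with the largest observed time as a lower bound.
    """
    records = _check_records(records)
    t = records["time_years"].to_numpy(dtype=float)
    e = 1 - records["event"].to_numpy(dtype=int)
    kmf = KaplanMeierFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(t, e)
    median = kmf.median_survival_time_
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    if np.isinf(median):
        return {
            "median_followup_years": None,
            "reached": False,
            "lower_bound_years": float(t.max()),
            "ci": (lo if np.isfinite(lo) else None, None),
        }
    return {
        "median_followup_years": float(median),
        "reached": True,
        "ci": (
            lo if np.isfinite(lo) else None,
            hi if np.isfinite(hi) else None,
        ),
    }


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model."""

    coefficients: pd.Series
    hr: pd.DataFrame  # columns: hr, ci_lower, ci_upper, p
    loglik: float
    n: int
    n_events: int
    ties_method: str = "efron"
    covariate_spec: str = ""
    _fitter: CoxPHFitter | None = field(default=None, repr=False)

    def summary(self) -> pd.DataFrame:
        out = self.hr.copy()
        out.insert(0, "coef", self.coefficients)
        return out


def _build_design(
    records: pd.DataFrame,
    clinical: pd.DataFrame | None,
    assignment: PhenogroupAssignment | None,
    covariates: list[str],
) -> pd.DataFrame:
    df = records[["sample_id", "time_years", "event"]].copy()
    if assignment is not None:
        labels = assignment.labels
        df["phenogroup"] = labels.reindex(df["sample_id"]).to_numpy()
        if df["phenogroup"].isna().any():
            raise SurvivalError("assignment does not cover all survival records")
        ref = min(labels.unique())  # phenogroup 1 (largest group) is reference
        for g in sorted(labels.unique()):
            if g != ref:
                df[f"phenogroup_{int(g)}"] = (df["phenogroup"] == g).astype(int)
        df = df.drop(columns=["phenogroup"])
    if covariates:
        if clinical is None:
            raise SurvivalError("covariates requested but no clinical table given")
        clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns \
            else clinical
        clin = clin.reindex(df["sample_id"])
        if clin.isna().all(axis=1).any():
            raise SurvivalError("clinical table does not cover all records")
        for cov in covariates:
            if cov == "log_nt_probnp":
                df[cov] = np.log(clin["nt_probnp"].to_numpy(dtype=float))
            elif cov in clin.columns:
                df[cov] = clin[cov].to_numpy(dtype=float)
            else:
                raise SurvivalError(f"unknown covariate {cov!r}")
    df = df.drop(columns=["sample_id"])
    for col in df.columns:
        if col in ("time_years", "event"):
            continue
        if df[col].nunique() < 2:
            raise SurvivalError(f"covariate {col!r} is constant")
    return df


def cox_fit(
    records: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    assignment: PhenogroupAssignment | None = None,
    model: str | list[str] = "M1",
    extra_columns: pd.DataFrame | None = None,
) -> CoxFit:
    """Fit a Cox model with phenogroup (reference = group 1) and covariates.

    ``model`` is a preset name or an explicit covariate list. Efron tie
    handling throughout. Requires >= 10 events.
    """
    records = _check_records(records)
    if int(records["event"].sum()) < 10:
        raise SurvivalError("fewer than 10 events; Cox fit unreliable")
    covariates = MODEL_PRESETS[model] if isinstance(model, str) else list(model)
    df = _build_design(records, clinical, assignment, covariates)
    if extra_columns is not None:
        df = pd.concat([df, extra_columns.reset_index(drop=True)], axis=1)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time_years", event_col="event")
    s = cph.summary
    hr = pd.DataFrame(
        {
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxFit(
        coefficients=s["coef"].copy(),
        hr=hr,
        loglik=float(cph.log_likelihood_),
        n=len(df),
        n_events=int(df["event"].sum()),
        covariate_spec=model if isinstance(model, str) else "+".join(covariates),
        _fitter=cph,
    )


def interaction_test(
    records: pd.DataFrame,
    clinical: pd.DataFrame,
    assignment: PhenogroupAssignment,
    factor: str,
    model: str | list[str] = "M1",
) -> dict:
    """Likelihood-ratio test for phenogroup x factor interaction.

    Fits the base model (with the factor as a main effect) and the model
    adding (k-1) x (levels-1) product terms; reports the chi-square LRT
    statistic, its df and p, and per-term Wald p-values from the full fit.
    """
    covariates = MODEL_PRESETS[model] if isinstance(model, str) else list(model)
    if factor not in covariates:
        covariates = covariates + [factor]
    base = cox_fit(records, clinical, assignment, model=covariates)

    df = _build_design(records, clinical, assignment, covariates)
    pheno_cols = [c for c in df.columns if c.startswith("phenogroup_")]
    fac = df[factor]
    levels = sorted(fac.unique())
    if len(levels) < 2:
        raise SurvivalError(f"factor {factor!r} has a single level")
    inter = pd.DataFrame(index=df.index)
    for pc in pheno_cols:
        for lv in levels[1:]:
            lv_str = f"{lv:g}" if isinstance(lv, float) else str(lv)
            inter[f"{pc}:{factor}_{lv_str}"] = df[pc] * (fac == lv).astype(int)
    full_df = pd.concat([df, inter], axis=1)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(full_df, duration_col="time_years", event_col="event")
    lrt = 2.0 * (cph.log_likelihood_ - base.loglik)
    dof = len(inter.columns)
    p = float(stats.chi2.sf(max(lrt, 0.0), dof))
    wald = {c: float(cph.summary.loc[c, "p"]) for c in inter.columns}
    return {
        "chi2": float(max(lrt, 0.0)),
        "df": dof,
        "p": p,
        "wald_p": wald,
        "base_loglik": base.loglik,
        "full_loglik": float(cph.log_likelihood_),
    }


def survival_by_strata(
    records: pd.DataFrame,
    assignment: PhenogroupAssignment,
    strata: pd.Series | None = None,
) -> dict[tuple, KMCurve]:
    """KM curve per (phenogroup x stratum) cell; empty cells are omitted.

    With ``strata=None`` returns one curve per phenogroup. Cells partition
    the cohort: per-cell n sums to the total.
    """
    records = _check_records(records)
    labels = assignment.labels.reindex(records["sample_id"])
    if labels.isna().any():
        raise SurvivalError("assignment does not cover all survival records")
    curves: dict[tuple, KMCurve] = {}
    if strata is None:
        strat_vals = pd.Series("all", index=records.index)
    else:
        strat_vals = pd.Series(
            strata.reindex(records["sample_id"]).to_numpy(), index=records.index
        )
    for g in sorted(labels.unique()):
        for s in sorted(pd.unique(strat_vals)):
            mask = (labels.to_numpy() == g) & (strat_vals.to_numpy() == s)
            if mask.sum() == 0:
                warnings.warn(f"empty cell (phenogroup {g}, stratum {s})",
                              stacklevel=2)
                continue
            curves[(int(g), s)] = km_estimate(
                records.loc[mask], group_label=f"phenogroup {int(g)} | {s}"
            )
    return curves


def km_curves_frame(curves: dict[tuple, KMCurve], at: float = 5.0) -> pd.DataFrame:
    """Tabulate S(t) with CI and cohort sizes for a set of KM curves."""
    rows = []
    for key, c in curves.items():
        lo, hi = c.ci_at(at)
        rows.append(
            {
                "cell": str(key),
                "n": c.n,
                "n_events": c.n_events,
                f"survival_{at:g}y": c.survival_at(at),
                "ci_lower": lo,
                "ci_upper": hi,
            }
        )
    return pd.DataFrame(rows)
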