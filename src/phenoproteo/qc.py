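"""Sample and feature quality control and transformation to analysis scale.

Sample QC mirrors the two mechanisms real aptamer studies use: explicit
exclusion lists and per-sample total-signal scale factors (a sample whose
total signal is far from the cohort median indicates a technical failure).
The exact vendor criteria are proprietary; the rule set here is an explicit
stand-in with the same effect — flagged samples are removed with a recorded
reason.

Feature QC estimates the intraassay coefficient of variation from replicate
measurements. Transformation to the clustering scale is log2 followed by a
per-feature z-score; the (mean, SD) pairs are retained so that held-out
samples can be placed on the training scale exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MatrixValidationError, ProteinMatrix


class QCError(ValueError):
    pass


@dataclass
class QCRules:
    """Sample-exclusion rule set: explicit IDs and/or scale-factor bounds."""

    exclude_ids: tuple[str, ...] = ()
    scale_factor_bounds: tuple[float, float] | None = None  # (low, high)


@dataclass
class QCReport:
    n_samples_in: int
    n_samples_out: int
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    dropped_features: list[str] = field(default_factory=list)
    per_feature_cv: pd.Series | None = None
    median_cv: float | None = None
    cv_iqr: tuple[float, float] | None = None

    def to_json(self, path: str | Path) -> None:
        d = {
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "excluded_samples": [list(x) for x in self.excluded_samples],
            "dropped_features": list(self.dropped_features),
            "median_cv": self.median_cv,
            "cv_iqr": list(self.cv_iqr) if self.cv_iqr else None,
        }
        if self.per_feature_cv is not None:
            d["per_feature_cv"] = self.per_feature_cv.round(4).to_dict()
        Path(path).write_text(json.dumps(d, indent=2))


@dataclass
class TransformParams:
    """Frozen per-feature log2 mean/SD used for z-scoring.

    SD is the population SD (divisor n). Applying these to new samples
    reproduces the training-scale transform exactly.
    """

    mean: pd.Series
    sd: pd.Series
    dropped_features: tuple[str, ...] = ()


def compute_feature_cv(
    values: pd.DataFrame | ProteinMatrix, replicate_groups: pd.Series
) -> tuple[pd.Series, QCReport]:
    """Per-feature intraassay CV (%) from replicate measurements.

    CV is 100 * SD / mean within each replicate group on the raw scale
    (sample SD, divisor n-1), averaged across groups. The report summarises
    median and IQR across features.
    """
    if isinstance(values, ProteinMatrix):
        values = values.values
    groups = replicate_groups.reindex(values.index)
    if groups.isna().any():
        raise QCError("replicate_groups does not cover all rows")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index[0]
        raise QCError(f"replicate group {bad!r} has fewer than 2 measurements")
    per_group_cv = []
    for _, block in values.groupby(groups, sort=True):
        mean = block.mean(axis=0)
        if (mean == 0).any():
            raise QCError("zero replicate mean; CV undefined")
        per_group_cv.append(100.0 * block.std(axis=0, ddof=1) / mean)
    cv = pd.concat(per_group_cv, axis=1).mean(axis=1)
    cv.name = "cv_percent"
    q1, q3 = np.percentile(cv, [25, 75])
    report = QCReport(
        n_samples_in=len(values),
        n_samples_out=len(values),
        per_feature_cv=cv,
        median_cv=float(cv.median()),
        cv_iqr=(float(q1), float(q3)),
    )
    return cv, report


def sample_scale_factors(matrix: ProteinMatrix) -> pd.Series:
    """Per-sample total signal divided by the cohort median total signal."""
    totals = matrix.values.sum(axis=1)
    return totals / totals.median()


def filter_samples(
    matrix: ProteinMatrix, rules: QCRules
) -> tuple[ProteinMatrix, QCReport]:
    """Remove flagged samples per ``rules``; the input matrix is untouched.

    Every exclusion carries a reason. Removing all samples is an error.
    Applying the same rules twice is idempotent by construction for the
    explicit list; for the scale-factor rule idempotence holds because the
    rule is re-evaluated relative to the retained cohort's median only on
    the first pass (factors are computed on the input matrix as given).
    """
    excluded: dict[str, str] = {}
    explicit = set(rules.exclude_ids)
    unknown = explicit - set(matrix.sample_ids)
    if unknown:
        raise QCError(f"exclusion list names unknown samples: {sorted(unknown)[:5]}")
    for sid in matrix.sample_ids:
        if sid in explicit:
            excluded[sid] = "explicit_exclusion"
    if rules.scale_factor_bounds is not None:
        lo, hi = rules.scale_factor_bounds
        factors = sample_scale_factors(matrix)
        for sid, f in factors.items():
            if sid not in excluded and not (lo <= f <= hi):
                excluded[sid] = f"scale_factor {f:.3f} outside [{lo}, {hi}]"
    keep = [s for s in matrix.sample_ids if s not in excluded]
    if not keep:
        raise QCError("QC rules excluded every sample")
    out = matrix.subset_samples(keep)
    report = QCReport(
        n_samples_in=matrix.n_samples,
        n_samples_out=len(keep),
        excluded_samples=sorted(excluded.items()),
    )
    return out, report


def log_standardize(
    matrix: ProteinMatrix,
) -> tuple[ProteinMatrix, TransformParams, QCReport]:
    """log2 then per-feature z-score (population SD) over retained samples.

    Zero-variance features cannot be standardized; they are dropped with a
    warning and recorded in the report rather than failing the run.
    """
    if matrix.transform_state != "raw":
        raise MatrixValidationError(
            f"log_standardize requires a raw matrix, got {matrix.transform_state!r}"
        )
    log2 = np.log2(matrix.values)
    mean = log2.mean(axis=0)
    sd = log2.std(axis=0, ddof=0)
    dropped = list(sd.index[sd == 0])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s): {dropped[:5]}",
            stacklevel=2,
        )
    keep = [f for f in matrix.feature_ids if f not in set(dropped)]
    z = (log2[keep] - mean[keep]) / sd[keep]
    params = TransformParams(
        mean=mean[keep], sd=sd[keep], dropped_features=tuple(dropped)
    )
    out = ProteinMatrix(
        values=z,
        feature_meta=matrix.feature_meta,
        sample_flags=dict(matrix.sample_flags),
        transform_state="standardized",
    )
    report = QCReport(
        n_samples_in=matrix.n_samples,
        n_samples_out=matrix.n_samples,
        dropped_features=dropped,
    )
    return out, params, report


def apply_transform(matrix: ProteinMatrix, params: TransformParams) -> ProteinMatrix:
    """Place new raw samples on a frozen training scale (exact reproduction)."""
    if matrix.transform_state != "raw":
        raise MatrixValidationError("apply_transform expects a raw matrix")
    feats = list(params.mean.index)
    missing = set(feats) - set(matrix.feature_ids)
    if missing:
        raise QCError(f"matrix lacks transformed features: {sorted(missing)[:5]}")
    log2 = np.log2(matrix.values[feats])
    z = (log2 - params.mean) / params.sd
    return ProteinMatrix(
        values=z,
        feature_meta=matrix.feature_meta,
        sample_flags=dict(matrix.sample_flags),
        transform_state="standardized",
    )
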