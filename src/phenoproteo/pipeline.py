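"""End-to-end phenomapping: one model object, one results object.

:class:`PhenomapModel` bundles the abundance matrix with optional clinical
and survival tables and the pipeline parameters; ``fit(seed)`` runs sample
QC, log2 z-scoring, MAD/module reduction, consensus clustering with PAC
k selection, and returns a :class:`PhenomapResults` carrying every
intermediate artifact plus convenience methods for validation statistics,
feature importance and survival contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from . import io as pio
from .cluster import (
    ConsensusResult,
    PhenogroupAssignment,
    assign_by_centroid,
    consensus_cluster,
)
from .config import PipelineParams
from .dimred import ReductionResult, reduce_features, reduction_to_dict
from .importance import (
    ImportanceRanking,
    cluster_on_top,
    permutation_importance,
    phenogroup_expression_profile,
)
from .matrix import ProteinMatrix, align_by_sample_id
from .qc import QCReport, QCRules, TransformParams, filter_samples, log_standardize
from .survival import CoxFit, KMCurve, cox_fit, km_estimate, survival_by_strata
from .validate import (
    IGPResult,
    in_group_proportion,
    internal_validation,
)


@dataclass
class PhenomapResults:
    """Everything the fitted phenomapping pipeline produced."""

    qc_report: QCReport
    transform: TransformParams
    reduction: ReductionResult
    consensus: ConsensusResult
    assignment: PhenogroupAssignment
    centroids: pd.DataFrame
    std_matrix: ProteinMatrix
    raw_matrix: ProteinMatrix
    clinical: pd.DataFrame | None = None
    survival: pd.DataFrame | None = None
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0

    @property
    def selected_values(self) -> pd.DataFrame:
        return self.std_matrix.values[self.reduction.selected_feature_ids]

    def summary(self) -> str:
        sizes = self.assignment.group_sizes()
        lines = [
            "Phenomapping results",
            "====================",
            f"samples (post-QC):      {self.std_matrix.n_samples}"
            f" (excluded {len(self.qc_report.excluded_samples)})",
            f"features selected:      {len(self.reduction.selected_feature_ids)}"
            f" of {self.raw_matrix.n_features}"
            f" (MAD fraction {self.params.mad_fraction},"
            f" |r| >= {self.params.corr_threshold})",
            f"chosen k (PAC rule):    {self.consensus.chosen_k}"
            f" (stable ks: {self.consensus.stable_ks or 'none'})",
            "PAC by k:               "
            + ", ".join(
                f"{k}: {self.consensus.pac[k]:.3f}" for k in self.consensus.k_values
            ),
            "phenogroup sizes:       "
            + ", ".join(f"{g}: n={n}" for g, n in sizes.items()),
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------------ #

    def igp(self) -> IGPResult:
        """In-group proportion of each phenogroup on the selected features."""
        return in_group_proportion(self.selected_values, self.assignment)

    def internal_validation(self, fraction: float = 0.5, seed: int | None = None):
        """Train/validation split mirror (centroid transfer + IGP)."""
        return internal_validation(
            self.raw_matrix,
            self.reduction.selected_feature_ids,
            k=self.consensus.chosen_k,
            fraction=fraction,
            seed=self.seed if seed is None else seed,
            n_init=self.params.n_init,
        )

    def importance(self, n_permutations: int = 50, seed: int | None = None
                   ) -> ImportanceRanking:
        return permutation_importance(
            self.selected_values,
            self.assignment,
            self.centroids,
            n_permutations=n_permutations,
            seed=self.seed if seed is None else seed,
        )

    def cluster_on_top_features(self, ranking: ImportanceRanking, m: int = 10,
                                seed: int | None = None):
        return cluster_on_top(
            self.selected_values, ranking, m, self.consensus.chosen_k,
            self.assignment, seed=self.seed if seed is None else seed,
            n_init=self.params.n_init,
        )

    def expression_profile(self, features: list[str] | None = None) -> pd.DataFrame:
        return phenogroup_expression_profile(
            self.selected_values, self.assignment, features
        )

    def km_by_phenogroup(self) -> dict[tuple, KMCurve]:
        self._require_survival()
        return survival_by_strata(self._aligned_survival(), self.assignment)

    def km_overall(self) -> KMCurve:
        self._require_survival()
        return km_estimate(self._aligned_survival(), group_label="overall")

    def cox(self, model: str | list[str] = "M1") -> CoxFit:
        self._require_survival()
        return cox_fit(
            self._aligned_survival(), self.clinical, self.assignment, model=model
        )

    def assign_new(self, new_raw: ProteinMatrix) -> PhenogroupAssignment:
        """Assign new raw samples via the frozen transform and centroids."""
        from .qc import apply_transform

        std = apply_transform(
            new_raw.subset_features(list(self.transform.mean.index)), self.transform
        )
        return assign_by_centroid(
            std.values[list(self.centroids.columns)], self.centroids
        )

    # ------------------------------------------------------------------ #

    def _require_survival(self) -> None:
        if self.survival is None:
            raise ValueError("no survival table attached to this model")

    def _aligned_survival(self) -> pd.DataFrame:
        surv = self.survival
        return surv[surv["sample_id"].isin(self.std_matrix.sample_ids)].reset_index(
            drop=True
        )

    def write(self, out_dir: str | Path) -> None:
        """Serialize assignment, reduction and consensus summaries."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_assignment(self.assignment, out / "phenogroups.csv")
        (out / "reduction.json").write_text(
            json.dumps(pio._jsonable(reduction_to_dict(self.reduction)), indent=2)
        )
        self.consensus.summary().to_csv(out / "consensus_summary.csv", index=False)
        self.qc_report.to_json(out / "qc_report.json")
        pd.Series(self.reduction.selected_feature_ids, name="feature_id").to_csv(
            out / "selected_features.tsv", sep="\t", index=False
        )


class PhenomapModel:
    """Phenomapping model over a raw abundance matrix.

    Parameters
    ----------
    matrix
        Raw (strictly positive) samples x features matrix.
    clinical, survival
        Optional tables keyed by ``sample_id``; aligned by ID, never by
        row order.
    params
        :class:`~phenoproteo.config.PipelineParams`.
    qc_rules
        Sample-exclusion rules applied before transformation.
    """

    def __init__(
        self,
        matrix: ProteinMatrix,
        clinical: pd.DataFrame | None = None,
        survival: pd.DataFrame | None = None,
        params: PipelineParams | None = None,
        qc_rules: QCRules | None = None,
    ):
        self.matrix = matrix
        self.clinical = clinical
        self.survival = survival
        self.params = params or PipelineParams()
        self.qc_rules = qc_rules or QCRules(
            scale_factor_bounds=self.params.scale_factor_bounds
        )
        if clinical is not None:
            align_by_sample_id(matrix, clinical)
        if survival is not None:
            align_by_sample_id(matrix, survival)

    @classmethod
    def from_cohort(cls, cohort, params: PipelineParams | None = None,
                    qc_rules: QCRules | None = None) -> "PhenomapModel":
        """Build from a :class:`~phenoproteo.synth.SyntheticCohort`."""
        return cls(
            matrix=cohort.matrix,
            clinical=cohort.clinical,
            survival=cohort.survival,
            params=params,
            qc_rules=qc_rules,
        )

    @classmethod
    def from_files(
        cls,
        matrix_path: str | Path,
        clinical_path: str | Path | None = None,
        survival_path: str | Path | None = None,
        params: PipelineParams | None = None,
        dialect: str = "tsv_wide",
    ) -> "PhenomapModel":
        matrix = pio.read_matrix(matrix_path, dialect=dialect)
        clinical = pio.read_clinical(clinical_path) if clinical_path else None
        survival = pio.read_survival(survival_path) if survival_path else None
        return cls(matrix, clinical, survival, params=params)

    def fit(self, seed: int = 0) -> PhenomapResults:
        """Run QC -> transform -> reduce -> consensus cluster."""
        p = self.params
        filtered, qc_report = filter_samples(self.matrix, self.qc_rules)
        std, transform, std_report = log_standardize(filtered)
        qc_report.dropped_features = std_report.dropped_features
        reduction = reduce_features(
            filtered,
            mad_fraction=p.mad_fraction,
            corr_threshold=p.corr_threshold,
            corr_method=p.corr_method,
            hub_rule=p.hub_rule,
            seed=seed,
            n_rounds=p.n_reduction_rounds,
        )
        selected = [
            f for f in reduction.selected_feature_ids
            if f in set(std.feature_ids)
        ]
        reduction.selected_feature_ids = selected
        consensus = consensus_cluster(
            std.values[selected],
            k_range=p.k_range,
            n_resamples=p.n_resamples,
            subsample_fraction=p.subsample_fraction,
            seed=seed,
            n_init=p.n_init,
        )
        return PhenomapResults(
            qc_report=qc_report,
            transform=transform,
            reduction=reduction,
            consensus=consensus,
            assignment=consensus.final_labels,
            centroids=consensus.centroids,
            std_matrix=std,
            raw_matrix=filtered,
            clinical=self.clinical,
            survival=self.survival,
            params=p,
            seed=seed,
        )
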