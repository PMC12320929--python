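"""Cluster agreement statistics, internal validation, and sensitivity reruns.

Agreement between two partitions is measured three ways:

* **Rand index** — fraction of sample pairs treated the same way (together
  in both or apart in both) by the two partitions;
* **adjusted Rand index** — Rand corrected for chance agreement;
* **concordance** — the maximum fraction of samples with matching labels
  over all injections of the smaller label set into the larger, found by
  optimal assignment on the confusion matrix. Unlike the Rand index this
  yields an explicit group-to-group matching.

The in-group proportion (IGP) of a cluster is the fraction of its samples
whose nearest neighbour (Euclidean, excluding self, on the standardized
selected-feature space) belongs to the same cluster — a nearest-neighbour
reproducibility statistic for cluster validation.

Sensitivity reruns repeat the reduce-and-cluster pipeline under perturbed
settings (randomized hubs, alternative MAD/correlation thresholds, feature
exclusions) and report agreement with the primary assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score, rand_score

from .cluster import PhenogroupAssignment, final_kmeans
from .dimred import ReductionResult, reduce_features
from .matrix import ProteinMatrix
from .qc import TransformParams, apply_transform, log_standardize


class ValidationError(ValueError):
    pass


@dataclass
class AgreementStats:
    concordance: float
    rand: float
    adjusted_rand: float
    matching: dict[int, int] = field(default_factory=dict)  # a-label -> b-label


@dataclass
class IGPResult:
    per_group_igp: dict[int, float]
    n_per_group: dict[int, int]
    distance_metric: str = "euclidean"

    @property
    def min_igp(self) -> float:
        return min(self.per_group_igp.values())


def _paired_labels(labels_a, labels_b) -> tuple[np.ndarray, np.ndarray]:
    a = labels_a.labels if isinstance(labels_a, PhenogroupAssignment) else labels_a
    b = labels_b.labels if isinstance(labels_b, PhenogroupAssignment) else labels_b
    a = pd.Series(a)
    b = pd.Series(b)
    if isinstance(a.index, pd.RangeIndex) or isinstance(b.index, pd.RangeIndex):
        if len(a) != len(b):
            raise ValidationError("label vectors differ in length")
        return a.to_numpy(), b.to_numpy()
    if set(a.index) != set(b.index):
        raise ValidationError("partitions cover different sample sets")
    b = b.loc[a.index]
    return a.to_numpy(), b.to_numpy()


def rand_index(labels_a, labels_b) -> float:
    """Rand index: (agreeing pairs) / (all pairs); label-permutation invariant."""
    a, b = _paired_labels(labels_a, labels_b)
    return float(rand_score(a, b))


def adjusted_rand(labels_a, labels_b) -> float:
    """Rand index corrected for chance (expected-index adjustment)."""
    a, b = _paired_labels(labels_a, labels_b)
    return float(adjusted_rand_score(a, b))


def concordance(labels_a, labels_b) -> AgreementStats:
    """Optimal-matching agreement between two partitions.

    Maximises the matched-sample fraction over injections of the smaller
    label set into the larger via the Hungarian algorithm on the confusion
    matrix. Also reports Rand and adjusted Rand.
    """
    a, b = _paired_labels(labels_a, labels_b)
    ua, ub = np.unique(a), np.unique(b)
    conf = np.zeros((len(ua), len(ub)))
    for i, la in enumerate(ua):
        for j, lb in enumerate(ub):
            conf[i, j] = np.sum((a == la) & (b == lb))
    rows, cols = linear_sum_assignment(-conf)
    agree = conf[rows, cols].sum()
    matching = {int(ua[i]): int(ub[j]) for i, j in zip(rows, cols)}
    return AgreementStats(
        concordance=float(agree / len(a)),
        rand=float(rand_score(a, b)),
        adjusted_rand=float(adjusted_rand_score(a, b)),
        matching=matching,
    )


def in_group_proportion(
    matrix: ProteinMatrix | pd.DataFrame, assignment: PhenogroupAssignment
) -> IGPResult:
    """IGP per group: share of members whose nearest neighbour is a co-member."""
    vals = matrix.values if isinstance(matrix, ProteinMatrix) else matrix
    labels = assignment.labels.loc[vals.index].to_numpy()
    sizes = pd.Series(labels).value_counts()
    singletons = sizes[sizes < 2]
    if len(singletons):
        raise ValidationError(
            f"group {int(singletons.index[0])} has fewer than 2 samples"
        )
    x = vals.to_numpy()
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    nn = np.argmin(d, axis=1)
    same = labels[nn] == labels
    per_group = {
        int(g): float(same[labels == g].mean()) for g in np.unique(labels)
    }
    n_per = {int(g): int((labels == g).sum()) for g in np.unique(labels)}
    return IGPResult(per_group_igp=per_group, n_per_group=n_per)


def split_train_validation(
    sample_ids: list[str], fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Seeded uniform split without replacement; train gets ``ceil(f * n)``."""
    if not (0 < fraction < 1):
        raise ValidationError("fraction must be in (0, 1)")
    n = len(sample_ids)
    n_train = int(np.ceil(fraction * n))
    if n_train == 0 or n_train == n:
        raise ValidationError("split leaves one side empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [sample_ids[i] for i in sorted(perm[:n_train])]
    valid = [sample_ids[i] for i in sorted(perm[n_train:])]
    return train, valid


@dataclass
class InternalValidationResult:
    train_assignment: PhenogroupAssignment
    validation_assignment: PhenogroupAssignment
    train_igp: IGPResult
    validation_igp: IGPResult
    transform: TransformParams


def internal_validation(
    raw_matrix: ProteinMatrix,
    selected_features: list[str],
    k: int,
    fraction: float = 0.5,
    seed: int = 0,
    n_init: int = 50,
) -> InternalValidationResult:
    """Train/validation mirror of the discovery pipeline at fixed features.

    The cohort is split; the log2 z-score transform is re-estimated on the
    training half and frozen; the training half is clustered at k and the
    validation half is assigned by training centroids; IGP is computed on
    each half in its own (training-scaled) feature space.
    """
    from .cluster import assign_by_centroid

    train_ids, valid_ids = split_train_validation(
        raw_matrix.sample_ids, fraction, seed
    )
    train_raw = raw_matrix.subset_samples(train_ids).subset_features(
        selected_features
    )
    valid_raw = raw_matrix.subset_samples(valid_ids).subset_features(
        selected_features
    )
    train_std, params, _ = log_standardize(train_raw)
    valid_std = apply_transform(valid_raw, params)
    train_assign, centroids = final_kmeans(train_std, k, seed=seed, n_init=n_init)
    valid_assign = assign_by_centroid(
        valid_std.values[list(centroids.columns)], centroids
    )
    return InternalValidationResult(
        train_assignment=train_assign,
        validation_assignment=valid_assign,
        train_igp=in_group_proportion(train_std.values[list(centroids.columns)],
                                      train_assign),
        validation_igp=in_group_proportion(valid_std.values[list(centroids.columns)],
                                           valid_assign),
        transform=params,
    )


@dataclass
class SensitivityDistribution:
    per_rep: list[AgreementStats]

    def median_concordance(self) -> float:
        return float(np.median([s.concordance for s in self.per_rep]))

    def median_rand(self) -> float:
        return float(np.median([s.rand for s in self.per_rep]))

    def iqr(self, stat: str = "concordance") -> tuple[float, float]:
        vals = [getattr(s, stat) for s in self.per_rep]
        q1, q3 = np.percentile(vals, [25, 75])
        return float(q1), float(q3)

    def to_dict(self) -> dict:
        return {
            "n_reps": len(self.per_rep),
            "median_concordance": self.median_concordance(),
            "median_rand": self.median_rand(),
            "concordance_iqr": list(self.iqr("concordance")),
            "rand_iqr": list(self.iqr("rand")),
        }


def hub_randomization_sensitivity(
    std_matrix: ProteinMatrix,
    reduction: ReductionResult,
    primary: PhenogroupAssignment,
    n_reps: int,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> SensitivityDistribution:
    """Re-draw hubs in modules of >= 3 correlated features, recluster, compare.

    Per repetition: hubs of multi-member modules (size >= 3) are redrawn
    uniformly, k-means reruns at fixed k on the new hub set, and agreement
    with the primary assignment is recorded. Modules of size < 3 keep
    their primary hub. If no module has >= 3 members every repetition
    reproduces the primary run (agreement 1) and a degenerate warning
    applies.
    """
    vals = std_matrix.values if isinstance(std_matrix, ProteinMatrix) else std_matrix
    rng = np.random.default_rng(seed)
    reps = []
    has_big = any(m.size >= 3 for m in reduction.modules)
    for rep in range(n_reps):
        if has_big:
            feats = []
            for m in reduction.modules:
                if m.size >= 3:
                    members = list(m.member_feature_ids)
                    feats.append(members[int(rng.integers(len(members)))])
                else:
                    feats.append(m.hub_feature_id)
        else:
            feats = [m.hub_feature_id for m in reduction.modules]
        assign, _ = final_kmeans(
            vals[feats], k, seed=int(rng.integers(2**31 - 1)), n_init=n_init
        )
        reps.append(concordance(primary, assign))
    return SensitivityDistribution(per_rep=reps)


@dataclass
class GridCell:
    mad_fraction: float
    corr_threshold: float
    stats: AgreementStats | None
    n_selected: int
    failed: bool = False


def threshold_grid_sensitivity(
    raw_matrix: ProteinMatrix,
    std_values: pd.DataFrame,
    primary: PhenogroupAssignment,
    k: int,
    grid: list[tuple[float, float]] | None = None,
    corr_method: str = "spearman",
    seed: int = 0,
    n_init: int = 10,
) -> list[GridCell]:
    """Rerun reduce-and-cluster over a (MAD fraction x corr threshold) grid.

    Reduction runs on the raw/log2 matrix (MAD is a log2-scale quantity);
    clustering runs on the corresponding columns of the standardized
    matrix. The default 12-cell grid crosses fractions {0.2, 0.3, 0.4}
    with thresholds {0.6, 0.7, 0.8, 0.9}. Cells yielding fewer than k
    features are marked failed and skipped rather than aborting the run.
    """
    if grid is None:
        grid = [(f, t) for f in (0.2, 0.3, 0.4) for t in (0.6, 0.7, 0.8, 0.9)]
    if not grid:
        raise ValidationError("empty sensitivity grid")
    cells = []
    rng = np.random.default_rng(seed)
    for frac, tau in grid:
        red = reduce_features(
            raw_matrix, mad_fraction=frac, corr_threshold=tau,
            corr_method=corr_method,
        )
        feats = [f for f in red.selected_feature_ids if f in std_values.columns]
        if len(feats) < k:
            cells.append(GridCell(frac, tau, None, len(feats), failed=True))
            continue
        assign, _ = final_kmeans(
            std_values[feats], k, seed=int(rng.integers(2**31 - 1)), n_init=n_init
        )
        cells.append(GridCell(frac, tau, concordance(primary, assign), len(feats)))
    return cells


def feature_exclusion_sensitivity(
    std_matrix: ProteinMatrix | pd.DataFrame,
    selected_features: list[str],
    exclude: list[str],
    primary: PhenogroupAssignment,
    k: int,
    seed: int = 0,
    n_init: int = 50,
) -> AgreementStats:
    """Recluster at fixed k after dropping named features; compare to primary."""
    unknown = set(exclude) - set(selected_features)
    if unknown:
        raise ValidationError(
            f"excluded features not in selected set: {sorted(unknown)[:5]}"
        )
    feats = [f for f in selected_features if f not in set(exclude)]
    if not feats:
        raise ValidationError("exclusion empties the feature set")
    vals = std_matrix.values if isinstance(std_matrix, ProteinMatrix) else std_matrix
    assign, _ = final_kmeans(vals[feats], k, seed=seed, n_init=n_init)
    return concordance(primary, assign)
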