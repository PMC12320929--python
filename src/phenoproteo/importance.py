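"""Permutation variable importance for phenogroup definition.

A feature matters for a clustering if scrambling it across samples moves
samples between phenogroups. Importance is defined against nearest-centroid
re-assignment: permute one feature column, re-assign every sample to its
nearest phenogroup centroid, and record the fraction of samples whose label
changes relative to the unpermuted assignment; the score is the mean over
permutations. This is self-contained and deterministic given a seed — no
auxiliary classifier is fitted (a classifier backend could be slotted in as
an alternative scorer). A feature that is constant across samples scores
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import PhenogroupAssignment, final_kmeans
from .matrix import ProteinMatrix
from .validate import AgreementStats, concordance


class ImportanceError(ValueError):
    pass


@dataclass
class ImportanceRanking:
    scores: pd.Series  # feature_id -> mean misassignment fraction
    ranks: pd.Series  # feature_id -> 1-based rank (ties broken by feature_id)
    n_permutations: int
    seed: int

    def top(self, m: int) -> list[str]:
        return list(self.ranks.sort_values().index[:m])

    def to_frame(self, feature_meta: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"score": self.scores, "rank": self.ranks})
        if feature_meta is not None and "target_name" in feature_meta.columns:
            df["target_name"] = feature_meta["target_name"].reindex(df.index)
        return df.sort_values("rank")


def _values(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ProteinMatrix) else matrix


def permutation_importance(
    matrix: ProteinMatrix | pd.DataFrame,
    assignment: PhenogroupAssignment,
    centroids: pd.DataFrame,
    n_permutations: int = 50,
    seed: int = 0,
) -> ImportanceRanking:
    """Mean label-change fraction under per-feature column permutation.

    Uses the identity that permuting one column only shifts each sample's
    squared distance to centroid g by terms involving that column, so the
    nearest-centroid argmin can be updated from cached cross-products
    instead of recomputing full distance matrices.
    """
    if n_permutations < 1:
        raise ImportanceError("n_permutations must be >= 1")
    vals = _values(matrix)
    if list(vals.columns) != list(centroids.columns):
        raise ImportanceError("matrix and centroid feature spaces differ")
    # canonical sample order: makes scores exactly invariant to joint
    # reordering of the matrix and its assignment
    vals = vals.sort_index()
    x = vals.to_numpy()
    c = centroids.to_numpy()  # k x p
    base_labels = assignment.labels.loc[vals.index].to_numpy()
    n, p = x.shape
    # argmin_g ||x - c_g||^2 = argmin_g (||c_g||^2 - 2 x . c_g)
    cross = x @ c.T  # n x k
    c_norm2 = (c**2).sum(axis=1)  # k

    rng = np.random.default_rng(seed)
    scores = np.zeros(p)
    for j in range(p):
        col = x[:, j]
        if np.all(col == col[0]):
            scores[j] = 0.0
            # burn the permutation draws so scores of other features do not
            # depend on which features happen to be constant
            for _ in range(n_permutations):
                rng.permutation(n)
            continue
        changed = 0.0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            delta = np.outer(col[perm] - col, c[:, j])  # n x k
            nearest = np.argmin(c_norm2 - 2.0 * (cross + delta), axis=1)
            labels = centroids.index.to_numpy()[nearest]
            changed += np.mean(labels != base_labels)
        scores[j] = changed / n_permutations

    score_s = pd.Series(scores, index=vals.columns, name="importance")
    order = sorted(vals.columns, key=lambda f: (-score_s[f], f))
    ranks = pd.Series(
        {f: i + 1 for i, f in enumerate(order)}, name="rank"
    ).reindex(vals.columns)
    return ImportanceRanking(
        scores=score_s, ranks=ranks, n_permutations=n_permutations, seed=seed
    )


def cluster_on_top(
    matrix: ProteinMatrix | pd.DataFrame,
    ranking: ImportanceRanking,
    m: int,
    k: int,
    primary: PhenogroupAssignment,
    seed: int = 0,
    n_init: int = 50,
) -> tuple[PhenogroupAssignment, AgreementStats]:
    """Re-cluster using only the top-m importance-ranked features."""
    vals = _values(matrix)
    if m > vals.shape[1]:
        raise ImportanceError(f"m={m} exceeds feature count {vals.shape[1]}")
    if m < k:
        raise ImportanceError(f"m={m} < k={k}: clustering underdetermined")
    feats = ranking.top(m)
    assign, _ = final_kmeans(vals[feats], k, seed=seed, n_init=n_init)
    return assign, concordance(primary, assign)


def feature_covariate_correlations(
    matrix: ProteinMatrix | pd.DataFrame,
    features: list[str],
    covariates: pd.DataFrame,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlation of each feature with each covariate column.

    Covariates are aligned to the matrix rows by index. Constant covariates
    yield NaN entries flagged in the ``defined`` column. Requires >= 10
    paired observations.
    """
    vals = _values(matrix)
    cov = covariates.loc[vals.index]
    rows = []
    for f in features:
        xf = vals[f].to_numpy()
        for cname in cov.columns:
            y = pd.to_numeric(cov[cname], errors="coerce").to_numpy()
            ok = np.isfinite(xf) & np.isfinite(y)
            if ok.sum() < 10:
                raise ImportanceError(
                    f"fewer than 10 paired observations for ({f}, {cname})"
                )
            if np.all(y[ok] == y[ok][0]):
                rows.append((f, cname, np.nan, int(ok.sum()), False))
                continue
            if method == "spearman":
                r = stats.spearmanr(xf[ok], y[ok]).statistic
            elif method == "pearson":
                r = stats.pearsonr(xf[ok], y[ok]).statistic
            else:
                raise ImportanceError(f"unknown method {method!r}")
            rows.append((f, cname, float(r), int(ok.sum()), True))
    return pd.DataFrame(
        rows, columns=["feature_id", "covariate", "correlation", "n", "defined"]
    )


def phenogroup_expression_profile(
    matrix: ProteinMatrix | pd.DataFrame,
    assignment: PhenogroupAssignment,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Group-wise mean expression (standardized units) per feature.

    Returns one row per feature with per-group means and the argmax group —
    the group in which the feature is most highly expressed.
    """
    vals = _values(matrix)
    feats = features if features is not None else list(vals.columns)
    labels = assignment.labels.loc[vals.index]
    means = vals[feats].groupby(labels).mean().T  # features x groups
    means.columns = [int(g) for g in means.columns]
    means["argmax_group"] = means.idxmax(axis=1).astype(int)
    means.index.name = "feature_id"
    return means
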