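"""Permutation importance against a naive full-recompute oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from phenoproteo.cluster import PhenogroupAssignment, final_kmeans
from phenoproteo.importance import (
    ImportanceError,
    cluster_on_top,
    feature_covariate_correlations,
    permutation_importance,
    phenogroup_expression_profile,
)
from phenoproteo.matrix import ProteinMatrix


def _case(n=40, p=6, seed=0, constant_col=None):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, p))
    labels = np.where(np.arange(n) < n // 2, 1, 2)
    x[:, 0] += np.where(labels == 1, -2.0, 2.0)
    if constant_col is not None:
        x[:, constant_col] = 3.0
    ids = [f"S{i:03d}" for i in range(n)]
    cols = [f"F{j:02d}" for j in range(p)]
    vals = pd.DataFrame(x, index=ids, columns=cols)
    m = ProteinMatrix(values=vals, transform_state="standardized")
    assign = PhenogroupAssignment(
        labels=pd.Series(labels, index=ids, name="phenogroup"), k=2, provenance={}
    )
    centroids = pd.DataFrame(
        [x[labels == 1].mean(0), x[labels == 2].mean(0)], index=[1, 2],
        columns=cols,
    )
    return m, assign, centroids


def _naive_importance(m, assign, centroids, n_permutations, seed):
    """Same algorithm, full distance recompute per permutation."""
    vals = m.values.sort_index()
    x = vals.to_numpy()
    c = centroids.to_numpy()
    base = assign.labels.loc[vals.index].to_numpy()
    n, p = x.shape
    rng = np.random.default_rng(seed)
    scores = np.zeros(p)
    for j in range(p):
        if np.all(x[:, j] == x[0, j]):
            for _ in range(n_permutations):
                rng.permutation(n)
            continue
        changed = 0.0
        for _ in range(n_permutations):
            xp = x.copy()
            xp[:, j] = x[rng.permutation(n), j]
            lab = centroids.index.to_numpy()[cdist(xp, c).argmin(axis=1)]
            changed += np.mean(lab != base)
        scores[j] = changed / n_permutations
    return pd.Series(scores, index=vals.columns)


class TestPermutationImportance:
    def test_matches_naive_oracle_exactly(self):
        m, assign, centroids = _case(constant_col=4)
        ranking = permutation_importance(m, assign, centroids,
                                         n_permutations=15, seed=3)
        oracle = _naive_importance(m, assign, centroids, 15, seed=3)
        pd.testing.assert_series_equal(
            ranking.scores, oracle, check_names=False, atol=1e-12, rtol=0
        )

    def test_discriminating_feature_ranks_first(self):
        m, assign, centroids = _case()
        ranking = permutation_importance(m, assign, centroids,
                                         n_permutations=40, seed=0)
        assert ranking.ranks["F00"] == 1
        assert ranking.scores["F00"] > ranking.scores.drop("F00").max()

    def test_constant_feature_scores_exactly_zero(self):
        m, assign, centroids = _case(constant_col=3)
        ranking = permutation_importance(m, assign, centroids,
                                         n_permutations=10, seed=1)
        assert ranking.scores["F03"] == 0.0

    def test_ranks_are_permutation_with_lexicographic_ties(self):
        m, assign, centroids = _case(p=5, constant_col=2)
        # two constant features tie at 0 -> lexicographic order between them
        vals = m.values.copy()
        vals["F04"] = 7.0
        m = ProteinMatrix(values=vals, transform_state="standardized")
        centroids = centroids.copy()
        centroids["F04"] = 7.0
        ranking = permutation_importance(m, assign, centroids,
                                         n_permutations=5, seed=0)
        assert sorted(ranking.ranks.index) == sorted(m.feature_ids)
        assert sorted(ranking.ranks.to_numpy()) == list(range(1, 6))
        assert ranking.ranks["F02"] < ranking.ranks["F04"]

    def test_joint_sample_reorder_invariance_is_exact(self):
        m, assign, centroids = _case(seed=5)
        ranking = permutation_importance(m, assign, centroids,
                                         n_permutations=20, seed=2)
        order = list(m.values.index[::-1])
        m2 = ProteinMatrix(values=m.values.loc[order],
                           transform_state="standardized")
        assign2 = PhenogroupAssignment(
            labels=assign.labels.loc[order], k=2, provenance={}
        )
        ranking2 = permutation_importance(m2, assign2, centroids,
                                          n_permutations=20, seed=2)
        pd.testing.assert_series_equal(ranking.scores, ranking2.scores)

    def test_duplicated_columns_agree_within_mc_error(self):
        rng = np.random.default_rng(8)
        n = 60
        labels = np.where(np.arange(n) < 30, 1, 2)
        base = rng.normal(size=n) + np.where(labels == 1, -1.5, 1.5)
        x = np.column_stack([base, base, rng.normal(size=n)])
        ids = [f"S{i}" for i in range(n)]
        vals = pd.DataFrame(x, index=ids, columns=["F0", "F1", "F2"])
        m = ProteinMatrix(values=vals, transform_state="standardized")
        assign = PhenogroupAssignment(
            labels=pd.Series(labels, index=ids), k=2, provenance={}
        )
        cents = pd.DataFrame(
            [x[labels == 1].mean(0), x[labels == 2].mean(0)], index=[1, 2],
            columns=vals.columns,
        )
        n_perm = 200
        ranking = permutation_importance(m, assign, cents,
                                         n_permutations=n_perm, seed=4)
        s0, s1 = ranking.scores["F0"], ranking.scores["F1"]
        se = np.sqrt((s0 * (1 - s0) + s1 * (1 - s1)) / n_perm) + 1e-9
        assert abs(s0 - s1) <= 2 * se + 0.02

    def test_feature_space_mismatch_raises(self):
        m, assign, centroids = _case()
        with pytest.raises(ImportanceError):
            permutation_importance(
                m, assign, centroids[list(centroids.columns[:-1])],
                n_permutations=5,
            )

    def test_top_listing(self):
        m, assign, centroids = _case()
        ranking = permutation_importance(m, assign, centroids,
                                         n_permutations=10, seed=0)
        top = ranking.top(3)
        assert len(top) == 3 and top[0] == ranking.ranks.idxmin()


class TestClusterOnTop:
    def test_top_features_reproduce_partition(self):
        m, assign, centroids = _case(n=80, p=8, seed=2)
        ranking = permutation_importance(m, assign, centroids,
                                         n_permutations=30, seed=0)
        new_assign, stats = cluster_on_top(m, ranking, m=3, k=2,
                                           primary=assign, seed=0, n_init=10)
        assert stats.concordance > 0.9

    def test_m_below_k_raises(self):
        m, assign, centroids = _case()
        ranking = permutation_importance(m, assign, centroids,
                                         n_permutations=5, seed=0)
        with pytest.raises(ImportanceError):
            cluster_on_top(m, ranking, m=1, k=2, primary=assign)


class TestCovariateCorrelations:
    def test_perfect_monotone_spearman(self):
        n = 20
        ids = [f"S{i:02d}" for i in range(n)]
        vals = pd.DataFrame({"F0": np.arange(n, dtype=float) + 1}, index=ids)
        m = ProteinMatrix(values=vals, transform_state="standardized")
        cov = pd.DataFrame({"age": np.arange(n, dtype=float) ** 3}, index=ids)
        out = feature_covariate_correlations(m, ["F0"], cov, method="spearman")
        assert out["correlation"].iloc[0] == pytest.approx(1.0)

    def test_constant_covariate_flagged_undefined(self):
        n = 15
        ids = [f"S{i:02d}" for i in range(n)]
        vals = pd.DataFrame(
            {"F0": np.random.default_rng(0).normal(size=n)}, index=ids
        )
        m = ProteinMatrix(values=vals, transform_state="standardized")
        cov = pd.DataFrame({"flat": np.ones(n)}, index=ids)
        out = feature_covariate_correlations(m, ["F0"], cov)
        assert not out["defined"].iloc[0]
        assert np.isnan(out["correlation"].iloc[0])

    def test_too_few_pairs_raises(self):
        ids = [f"S{i}" for i in range(5)]
        vals = pd.DataFrame({"F0": np.arange(5.0)}, index=ids)
        m = ProteinMatrix(values=vals, transform_state="standardized")
        cov = pd.DataFrame({"age": np.arange(5.0)}, index=ids)
        with pytest.raises(ImportanceError):
            feature_covariate_correlations(m, ["F0"], cov)


class TestExpressionProfile:
    def test_argmax_group_matches_planted_shift(self):
        m, assign, _ = _case()
        prof = phenogroup_expression_profile(m, assign)
        assert prof.loc["F00", "argmax_group"] == 2  # planted +2 shift in group 2
        np.testing.assert_allclose(
            prof.loc["F00", 2],
            m.values.loc[assign.labels == 2, "F00"].mean(),
        )
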