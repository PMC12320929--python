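"""Feature reduction: MAD selection, module building, hub rules."""

import numpy as np
import pandas as pd
import pytest

from phenoproteo.dimred import (
    DimredError,
    build_modules,
    mad_select,
    reduce_features,
    reduction_to_dict,
    select_hubs,
)
from phenoproteo.matrix import ProteinMatrix


def _std_matrix(values: np.ndarray, features=None) -> ProteinMatrix:
    n, p = values.shape
    df = pd.DataFrame(
        values,
        index=[f"S{i}" for i in range(n)],
        columns=features or [f"F{j}" for j in range(p)],
    )
    return ProteinMatrix(values=df, transform_state="log2")


class TestMADSelect:
    def test_hand_computed_mad_and_order(self):
        # F0: (0,0,0,10) -> median 0, MAD 0; F1: (0,2,4,6) -> MAD 2
        # F2: (0,1,2,3) -> MAD 1
        m = _std_matrix(np.array(
            [[0.0, 0.0, 0.0], [0.0, 2.0, 1.0], [0.0, 4.0, 2.0], [10.0, 6.0, 3.0]]
        ))
        selected, mad = mad_select(m, fraction=2 / 3)
        assert mad["F0"] == 0.0 and mad["F1"] == 2.0 and mad["F2"] == 1.0
        assert selected == ["F1", "F2"]

    def test_tie_breaks_lexicographically(self):
        vals = np.tile(np.array([[0.0], [1.0], [2.0]]), (1, 3))
        m = _std_matrix(vals, features=["Fb", "Fa", "Fc"])
        selected, _ = mad_select(m, fraction=2 / 3)
        assert selected == ["Fa", "Fb"]

    def test_count_is_ceiling(self):
        m = _std_matrix(np.random.default_rng(0).normal(size=(10, 7)))
        selected, _ = mad_select(m, fraction=0.3)  # ceil(2.1) = 3
        assert len(selected) == 3

    def test_invariant_to_sample_and_feature_order(self):
        rng = np.random.default_rng(1)
        m = _std_matrix(rng.normal(size=(20, 8)))
        sel_a, _ = mad_select(m, 0.5)
        shuffled = ProteinMatrix(
            values=m.values.sample(frac=1, random_state=3)[
                list(m.values.columns[::-1])
            ],
            transform_state="log2",
        )
        sel_b, _ = mad_select(shuffled, 0.5)
        assert set(sel_a) == set(sel_b)

    def test_fraction_bounds(self):
        m = _std_matrix(np.random.default_rng(0).normal(size=(5, 3)))
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(DimredError):
                mad_select(m, bad)


class TestBuildModules:
    def _pair_matrix(self):
        # F0~F1 perfectly correlated, F2~F3 perfectly anti-correlated,
        # F4 independent noise
        rng = np.random.default_rng(5)
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        c = rng.normal(size=40)
        x = np.column_stack([a, a * 2 + 1, b, -b, c])
        return _std_matrix(x)

    def test_connected_components_oracle(self):
        m = self._pair_matrix()
        modules, corr = build_modules(m, m.feature_ids, corr_threshold=0.7)
        members = sorted(tuple(mod.member_feature_ids) for mod in modules)
        assert members == [("F0", "F1"), ("F2", "F3"), ("F4",)]

    def test_absolute_correlation_is_used(self):
        m = self._pair_matrix()
        modules, corr = build_modules(m, ["F2", "F3"], corr_threshold=0.9)
        assert corr.loc["F2", "F3"] < 0  # anti-correlated, still one module
        assert len(modules) == 1

    def test_corr_matrix_is_symmetric_unit_diagonal(self):
        m = self._pair_matrix()
        _, corr = build_modules(m, m.feature_ids)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr.to_numpy()), 1.0)

    def test_partition_independent_of_discovery_order(self):
        m = self._pair_matrix()
        modules_a, _ = build_modules(m, m.feature_ids)
        modules_b, _ = build_modules(m, list(reversed(m.feature_ids)))
        parts_a = {mod.member_feature_ids for mod in modules_a}
        parts_b = {mod.member_feature_ids for mod in modules_b}
        assert parts_a == parts_b

    def test_zero_variance_feature_raises(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        x[:, 1] = 4.0
        with pytest.raises(DimredError):
            build_modules(_std_matrix(x), ["F0", "F1", "F2"])

    def test_empty_subset_raises(self):
        m = self._pair_matrix()
        with pytest.raises(DimredError):
            build_modules(m, [])


class TestSelectHubs:
    def _chain_module(self):
        # F0-F1-F2 chain: F1 correlates strongly with both ends, the ends
        # correlate less with each other -> F1 is the connectivity hub
        rng = np.random.default_rng(7)
        mid = rng.normal(size=200)
        x = np.column_stack(
            [mid + rng.normal(0, 0.45, 200), mid, mid + rng.normal(0, 0.45, 200)]
        )
        m = _std_matrix(x)
        modules, corr = build_modules(m, m.feature_ids, corr_threshold=0.6)
        _, mad = mad_select(m, 1.0)
        return m, modules, corr, mad

    def test_max_connectivity_picks_center(self):
        _, modules, corr, mad = self._chain_module()
        assert len(modules) == 1
        res = select_hubs(modules, corr, mad, rule="max_connectivity")
        assert res.selected_feature_ids == ["F1"]

    def test_max_mad_rule(self):
        _, modules, corr, mad = self._chain_module()
        res = select_hubs(modules, corr, mad, rule="max_mad")
        expected = min(mad.index, key=lambda f: (-mad[f], f))
        assert res.selected_feature_ids == [expected]

    def test_random_rule_is_seeded(self):
        _, modules, corr, mad = self._chain_module()
        a = select_hubs(modules, corr, mad, rule="random", seed=3)
        b = select_hubs(modules, corr, mad, rule="random", seed=3)
        assert a.selected_feature_ids == b.selected_feature_ids

    def test_unknown_rule_raises(self):
        _, modules, corr, mad = self._chain_module()
        with pytest.raises(DimredError):
            select_hubs(modules, corr, mad, rule="bogus")


class TestReduceFeatures:
    def test_one_hub_per_module(self, small_cohort):
        red = reduce_features(small_cohort.matrix, mad_fraction=0.5)
        assert len(red.selected_feature_ids) == len(red.modules)
        hubs = {m.hub_feature_id for m in red.modules}
        assert hubs == set(red.selected_feature_ids)
        for m in red.modules:
            assert m.hub_feature_id in m.member_feature_ids

    def test_recovers_planted_modules(self, small_cohort):
        # generator modules with r=0.8 should reduce below the MAD-selected
        # count: correlated co-members collapse to one hub each
        red = reduce_features(
            small_cohort.matrix, mad_fraction=1.0, corr_threshold=0.6
        )
        truth_sizes = sorted(
            len(mem) for mem in small_cohort.truth_manifest["modules"].values()
        )
        found_multi = [m.size for m in red.modules if m.size > 1]
        assert len(red.selected_feature_ids) < small_cohort.matrix.n_features
        assert len(found_multi) >= len([s for s in truth_sizes if s > 1]) // 2

    def test_multi_round_reaches_fixed_point(self, small_cohort):
        once = reduce_features(small_cohort.matrix, n_rounds=1, corr_threshold=0.6)
        many = reduce_features(small_cohort.matrix, n_rounds=5, corr_threshold=0.6)
        assert len(many.selected_feature_ids) <= len(once.selected_feature_ids)
        again = reduce_features(small_cohort.matrix, n_rounds=6, corr_threshold=0.6)
        assert many.selected_feature_ids == again.selected_feature_ids

    def test_bad_round_count(self, small_cohort):
        with pytest.raises(DimredError):
            reduce_features(small_cohort.matrix, n_rounds=0)

    def test_reduction_to_dict_is_json_ready(self, small_cohort):
        import json

        red = reduce_features(small_cohort.matrix)
        payload = reduction_to_dict(red)
        text = json.dumps(payload)
        assert "selected_feature_ids" in text
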