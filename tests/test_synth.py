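"""Generator properties: the synthetic cohort must match its own manifest."""

import numpy as np
import pandas as pd
import pytest

from phenoproteo.config import CohortConfig, ConfigurationError
from phenoproteo.qc import compute_feature_cv
from phenoproteo.synth import (
    generate_cohort,
    inject_qc_failures,
    simulate_replicates,
    write_cohort,
)


class TestConfigValidation:
    def test_bad_proportions(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_groups=2, group_proportions=(0.7, 0.2),
                         hazard_scale_per_group=(0.1, 0.2))

    def test_group_count_mismatch(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_groups=3, group_proportions=(0.5, 0.5),
                         hazard_scale_per_group=(0.1, 0.2, 0.3))

    def test_module_packing_infeasible(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_features=10, n_modules=10, module_size_range=(4, 6))

    def test_round_trip_dict(self):
        cfg = CohortConfig(n_samples=50, n_features=40, n_modules=8,
                           module_size_range=(2, 4), n_informative_modules=4,
                           seed=5)
        assert CohortConfig.from_dict(cfg.to_dict()) == cfg


class TestCohortStructure:
    def test_tables_aligned(self, small_cohort):
        small_cohort.validate()
        assert small_cohort.matrix.n_samples == 120
        assert small_cohort.matrix.n_features == 80

    def test_raw_scale_is_positive(self, small_cohort):
        assert (small_cohort.matrix.values.to_numpy() > 0).all()

    def test_group_proportions_match_config(self, small_config):
        # labels are drawn i.i.d., so check at a sample size where the
        # multinomial noise (3 sd ~ 0.03 at n=2000) is well below effect size
        cfg = CohortConfig.from_dict(
            {**small_config.to_dict(), "n_samples": 2000, "seed": 11}
        )
        cohort = generate_cohort(cfg)
        counts = cohort.true_labels.value_counts(normalize=True).sort_index()
        np.testing.assert_allclose(
            counts.to_numpy(), cfg.group_proportions, atol=0.04
        )

    def test_manifest_modules_partition_features(self, small_cohort):
        modules = small_cohort.truth_manifest["modules"]
        members = [f for mem in modules.values() for f in mem]
        assert len(members) == len(set(members))
        assert set(members) <= set(small_cohort.matrix.feature_ids)

    def test_informative_member_shift_matches_effect_size(self, small_config):
        # a member of an informative module should differ between its
        # elevated group and the others by ~effect_size marginal (log2) SDs
        cfg = CohortConfig.from_dict(
            {**small_config.to_dict(), "n_samples": 2000, "technical_cv": 0.0,
             "seed": 3}
        )
        cohort = generate_cohort(cfg)
        log2 = np.log2(cohort.matrix.values)
        labels = cohort.true_labels.to_numpy()
        manifest = cohort.truth_manifest
        mod = manifest["informative_modules"][0]
        shifts = np.asarray(manifest["group_shifts"][mod])
        elevated = int(np.argmax(np.abs(shifts)))
        member = manifest["modules"][mod][0]
        x = log2[member].to_numpy()
        within_sd = np.std(x[labels == elevated])
        gap = x[labels == elevated].mean() - x[labels != elevated].mean()
        assert gap / within_sd == pytest.approx(cfg.effect_size, abs=0.35)

    def test_within_module_correlation(self, small_config):
        cfg = CohortConfig.from_dict(
            {**small_config.to_dict(), "n_samples": 2000, "technical_cv": 0.0,
             "effect_size": 0.0, "seed": 4}
        )
        cohort = generate_cohort(cfg)
        log2 = np.log2(cohort.matrix.values)
        modules = cohort.truth_manifest["modules"]
        big = next(mem for mem in modules.values() if len(mem) >= 3)
        corr = log2[big].corr().to_numpy()
        off = corr[~np.eye(len(big), dtype=bool)]
        assert off.mean() == pytest.approx(cfg.within_module_corr, abs=0.05)

    def test_cross_module_independence(self, small_config):
        cfg = CohortConfig.from_dict(
            {**small_config.to_dict(), "n_samples": 2000, "effect_size": 0.0,
             "seed": 5}
        )
        cohort = generate_cohort(cfg)
        log2 = np.log2(cohort.matrix.values)
        modules = list(cohort.truth_manifest["modules"].values())
        f_a, f_b = modules[0][0], modules[1][0]
        r = np.corrcoef(log2[f_a], log2[f_b])[0, 1]
        assert abs(r) < 0.1

    def test_determinism(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        pd.testing.assert_frame_equal(a.matrix.values, b.matrix.values)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)
        pd.testing.assert_frame_equal(a.survival, b.survival)
        pd.testing.assert_series_equal(a.true_labels, b.true_labels)

    def test_seed_changes_output(self, small_config):
        other = CohortConfig.from_dict({**small_config.to_dict(), "seed": 8})
        a = generate_cohort(small_config)
        b = generate_cohort(other)
        assert not a.matrix.values.equals(b.matrix.values)


class TestClinicalAndSurvival:
    def test_clinical_columns_and_trends(self, small_config):
        cfg = CohortConfig.from_dict(
            {**small_config.to_dict(), "n_samples": 4000, "seed": 9}
        )
        cohort = generate_cohort(cfg)
        clin = cohort.clinical.set_index("sample_id")
        for col in ("age", "sex", "egfr", "nt_probnp", "maggic",
                    "ef_lt40", "afib", "hf_duration_ge18mo"):
            assert col in clin.columns
        labels = cohort.true_labels
        worst, best = labels.index[labels == 2], labels.index[labels == 0]
        assert clin.loc[worst, "age"].mean() > clin.loc[best, "age"].mean()
        assert clin.loc[worst, "egfr"].mean() < clin.loc[best, "egfr"].mean()
        assert (
            np.log(clin.loc[worst, "nt_probnp"]).mean()
            > np.log(clin.loc[best, "nt_probnp"]).mean()
        )

    def test_survival_closed_form_event_times(self, small_config):
        # censoring off: every subject is an event; exponential group hazard
        # lambda implies mean event time 1/lambda
        cfg = CohortConfig.from_dict(
            {**small_config.to_dict(), "n_samples": 6000, "censoring_rate": 0.0,
             "followup_horizon": 1e9, "seed": 10}
        )
        cohort = generate_cohort(cfg)
        surv = cohort.survival.set_index("sample_id")
        assert (surv["event"] == 1).all()
        labels = cohort.true_labels
        for g, lam in enumerate(cfg.hazard_scale_per_group):
            mean_t = surv.loc[labels.index[labels == g], "time_years"].mean()
            assert mean_t == pytest.approx(1.0 / lam, rel=0.1)

    def test_censoring_horizon_truncates(self, small_config):
        cohort = generate_cohort(small_config)
        assert (cohort.survival["time_years"]
                <= small_config.followup_horizon + 1e-9).all()


class TestQCInjectionAndReplicates:
    def test_inject_qc_failures_flags_and_scales(self, small_cohort):
        injected = inject_qc_failures(small_cohort, n_fail=3, seed=99)
        fails = injected.truth_manifest["qc_fail_samples"]
        assert len(fails) == 3
        for sid in fails:
            assert injected.matrix.sample_flags[sid] == "injected_qc_failure"
            ratio = (
                injected.matrix.values.loc[sid].sum()
                / small_cohort.matrix.values.loc[sid].sum()
            )
            assert ratio == pytest.approx(8.0, rel=1e-9) or ratio == pytest.approx(
                1.0 / 8.0, rel=1e-9
            )

    def test_inject_zero_is_identity(self, small_cohort):
        assert inject_qc_failures(small_cohort, 0, seed=1) is small_cohort

    def test_replicate_cv_recovers_technical_cv(self, small_config):
        values, groups = simulate_replicates(small_config, n_replicates=12, seed=21)
        cv, report = compute_feature_cv(values, groups)
        assert report.median_cv == pytest.approx(
            100.0 * small_config.technical_cv, rel=0.15
        )

    def test_replicates_require_two(self, small_config):
        with pytest.raises(ValueError):
            simulate_replicates(small_config, n_replicates=1)


def test_write_cohort_round_trip(tmp_path, small_cohort):
    from phenoproteo import io as pio

    paths = write_cohort(small_cohort, tmp_path)
    back = pio.read_matrix(paths["matrix"])
    np.testing.assert_allclose(
        back.values.to_numpy(), small_cohort.matrix.values.to_numpy(), rtol=1e-6
    )
    clin = pio.read_clinical(paths["clinical"])
    assert list(clin["sample_id"]) == small_cohort.matrix.sample_ids
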