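"""Shared fixtures: one small synthetic cohort reused across unit tests."""

import pytest

from phenoproteo.config import CohortConfig, PipelineParams
from phenoproteo.pipeline import PhenomapModel
from phenoproteo.synth import generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(
        n_samples=120,
        n_features=80,
        n_groups=3,
        group_proportions=(0.45, 0.245, 0.305),
        n_modules=12,
        module_size_range=(3, 6),
        within_module_corr=0.8,
        n_informative_modules=8,
        effect_size=2.5,
        technical_cv=0.05,
        hazard_scale_per_group=(0.10, 0.15, 0.22),
        censoring_rate=0.02,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_params() -> PipelineParams:
    return PipelineParams(k_range=(2, 4), n_resamples=40, n_init=10)


@pytest.fixture(scope="session")
def fitted(small_cohort, small_params):
    """A fitted phenomapping run on the small cohort (shared, read-only)."""
    model = PhenomapModel.from_cohort(small_cohort, params=small_params)
    return model.fit(seed=1)
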