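import pytest

from oralcyto.simdata import CohortSimConfig, ImageSimConfig, simulate_cohort, simulate_image


@pytest.fixture(scope="session")
def small_bundle():
    """A well-separated synthetic field used by several imaging tests."""
    cfg = ImageSimConfig(width=512, height=512, n_cells=12,
                         atypical_fraction=0.3, cluster_fraction=0.0, seed=5)
    return simulate_image(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortSimConfig(n_per_class=(50, 50, 50), seed=3))
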