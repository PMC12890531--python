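import pytest

from tcrshare import GeneratorConfig, generate_study, null_config


@pytest.fixture(scope="session")
def study():
    """Default synthetic study with planted structure (seed fixed)."""
    return generate_study(GeneratorConfig(seed=5))


@pytest.fixture(scope="session")
def null_study():
    """Synthetic study with no planted structure."""
    return generate_study(null_config(11))


def small_generator_config(seed: int = 0) -> GeneratorConfig:
    """A reduced study for fast end-to-end / determinism tests."""
    return GeneratorConfig(
        n_cases=6,
        n_controls=6,
        n_inadequate_pb_per_cohort=0,
        pb_mean_case=350.0,
        pb_mean_control=450.0,
        n_planted_exclusive=1,
        n_planted_enriched=1,
        exclusive_prevalence=3,
        enriched_prevalence_cases=4,
        enriched_prevalence_controls=4,
        enriched_sg_cases=2,
        n_public_pool=200,
        min_pb_clonotypes=100,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_generator_config(3))
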