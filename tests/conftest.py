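import pytest

from heatstrain.population import (
    assign_exposure_exertion,
    build_person_types,
    discretize_body_distribution,
)
from heatstrain.synthetic_population import (
    GeneratorConfig,
    generate_occupation_table,
    generate_population_table,
)


@pytest.fixture(scope="session")
def generator_config() -> GeneratorConfig:
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def default_person_types(generator_config):
    """Person-types for the default synthetic population (seed 1)."""
    binned = discretize_body_distribution(generate_population_table(generator_config))
    exposure = assign_exposure_exertion(generate_occupation_table(generator_config))
    return build_person_types(
        binned, exposure, stratum_shares=generator_config.stratum_shares()
    )
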