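import numpy as np
import pandas as pd
import pytest

from ffqpipe import (
    DEFAULT_FOOD_GROUPS,
    FfqResponse,
    SyntheticCohortConfig,
    aggregate_groups,
    build_default_instrument,
    default_composition_table,
    full_nutrient_table,
    generate,
    quantify_cohort,
)


@pytest.fixture(scope="session")
def instrument():
    return build_default_instrument()


@pytest.fixture(scope="session")
def composition():
    return default_composition_table()


@pytest.fixture(scope="session")
def small_cohort():
    """60-child cohort with no feeding exclusions, deterministic."""
    return generate(
        SyntheticCohortConfig(n_children=60, feeding_marginals=(0, 0, 0, 0), seed=7)
    )


@pytest.fixture(scope="session")
def small_nutrients(small_cohort, composition):
    intakes = aggregate_groups(
        quantify_cohort(small_cohort.responses, small_cohort.instrument),
        DEFAULT_FOOD_GROUPS,
    )
    return full_nutrient_table(intakes, composition)


def make_response(child_id="X1", **kwargs):
    defaults = dict(age_days=365, breastfed_beyond_10m="no", formula_beyond_10m="no")
    defaults.update(kwargs)
    return FfqResponse(child_id=child_id, **defaults)


@pytest.fixture
def response_factory():
    return make_response
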