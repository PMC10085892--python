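import json

import numpy as np
import pytest

from cvcost.model_spec import (
    CohortStratum,
    default_fixture_path,
    load_published_models,
    reference_profile,
    reference_state,
)
from cvcost.predictor import annual_states
from cvcost.simulator import sample_baseline


@pytest.fixture(scope="session")
def models():
    return load_published_models()


@pytest.fixture(scope="session")
def raw_fixture():
    return json.loads(default_fixture_path().read_text())


@pytest.fixture
def ref_without():
    return reference_profile(CohortStratum.WITHOUT_CVD), reference_state()


@pytest.fixture
def ref_with():
    return reference_profile(CohortStratum.WITH_CVD), reference_state()


@pytest.fixture(scope="session")
def random_population():
    """Event-free year-0 states for a mixed random cohort."""
    profiles = sample_baseline(60, CohortStratum.WITHOUT_CVD, seed=42)
    return [(p, annual_states(p, {}, 1)[0]) for p in profiles]
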