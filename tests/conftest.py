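import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hsettings

from agtkit.choice_models import constrained_winning_spec
from agtkit.inference import SamplerSettings, fit_hierarchical
from agtkit.synthetic_cohort import (GroupSpec, default_group_specs,
                                     generate_cohort)

hsettings.register_profile("ci", derandomize=True, max_examples=50)
hsettings.load_profile("ci")

#: reduced MCMC settings for unit tests (fast, adequately mixed)
FAST = SamplerSettings(chains=2, warmup=400, draws=300, thin=3)


@pytest.fixture(scope="session")
def winning_model():
    return constrained_winning_spec()


@pytest.fixture(scope="session")
def default_cohort():
    """Full four-group cohort at the empirical sample sizes."""
    specs = default_group_specs()
    return generate_cohort(list(specs.values()), [57, 36, 46, 41], seed=1234)


@pytest.fixture(scope="session")
def small_cohort(winning_model):
    """Single-group cohort of 25 subjects, no age effect."""
    spec = GroupSpec(label="HV", age_effect_on_k=0.0)
    return generate_cohort([spec], [25], seed=77, model=winning_model)


@pytest.fixture(scope="session")
def small_fit(small_cohort, winning_model):
    return fit_hierarchical(small_cohort, winning_model, settings=FAST, seed=3)
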