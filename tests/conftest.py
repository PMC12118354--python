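import pytest
from hypothesis import settings

import standmix as sm

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    dataset, truth = sm.generate_study(sm.default_design(), seed=7)
    return dataset, truth


@pytest.fixture(scope="session")
def noise_free_dataset():
    design = sm.default_design(cv_green=0.0, cv_senescent=0.0)
    dataset, truth = sm.generate_study(design, seed=11)
    return dataset, truth
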