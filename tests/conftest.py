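import pytest
from hypothesis import settings

from snpmeta import EffectEstimate, GeneticModel, load_example_table

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")


def make_effect(log_or, variance, study_id="s", model=GeneticModel.ALLELE):
    return EffectEstimate(study_id=study_id, model=model,
                          log_or=log_or, se=variance ** 0.5)


@pytest.fixture
def mk_effect():
    return make_effect


@pytest.fixture(scope="session")
def example_table():
    """The shipped 26-study rs13387042 breast-cancer table."""
    return load_example_table()
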