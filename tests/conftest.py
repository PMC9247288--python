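import pytest

from conflictsim import ModelParameters, apply_scenario, get_scenario


@pytest.fixture
def defaults() -> ModelParameters:
    return ModelParameters()


@pytest.fixture
def scenario_params(defaults):
    """Factory: parameters with a named built-in scenario applied."""

    def make(name: str) -> ModelParameters:
        return apply_scenario(defaults, get_scenario(name))

    return make
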