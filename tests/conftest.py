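import pytest

from fillitup import DesignSpec, stage_plan


@pytest.fixture(scope="session")
def ataxia_spec():
    """Small-effect planning setting: delta=0.275, 500 historical controls."""
    return DesignSpec(delta=0.275, alpha_ept=0.05, n_h=500, margin=0.22)


@pytest.fixture(scope="session")
def ataxia_plan(ataxia_spec):
    return stage_plan(ataxia_spec)


@pytest.fixture(scope="session")
def medium_spec():
    """Medium-effect setting: delta=0.5, 500 historical controls."""
    return DesignSpec(delta=0.5, alpha_ept=0.05, n_h=500, margin=0.44)


@pytest.fixture(scope="session")
def medium_plan(medium_spec):
    return stage_plan(medium_spec)
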