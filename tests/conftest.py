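import pytest

from mtasekit import (MTaseSpecificity, make_alw44i_fixture, make_selection_fixture,
                      shipped_enzymes)


@pytest.fixture(scope="session")
def enzymes():
    return shipped_enzymes()


@pytest.fixture(scope="session")
def alw44i_fixture():
    return make_alw44i_fixture(seed=0)


@pytest.fixture(scope="session")
def selection_fixture():
    return make_selection_fixture(seed=0)


@pytest.fixture
def no_methylation():
    return MTaseSpecificity.inactive()
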