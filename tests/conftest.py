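import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from neoexam import fixtures as fx


@pytest.fixture(scope="session")
def by_quality():
    """Reflex hierarchy grouping leaves under brisk/absent reflex."""
    return fx.reflex_grouping_fixtures()[0]


@pytest.fixture(scope="session")
def by_muscle():
    """Reflex hierarchy grouping the same leaves under biceps/knee findings."""
    return fx.reflex_grouping_fixtures()[1]


@pytest.fixture(scope="session")
def skeleton():
    return fx.neo_skeleton()


@pytest.fixture(scope="session")
def plantar_lexicon():
    return fx.extensor_plantar_lexicon()


@pytest.fixture(scope="session")
def demo_lexicon():
    return fx.demo_lexicon()
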