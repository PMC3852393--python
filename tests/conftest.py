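import pytest

import splitmap as sm


@pytest.fixture(scope="session")
def chr3():
    return sm.fixtures.load_chr3_map()


@pytest.fixture(scope="session")
def refmap():
    return sm.fixtures.load_chr3_refmap()


@pytest.fixture(scope="session")
def table1_records():
    return sm.fixtures.load_table1_records()


@pytest.fixture(scope="session")
def table1_kit():
    return sm.fixtures.load_table1_kit()


@pytest.fixture
def hpr_counts():
    """The worked-example split counts: 14 lost the left marker (H),
    13 lost the right marker (Pr), no unmarked progeny."""
    return sm.ProgenyCounts(
        pair_id="H,Pr", n_lost_left=14, n_lost_right=13, n_unmarked=0
    )
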