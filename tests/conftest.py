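import pytest

from mimoscan import table1_fixture


@pytest.fixture(scope="session")
def table1_panels():
    return table1_fixture()


@pytest.fixture(scope="session")
def panels_by_id(table1_panels):
    return {p.panel_id: p for p in table1_panels}
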