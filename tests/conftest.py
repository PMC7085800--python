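import pytest

from duoact.casas_io import segment_activities
from duoact.features import build_sia
from duoact.synthgen import table1_fixture


@pytest.fixture(scope="session")
def table1_events():
    return table1_fixture()


@pytest.fixture(scope="session")
def table1_instances(table1_events):
    return segment_activities(table1_events)


@pytest.fixture(scope="session")
def table1_sia(table1_instances):
    return build_sia([a.sq for a in table1_instances])
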