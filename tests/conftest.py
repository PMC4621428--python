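import pytest

from eventmodels import (
    construct_model,
    office_day_fixture,
    patrol_fixture,
    segment_stream,
    two_location_goal_fixture,
)


@pytest.fixture
def patrol():
    return patrol_fixture()


@pytest.fixture
def two_location():
    return two_location_goal_fixture()


@pytest.fixture
def office_day():
    return office_day_fixture()


@pytest.fixture
def patrol_markers(patrol):
    return segment_stream(patrol)


@pytest.fixture
def two_location_markers(two_location):
    return segment_stream(two_location)


@pytest.fixture
def office_day_markers(office_day):
    return segment_stream(office_day)


@pytest.fixture
def two_location_model(two_location_markers):
    return construct_model(two_location_markers)


@pytest.fixture
def office_day_model(office_day_markers):
    return construct_model(office_day_markers)
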