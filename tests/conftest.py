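import datetime as dt

import pytest

from nutrimission.engine import load_default_bundle
from nutrimission.ffq import DietaryPreferences, FrequencyReport


@pytest.fixture(scope="session")
def bundle():
    return load_default_bundle()


@pytest.fixture(scope="session")
def guidelines_by_group(bundle):
    return {e.food_group_id: e for e in bundle.guidelines}


@pytest.fixture
def full_response(bundle):
    """A complete full-FFQ response at 2/week for every item."""
    return [
        FrequencyReport(item_id=it.item_id, count=2, period="week")
        for it in bundle.schemas["full"].items
    ]


def make_response(schema, weekly_by_group):
    """Build a response reporting a group's weekly servings split evenly
    over the schema's items of that group (weekly period throughout)."""
    reports = []
    for it in schema.items:
        n = len(schema.items_for_group(it.food_group_id))
        reports.append(
            FrequencyReport(
                item_id=it.item_id,
                count=weekly_by_group.get(it.food_group_id, 0.0) / n,
                period="week",
            )
        )
    return reports


@pytest.fixture
def no_restrictions():
    return DietaryPreferences()


@pytest.fixture
def a_date():
    return dt.date(2024, 1, 1)
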