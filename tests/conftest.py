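import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("default")


def make_observations(rows):
    """Build an observation DataFrame from (bout, pollinator, index, plant) tuples."""
    return pd.DataFrame(rows, columns=["bout_id", "pollinator_id", "visit_index", "plant_id"])


@pytest.fixture
def single_bout_table():
    """One bout F,F,O,F by one pollinator — the canonical hand-countable case."""
    from pollinator_ri import ObservationTable

    rows = [("b1", "p1", 1, "F"), ("b1", "p1", 2, "F"), ("b1", "p1", 3, "O"), ("b1", "p1", 4, "F")]
    return ObservationTable(make_observations(rows), focal_plant_id="F")
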