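import numpy as np
import pytest

from orsim import library, scenario


@pytest.fixture(scope="session")
def rules():
    r, _ = scenario.default_rules()
    return r


@pytest.fixture(scope="session")
def bradycardia_scenario():
    """The eventful_1 script (circuit disconnect / bradycardia /
    endobronchial migration) with evaluated alarms, plus its manifest."""
    return library.make_scenario("eventful_1")


@pytest.fixture(scope="session")
def hypovolemia_scenario():
    return library.make_scenario("eventful_2")


@pytest.fixture(scope="session")
def uneventful_scenario():
    return library.make_scenario("uneventful_1")


@pytest.fixture()
def small_tracks():
    n = 120
    return {
        "HR": np.full(n, 75.0),
        "SpO2": np.full(n, 98.0),
        "NIBP_sys": np.full(n, 120.0),
    }


def brute_force_alarms(tracks, rules):
    """Independent per-row oracle for alarm evaluation: plain Python loop."""
    n = len(next(iter(tracks.values())))
    states = {r.alarm_id: [0] * n for r in rules}
    for r in rules:
        for i in range(n):
            v = tracks[r.parameter][i]
            hit = v < r.threshold if r.direction == "low" else v > r.threshold
            if hit:
                states[r.alarm_id][i] = 1
    return states
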