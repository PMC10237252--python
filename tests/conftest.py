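import numpy as np
import pytest

from msns import NeonateObservation, build_fixture_cohort

#: An entirely normal admission: every rubric parameter in its score-2 band.
ALL_NORMAL = dict(
    id="normal",
    apnea_or_grunt=False,
    respiratory_rate=50.0,
    retractions=False,
    heart_rate=120.0,
    axillary_temperature=37.0,
    capillary_refill_time=2.0,
    random_blood_sugar=80.0,
    spo2_room_air=98.0,
    gestational_age=39.0,
    birth_weight=3.0,
    sex="male",
    mode_of_delivery="vaginal",
    parity="primi",
    outcome="discharged",
)

#: Every rubric parameter in its score-0 band.
ALL_WORST = dict(
    ALL_NORMAL,
    id="worst",
    apnea_or_grunt=True,
    respiratory_rate=None,
    heart_rate=0.0,  # asystole
    axillary_temperature=34.0,
    capillary_refill_time=6.0,
    random_blood_sugar=20.0,
    spo2_room_air=70.0,
    gestational_age=30.0,
    birth_weight=1.2,
    outcome="expired",
)


def make_observation(**overrides) -> NeonateObservation:
    return NeonateObservation(**{**ALL_NORMAL, **overrides})


@pytest.fixture
def all_normal():
    return make_observation()


@pytest.fixture
def all_worst():
    return NeonateObservation(**ALL_WORST)


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_fixture_cohort(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
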