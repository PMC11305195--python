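import pytest

from snpdiet.fixtures import FixtureSpec, generate_food_db, toy_instances


@pytest.fixture(scope="session")
def toys():
    return toy_instances()


@pytest.fixture(scope="session")
def thr_toy(toys):
    return toys["thr_toy_5"]


@pytest.fixture(scope="session")
def hcm_toy(toys):
    return toys["hcm_toy"]


@pytest.fixture(scope="session")
def feasible_db():
    return generate_food_db(FixtureSpec(seed=11))
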