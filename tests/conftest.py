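import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from colonynet.events import (
    ClassRoster,
    FunctionalClass,
    ObservationWindow,
    TrophallaxisEvent,
)
from colonynet.synth import scenario, generate_colony

SHORT = {
    "AF": FunctionalClass.ACTIVE_FORAGER,
    "IF": FunctionalClass.INACTIVE_FORAGER,
    "NW": FunctionalClass.NEST_WORKER,
    "Q": FunctionalClass.QUEEN,
}


def make_roster(colony: str, night: int, classes: dict[str, str]) -> ClassRoster:
    """Quick roster builder: {'ant': 'AF'|'IF'|'NW'|'Q'} for one night."""
    r = ClassRoster()
    for ant, short in classes.items():
        r.assignments[(colony, night, ant)] = SHORT[short]
    return r


def ev(a, b, t0, t1, colony="C1", night=1, cell=None) -> TrophallaxisEvent:
    return TrophallaxisEvent(
        colony=colony, night=night, ant_a=a, ant_b=b,
        t_start_s=t0, t_end_s=t1, cell=cell,
    )


@pytest.fixture(scope="session")
def window():
    return ObservationWindow("C1", 1, 1200.0)


@pytest.fixture(scope="session")
def small_colony():
    """One small synthetic colony-night set shared by read-only tests."""
    cfg = dataclasses.replace(
        scenario("paper_like", seed=11),
        colonies=("C1",),
        nights=3,
        n_nest_workers=20,
        n_foragers=6,
        n_tracked_foragers=2,
        n_tracked_nest_workers=2,
    )
    return generate_colony(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
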