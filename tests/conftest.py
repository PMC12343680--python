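import numpy as np
import pytest

from fnsgait.model import (
    Coordinate,
    MskModel,
    ReserveActuator,
    Segment,
    pendulum_model,
    planar_biped,
)


@pytest.fixture(scope="session")
def biped():
    return planar_biped()


@pytest.fixture(scope="session")
def pendulum():
    return pendulum_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20250930)


def make_double_integrator(force_max=10.0):
    """Point mass on a frictionless rail with one bounded force actuator."""
    coords = [Coordinate("x", "tx", (-2.0, 2.0), (-5.0, 5.0))]
    seg = Segment("cart", 1.0, 0.0, 0.1, parent="ground", coordinates=("x",))
    act = ReserveActuator("x", "force", force_max, "normal")
    return MskModel([seg], coords, [], [], [], [act], markers=(),
                    gravity=0.0, symmetric=False, name="double_integrator")


@pytest.fixture(scope="session")
def double_integrator():
    return make_double_integrator()
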