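import numpy as np
import pytest
from hypothesis import settings

from wayfam.synthetic_data import (
    DecisionPoint,
    EffectConfig,
    RouteGeometry,
    generate_recording,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_route():
    """~90 m L-shaped route with one turn junction (fast ~70 s recordings)."""
    poly = np.array([[0.0, 0.0], [45.0, 0.0], [45.0, 45.0]])
    dps = (DecisionPoint(vertex_index=1, junction_id="J1", is_turn=True),)
    return RouteGeometry(polyline=poly, decision_points=dps)


@pytest.fixture
def effect():
    return EffectConfig()


@pytest.fixture
def recording(effect, short_route):
    return generate_recording("P000", "familiar", effect, route=short_route, seed=7)
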