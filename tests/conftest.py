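import numpy as np
import pytest

from aaafsi import geometry as geo


@pytest.fixture(scope="session")
def table1():
    return geo.table1_curves()


@pytest.fixture(scope="session")
def default_geometry():
    return geo.build_geometry(n_stations=201)


@pytest.fixture(scope="session")
def straight_tube_curves():
    """All bump amplitudes zero, common baseline radius 10 mm."""
    curves = {}
    for name, spec in geo.table1_curves().items():
        curves[name] = geo.CurveSpec(name, 10.0, 0.0, spec.c2, spec.c3, spec.p1, spec.p2)
    return curves


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
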