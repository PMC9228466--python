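import numpy as np
import pytest

from cntdiff import SurfaceSpec, cnt_radius
from cntdiff.synthetic import dopamine_like


@pytest.fixture(scope="session")
def plane_spec():
    return SurfaceSpec.plane(0.0, [98.2419, 97.8420, 60.0])


@pytest.fixture(scope="session")
def cnt_ext_spec():
    r = cnt_radius(15, 15)
    return SurfaceSpec.cylinder(r, "cylinder_exterior", (30.0, 30.0),
                                [60.0, 60.0, 100.698])


@pytest.fixture(scope="session")
def cnt_int_spec():
    r = cnt_radius(15, 15)
    return SurfaceSpec.cylinder(r, "cylinder_interior", (30.0, 30.0),
                                [60.0, 60.0, 100.698])


@pytest.fixture(scope="session")
def dopamine():
    """(template, species, moiety map) of the rigid reference adsorbate."""
    return dopamine_like()


@pytest.fixture(scope="session")
def groove_spec():
    from cntdiff.synthetic import default_groove_spec
    return default_groove_spec()
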