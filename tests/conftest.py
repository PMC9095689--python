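import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tetrahedron():
    """Smallest valid closed mesh."""
    from myoshape.mesh import SurfaceMesh

    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return SurfaceMesh(verts, faces)


@pytest.fixture(scope="session")
def template_small():
    from myoshape.synthetic import base_soleus_template

    return base_soleus_template(8)


@pytest.fixture(scope="session")
def template_medium():
    from myoshape.synthetic import base_soleus_template

    return base_soleus_template(14)
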