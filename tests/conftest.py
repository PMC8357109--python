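import numpy as np
import pytest

from airwaykit import (
    DeformationConfig,
    PivotalPlaneSpec,
    SyntheticAirwaySpec,
    TriangleMesh,
    generate_airway,
)

TETRA_ASCII = """solid tetra
facet normal 0 0 -1
  outer loop
    vertex 0 0 0
    vertex 0 1 0
    vertex 1 0 0
  endloop
endfacet
facet normal 0 -1 0
  outer loop
    vertex 0 0 0
    vertex 1 0 0
    vertex 0 0 1
  endloop
endfacet
facet normal -1 0 0
  outer loop
    vertex 0 0 0
    vertex 0 0 1
    vertex 0 1 0
  endloop
endfacet
facet normal 1 1 1
  outer loop
    vertex 1 0 0
    vertex 0 1 0
    vertex 0 0 1
  endloop
endfacet
endsolid tetra
"""


@pytest.fixture
def tetra_stl(tmp_path):
    path = tmp_path / "tetra.stl"
    path.write_text(TETRA_ASCII)
    return path


@pytest.fixture
def tetrahedron():
    v = np.array([[0, 0, 0], [0, 1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
    f = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [2, 1, 3]])
    return TriangleMesh(v, f)


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticAirwaySpec()


@pytest.fixture(scope="session")
def airway(default_spec):
    """Default surrogate airway: elliptical pharynx + two nasal branches."""
    return generate_airway(default_spec)


@pytest.fixture(scope="session")
def airway_fine():
    """High angular resolution variant for slicing-precision checks."""
    return generate_airway(SyntheticAirwaySpec(vertices_per_ring=256))


def planning_config(dY_mid=4.0, dX_mid=1.0, dY_low=6.0, dX_low=2.0):
    """The worked planning example: fixed plane -566, soft palate -587,
    epiglottis level -610, with the published enlargement parameters."""
    return DeformationConfig(
        top_plane=PivotalPlaneSpec(z=-566.0, label="fixed"),
        middle_plane=PivotalPlaneSpec(
            z=-587.0, label="tip of soft palate", dY=dY_mid, dX_half=dX_mid
        ),
        lower_plane=PivotalPlaneSpec(
            z=-610.0, label="tip of epiglottis", dY=dY_low, dX_half=dX_low
        ),
    )


@pytest.fixture
def table_config():
    return planning_config()


@pytest.fixture
def zero_config():
    return planning_config(0.0, 0.0, 0.0, 0.0)
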