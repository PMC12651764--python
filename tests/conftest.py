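import numpy as np
import pytest

from prepscore.geometry import TriangleMesh


@pytest.fixture
def unit_triangle() -> TriangleMesh:
    return TriangleMesh(
        vertices=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
        faces=np.array([[0, 1, 2]]),
        source_id="tri",
    )


@pytest.fixture
def two_face_mesh() -> TriangleMesh:
    """Two coplanar triangles with a 9:1 area ratio."""
    return TriangleMesh(
        vertices=np.array(
            [[0.0, 0, 0], [3, 0, 0], [0, 6, 0], [10, 0, 0], [11, 0, 0], [10, 2, 0]]
        ),
        faces=np.array([[0, 1, 2], [3, 4, 5]]),
        source_id="two",
    )


@pytest.fixture
def tetra_mesh() -> TriangleMesh:
    """A closed tetrahedron — small but valid 3D surface."""
    v = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f, source_id="tetra")
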