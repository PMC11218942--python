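import numpy as np
import pytest

from image2flow.losses import LossWeights
from image2flow.mesh_core import FieldSet, ImageVolume, VolumeMesh
from image2flow.network import Image2FlowNet, ModelConfig
from image2flow.normalization import fit_stats, standardize
from image2flow.synthetic import (
    ScaleSpec,
    analytic_flow,
    average_params,
    build_structured_tube_mesh,
    generate_case,
    template_for_scale,
)


@pytest.fixture
def single_tet():
    return VolumeMesh(
        nodes=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
        tets=np.array([[0, 1, 2, 3]]),
    )


@pytest.fixture
def two_tets():
    """Two tets sharing the face (0, 1, 2)."""
    return VolumeMesh(
        nodes=np.array(
            [[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0.4, 0.4, -1.0]]
        ),
        tets=np.array([[0, 1, 2, 3], [0, 2, 1, 4]]),
    )


def regular_tet_nodes(scale=1.0):
    """Vertices of an equilateral tetrahedron with unit edge length * scale."""
    return scale * np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.5, np.sqrt(3) / 2, 0.0],
            [0.5, np.sqrt(3) / 6, np.sqrt(6) / 3],
        ]
    )


@pytest.fixture
def regular_tet():
    return VolumeMesh(nodes=regular_tet_nodes(), tets=np.array([[0, 1, 2, 3]]))


@pytest.fixture(scope="session")
def small_scale():
    return ScaleSpec.small()


@pytest.fixture(scope="session")
def tiny_scale():
    return ScaleSpec.tiny()


@pytest.fixture(scope="session")
def small_template(small_scale):
    """(mesh, lattice, fields@0.2, params) for the small-scale template."""
    return template_for_scale(small_scale)


@pytest.fixture(scope="session")
def small_case(small_scale):
    return generate_case("case_fix", 0, 12345, small_scale)


@pytest.fixture(scope="session")
def tiny_case(tiny_scale):
    return generate_case("tiny_fix", 0, 999, tiny_scale)


@pytest.fixture(scope="session")
def wye():
    """Default-parameter Y mesh + lattice at small resolution."""
    params = average_params()
    mesh, lattice = build_structured_tube_mesh(params)
    return mesh, lattice, params


@pytest.fixture(scope="session")
def tiny_model(tiny_scale, tiny_case):
    """Tiny float64 model with fitted stats; shared read-only across tests."""
    mesh, lattice, fields, params = template_for_scale(tiny_scale)
    stats = fit_stats(list(tiny_case.fields.values()))
    return Image2FlowNet(
        ModelConfig.tiny(seed=3), mesh, standardize(fields, stats), stats
    )


@pytest.fixture
def weights():
    return LossWeights()
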