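import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitopits.graph import GraphEdge, GraphNode, SkeletonGraph
from mitopits.synthetic import ImagingModel

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_tube_graph(length_nm: float, radius_nm: float = 250.0,
                    origin=(3000.0, 3000.0), n_points: int = 21,
                    field_nm=(23040.0, 23040.0)) -> SkeletonGraph:
    """A straight horizontal tube with two endpoint nodes."""
    x0, y0 = origin
    xs = np.linspace(x0, x0 + length_nm, n_points)
    poly = np.column_stack([xs, np.full(n_points, y0)])
    nodes = [
        GraphNode(id=0, position_nm=poly[0].copy(), node_class="endpoint"),
        GraphNode(id=1, position_nm=poly[-1].copy(), node_class="endpoint"),
    ]
    edges = [GraphEdge(u=0, v=1, polyline_nm=poly, length_nm=float(length_nm),
                       radius_nm=float(radius_nm))]
    return SkeletonGraph(nodes=nodes, edges=edges, field_size_nm=field_nm,
                         pixel_size_nm=45.0)


@pytest.fixture
def tube_graph() -> SkeletonGraph:
    """Straight tube, l = 1000 nm, r = 250 nm: endpoint area fraction 1/3."""
    return make_tube_graph(1000.0)


@pytest.fixture
def noiseless_imaging() -> ImagingModel:
    return ImagingModel(poisson_scale=0.0, read_noise_sd=0.0)
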