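import numpy as np
import pytest

from cartdegen import (
    CartilageMesh,
    Element,
    FibrilSpec,
    StaticFieldLoading,
)


def make_fibrils():
    return [
        FibrilSpec(direction=np.array([1.0, 0.0, 0.0]), is_primary=True),
        FibrilSpec(direction=np.array([0.0, 0.0, 1.0]), is_primary=False),
    ]


@pytest.fixture
def two_element_mesh():
    """Minimal mesh: one femoral (1 mm^3) and one tibial (2 mm^3) element."""
    return CartilageMesh(
        elements=[
            Element(id=1, volume=1.0, depth_z=0.1, region="femoral", fibrils=make_fibrils()),
            Element(id=2, volume=2.0, depth_z=0.6, region="tibial", fibrils=make_fibrils()),
        ],
        name="fixture",
        stance_duration=0.8,
    )


@pytest.fixture
def single_element_mesh():
    return CartilageMesh(
        elements=[
            Element(id=0, volume=1.0, depth_z=0.5, region="tibial", fibrils=make_fibrils())
        ],
        name="single",
        stance_duration=0.8,
    )


def static_loading_for(mesh, stresses_by_id, n_increments=1):
    """Constant-in-time static loading on a uniform stance grid."""
    durations = np.full(n_increments, mesh.stance_duration / n_increments)
    histories = {
        eid: np.full(n_increments, s) for eid, s in stresses_by_id.items()
    }
    return StaticFieldLoading(histories, durations)
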