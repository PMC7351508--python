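import numpy as np
import pytest
import trimesh as _trimesh

from shapereg import PointCloud, TriMesh


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def unit_cube() -> TriMesh:
    """Axis-aligned unit cube [0,1]^3 with outward-oriented faces."""
    box = _trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriMesh(np.asarray(box.vertices) + 0.5, np.asarray(box.faces), name="cube")


@pytest.fixture
def icosphere() -> TriMesh:
    sph = _trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    return TriMesh(np.asarray(sph.vertices), np.asarray(sph.faces), name="icosphere")


@pytest.fixture
def small_cloud(rng) -> PointCloud:
    return PointCloud(rng.normal(size=(25, 3)), source_id="small")
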