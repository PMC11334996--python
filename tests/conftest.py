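import numpy as np
import pytest

from viewflow import flow_model, mesh_scene, synthetic

CUBE_OBJ = """\
# unit cube
v -1 -1 -1
v  1 -1 -1
v  1  1 -1
v -1  1 -1
v -1 -1  1
v  1 -1  1
v  1  1  1
v -1  1  1
f 1 3 2
f 1 4 3
f 5 6 7
f 5 7 8
f 1 2 6
f 1 6 5
f 2 3 7
f 2 7 6
f 3 4 8
f 3 8 7
f 4 1 5
f 4 5 8
"""

TETRA_PLY = """\
ply
format ascii 1.0
element vertex 4
property float x
property float y
property float z
element face 4
property list uchar int vertex_indices
end_header
1 1 1
1 -1 -1
-1 1 -1
-1 -1 1
3 0 1 2
3 0 3 1
3 0 2 3
3 1 3 2
"""


@pytest.fixture
def cube_obj_path(tmp_path):
    path = tmp_path / "cube.obj"
    path.write_text(CUBE_OBJ)
    return path


@pytest.fixture
def tetra_ply_path(tmp_path):
    path = tmp_path / "tetra.ply"
    path.write_text(TETRA_PLY)
    return path


@pytest.fixture
def cube_mesh(cube_obj_path):
    return mesh_scene.load_mesh(cube_obj_path)


@pytest.fixture(scope="session")
def small_blob():
    """A ~100-vertex irregular mesh for fast geometric tests."""
    spec = synthetic.ShapeSpec(
        family="perturbed-blob", elongation=1.2, mirror_symmetric=False,
        n_fold_symmetry=1, resolution=100, seed=11,
    )
    return synthetic.generate_mesh(spec, "small-blob")


@pytest.fixture(scope="session")
def familiar_curves():
    """Flow curves of the 13-object regular suite (shared; expensive)."""
    suite = synthetic.familiar_like_suite(n_objects=13, master_seed=101)
    return {label: flow_model.flow_curve(mesh) for label, mesh in suite}


@pytest.fixture(scope="session")
def novel_curves():
    """Flow curves of the 10-object irregular suite (shared; expensive)."""
    suite = synthetic.novel_like_suite(n_objects=10, master_seed=101)
    return {label: flow_model.flow_curve(mesh) for label, mesh in suite}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
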