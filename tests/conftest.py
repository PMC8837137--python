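import numpy as np
import pytest
import trimesh

from bonereg.geometry import Point3Set, RigidTransform, TriangleMesh, rotation_about_axis


def random_rigid(rng, max_angle_deg=90.0, max_trans=20.0) -> RigidTransform:
    axis = rng.standard_normal(3)
    angle = rng.uniform(0.0, max_angle_deg)
    t = rng.uniform(-max_trans, max_trans, 3)
    return RigidTransform(rotation_about_axis(axis, angle), t)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def sphere10():
    return TriangleMesh.from_trimesh(trimesh.creation.icosphere(subdivisions=4, radius=10.0))


@pytest.fixture(scope="session")
def sphere105():
    return TriangleMesh.from_trimesh(trimesh.creation.icosphere(subdivisions=4, radius=10.5))


def make_cube(extent=10.0, offset=(0.0, 0.0, 0.0)) -> TriangleMesh:
    box = trimesh.creation.box(extents=[extent] * 3)
    box.apply_translation(np.asarray(offset) + extent / 2.0)
    return TriangleMesh.from_trimesh(box)


@pytest.fixture(scope="session")
def cube10():
    return make_cube()


@pytest.fixture(scope="session")
def coarse_femur():
    from bonereg.synthetic import make_bone_like_mesh

    return make_bone_like_mesh("femur", seed=1, detail="coarse")
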