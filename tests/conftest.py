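"""Shared fixtures and mesh construction helpers for the test suite."""

import numpy as np
import pytest
import trimesh

from subshape.mesh import TriangleMesh


def icosphere(level: int = 3, radius: float = 1.0, structure_id: str = "sphere"):
    m = trimesh.creation.icosphere(subdivisions=level, radius=radius)
    return TriangleMesh(structure_id, np.asarray(m.vertices), np.asarray(m.faces))


def bumpy_sphere(seed: int = 0, level: int = 2, radius: float = 1.0,
                 bump: float = 0.08, structure_id: str = "bumpy"):
    """A random radially perturbed sphere: valid, asymmetric, generic."""
    m = icosphere(level, radius, structure_id)
    rng = np.random.default_rng(seed)
    r = 1.0 + bump * rng.uniform(-1, 1, size=m.n_vertices)
    m.vertices = m.vertices * r[:, None]
    return m.validate()


def unit_cube():
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriangleMesh("cube", np.asarray(box.vertices) + 0.5, np.asarray(box.faces))


def regular_tetrahedron(edge: float = 1.0):
    v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    v *= edge / np.linalg.norm(v[0] - v[1])
    f = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]])
    return TriangleMesh("tetra", v, f).validate()


def torus_mesh():
    t = trimesh.creation.torus(major_radius=2.0, minor_radius=0.5,
                               major_sections=24, minor_sections=12)
    return TriangleMesh("torus", np.asarray(t.vertices), np.asarray(t.faces))


def random_rotation(seed: int):
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(axis * rng.uniform(0.2, np.pi)).as_matrix()


@pytest.fixture(scope="session")
def sphere3():
    return icosphere(3)


@pytest.fixture(scope="session")
def small_cohort():
    """One 10+6 subject cohort on the default structure, reused read-only."""
    from subshape.synthetic import CohortConfig, simulate_cohort

    return simulate_cohort(
        CohortConfig(n_cases=10, n_controls=6), seed=42
    )


@pytest.fixture(scope="session")
def small_features(small_cohort):
    from subshape.features import extract_features

    return extract_features(small_cohort)
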