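import warnings

import numpy as np
import pytest
import trimesh

from cranioshape.cohort import sample_cohort
from cranioshape.mesh import TriangleMesh
from cranioshape.pipeline import measure_cohort

COHORT_SEED = 0  # fixed seed for the reference synthetic study cohort


def make_icosphere(radius: float, subdivisions: int = 4) -> TriangleMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh.from_trimesh(tm)


def make_cylinder(radius: float = 20.0, height: float = 80.0,
                  n_theta: int = 64, n_z: int = 24) -> TriangleMesh:
    """Open lateral cylinder surface with interior vertices (no caps)."""
    th = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(-height / 2, height / 2, n_z)
    T, Z = np.meshgrid(th, z)
    V = np.column_stack([radius * np.cos(T).ravel(),
                         radius * np.sin(T).ravel(), Z.ravel()])
    faces = []
    def vid(i, j):
        return i * n_theta + (j % n_theta)
    for i in range(n_z - 1):
        for j in range(n_theta):
            faces.append([vid(i, j), vid(i, j + 1), vid(i + 1, j)])
            faces.append([vid(i, j + 1), vid(i + 1, j + 1), vid(i + 1, j)])
    return TriangleMesh(V, np.array(faces))


@pytest.fixture(scope="session")
def icosphere():
    return make_icosphere


@pytest.fixture(scope="session")
def cylinder():
    return make_cylinder


@pytest.fixture(scope="session")
def study_cohort():
    """Measured synthetic cohort (30 TG, 27 MR, 30 C) at the reference seed.

    Shared by the acceptance-style end-to-end tests; generating and measuring
    87 subjects takes tens of seconds, so it is built once per session.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        subjects, meta = sample_cohort((30, 27, 30), seed=COHORT_SEED)
        measures, profiles = measure_cohort(subjects)
    return {"subjects": subjects, "meta": meta,
            "measures": measures, "profiles": profiles}
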