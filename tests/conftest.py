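import numpy as np
import pytest
from hypothesis import settings

from surfatlas import Cohort, RoiLabel, TriangleMesh, make_icosphere

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tetrahedron() -> TriangleMesh:
    v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return TriangleMesh(v, f, name="tetra")


@pytest.fixture(scope="session")
def octahedron() -> TriangleMesh:
    v = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        float,
    )
    f = np.array(
        [[0, 2, 4], [2, 1, 4], [1, 3, 4], [3, 0, 4],
         [2, 0, 5], [1, 2, 5], [3, 1, 5], [0, 3, 5]]
    )
    return TriangleMesh(v, f, name="octa")


@pytest.fixture(scope="session")
def icosahedron() -> TriangleMesh:
    return make_icosphere(0)


@pytest.fixture(scope="session")
def sphere4() -> TriangleMesh:
    return make_icosphere(4)


def toy_cohort(mesh, subject_sets, roi_id="r1", hemi="left", condition="c"):
    """Cohort with one ROI and the given per-subject vertex sets."""
    subjects = [f"s{i}" for i in range(len(subject_sets))]
    labels = {
        (s, roi_id, hemi): RoiLabel(s, roi_id, hemi, frozenset(vs))
        for s, vs in zip(subjects, subject_sets)
    }
    return Cohort(
        mesh=mesh,
        subjects=subjects,
        rois=[roi_id],
        hemispheres=[hemi],
        condition=condition,
        labels=labels,
    )
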