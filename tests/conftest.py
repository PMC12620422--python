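import numpy as np
import pytest

from parafemur.mesh import AnthropometricRecord, DensityField, FemurSample, HexMesh
from parafemur.synthetic import SyntheticCohortSpec, generate_cohort, make_template

# a coarse template resolution for tests that only need a valid mesh
SMALL_RES = (24, 2, 12)


@pytest.fixture(scope="session")
def template():
    """Default-resolution template (length-calibrated to 430 mm)."""
    return make_template()


@pytest.fixture(scope="session")
def small_template():
    return make_template(SMALL_RES)


@pytest.fixture(scope="session")
def exact_cohort():
    """18-subject exact-linear (noise-free) cohort at reference-study conditions."""
    spec = SyntheticCohortSpec(n_subjects=18, seed=1, exact_linear=True)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def noisy_cohort():
    """18-subject cohort with default residual noise."""
    spec = SyntheticCohortSpec(n_subjects=18, seed=1)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Small, coarse cohort for plumbing tests (random rigid poses)."""
    spec = SyntheticCohortSpec(n_subjects=5, seed=11, resolution=SMALL_RES,
                               random_pose=True)
    return generate_cohort(spec)


def make_box_mesh(origin=(0.0, 0.0, 0.0), size=1.0) -> HexMesh:
    """One axis-aligned hexahedral element."""
    o = np.asarray(origin, dtype=float)
    s = float(size)
    nodes = o + s * np.array([
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ], dtype=float)
    return HexMesh(nodes=nodes, elements=np.arange(8, dtype=np.int64)[None, :],
                   surface_node_ids=np.arange(8))


def make_sample(mesh: HexMesh, density=None, subject_id="s0", stature=160.0,
                bmi=25.0, age=60.0) -> FemurSample:
    if density is None:
        density = DensityField(values=np.full(mesh.n_elements, 1.0))
    return FemurSample(
        anthro=AnthropometricRecord(subject_id=subject_id, stature=stature,
                                    bmi=bmi, age=age),
        mesh=mesh, density=density,
    )
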