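"""Cohort loading, correspondence checking and rigid Procrustes alignment."""

import numpy as np
import pytest

from parafemur import io as pio
from parafemur.mesh import (
    AlignmentError,
    CorrespondenceError,
    DensityField,
    HexMesh,
    RigidTransform,
    align_cohort,
    mean_surface_distance,
    procrustes_align,
)

from conftest import make_box_mesh, make_sample


def rot_z(deg: float) -> np.ndarray:
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

def test_hexmesh_rejects_out_of_range_connectivity():
    mesh = make_box_mesh()
    bad = mesh.elements.copy()
    bad[0, 0] = 99
    with pytest.raises(CorrespondenceError):
        HexMesh(nodes=mesh.nodes, elements=bad, surface_node_ids=mesh.surface_node_ids)


def test_density_field_validation():
    with pytest.raises(ValueError):
        DensityField(values=np.array([-0.1, 0.5]))
    with pytest.raises(ValueError):
        DensityField(values=np.array([0.1]), basis="bogus")


def test_rigid_transform_rejects_reflection_and_scaling():
    with pytest.raises(ValueError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
    with pytest.raises(ValueError):
        RigidTransform(2.0 * np.eye(3), np.zeros(3))


def test_topology_hash_shared_and_sensitive():
    a, b = make_box_mesh(), make_box_mesh(origin=(5, 5, 5))
    assert a.topology_hash == b.topology_hash
    permuted = a.elements.copy()
    permuted[0] = permuted[0][::-1]
    c = HexMesh(nodes=a.nodes, elements=permuted, surface_node_ids=a.surface_node_ids)
    assert c.topology_hash != a.topology_hash


# ---------------------------------------------------------------------------
# load_cohort
# ---------------------------------------------------------------------------

def test_load_cohort_roundtrip(tmp_path, small_cohort):
    samples, _ = small_cohort
    paths = pio.save_cohort(tmp_path, samples)
    loaded = pio.load_cohort(paths, tmp_path / "anthro.csv")
    assert len(loaded) == len(samples)
    hashes = {s.mesh.topology_hash for s in loaded}
    assert len(hashes) == 1
    for a, b in zip(loaded, samples):
        assert a.anthro == b.anthro
        np.testing.assert_allclose(a.mesh.nodes, b.mesh.nodes, atol=1e-12)
        np.testing.assert_allclose(a.density.values, b.density.values, atol=1e-14)


def test_load_cohort_permuted_connectivity_is_correspondence_error(tmp_path, small_cohort):
    samples, _ = small_cohort
    paths = pio.save_cohort(tmp_path, samples)
    bad = samples[1].mesh.elements.copy()
    bad[3] = bad[3][::-1]
    broken = HexMesh(nodes=samples[1].mesh.nodes, elements=bad,
                     surface_node_ids=samples[1].mesh.surface_node_ids)
    pio.write_vtk(paths[1], broken, samples[1].density)
    with pytest.raises(CorrespondenceError, match=samples[1].anthro.subject_id):
        pio.load_cohort(paths, tmp_path / "anthro.csv")


def test_load_cohort_missing_anthro_row(tmp_path, small_cohort):
    samples, _ = small_cohort
    paths = pio.save_cohort(tmp_path, samples[:3])
    extra = tmp_path / "stranger.vtk"
    pio.write_vtk(extra, samples[3].mesh, samples[3].density)
    with pytest.raises(KeyError, match="stranger"):
        pio.load_cohort(list(paths) + [extra], tmp_path / "anthro.csv")


def test_load_cohort_warns_on_implausible_anthropometrics(tmp_path, small_cohort):
    import pandas as pd

    samples, _ = small_cohort
    paths = pio.save_cohort(tmp_path, samples[:3])
    csv = tmp_path / "anthro.csv"
    df = pd.read_csv(csv)
    df.loc[0, "stature_cm"] = 250.0  # beyond plausible human stature
    df.to_csv(csv, index=False)
    with pytest.warns(UserWarning, match="stature"):
        pio.load_cohort(paths, csv)


# ---------------------------------------------------------------------------
# procrustes_align
# ---------------------------------------------------------------------------

def test_align_identity_when_already_aligned(small_template):
    mesh = small_template.mesh
    transform, aligned = procrustes_align(mesh, mesh)
    np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(transform.translation, 0.0, atol=1e-9)
    np.testing.assert_allclose(aligned.nodes, mesh.nodes, atol=1e-9)


def test_align_recovers_known_rigid_motion(small_template):
    mesh = small_template.mesh
    applied = RigidTransform(rot_z(30.0), np.array([5.0, -2.0, 7.0]))
    moved = mesh.with_nodes(applied.apply(mesh.nodes))
    recovered, aligned = procrustes_align(moved, mesh)
    np.testing.assert_allclose(aligned.nodes, mesh.nodes, atol=1e-8)
    np.testing.assert_allclose(recovered.rotation @ applied.rotation, np.eye(3), atol=1e-9)


def test_align_never_scales(small_template):
    """Inter-node distance ratios are exactly preserved (rigid only)."""
    mesh = small_template.mesh
    moved = mesh.with_nodes(RigidTransform(rot_z(77.0), np.array([1.0, 2.0, 3.0])).apply(mesh.nodes))
    _, aligned = procrustes_align(moved, mesh)
    idx = np.arange(0, mesh.n_nodes, 97)
    before = np.linalg.norm(moved.nodes[idx][:, None] - moved.nodes[idx][None], axis=2)
    after = np.linalg.norm(aligned.nodes[idx][:, None] - aligned.nodes[idx][None], axis=2)
    np.testing.assert_allclose(after, before, rtol=1e-12)


def test_align_reduces_mean_surface_distance(small_cohort):
    samples, _ = small_cohort  # generated at random poses
    ref = samples[0]
    for s in samples[1:]:
        _, aligned = procrustes_align(s.mesh, ref.mesh)
        assert (mean_surface_distance(aligned, ref.mesh)
                <= mean_surface_distance(s.mesh, ref.mesh) + 1e-12)


def test_align_invariant_to_initial_pose(small_template):
    """Any rigid pre-transform of the moving mesh yields the same alignment."""
    rng = np.random.default_rng(5)
    base = small_template.mesh
    # a genuinely deformed moving mesh (so the optimum is nontrivial)
    moving = base.with_nodes(base.nodes + rng.normal(0, 0.5, base.nodes.shape))
    _, aligned1 = procrustes_align(moving, base)
    pre = RigidTransform(rot_z(123.0), np.array([-30.0, 4.0, 9.0]))
    _, aligned2 = procrustes_align(moving.with_nodes(pre.apply(moving.nodes)), base)
    np.testing.assert_allclose(aligned1.nodes, aligned2.nodes, atol=1e-6)


def test_align_noisy_copy_residual_vs_bruteforce_oracle():
    """On a toy cloud moved by a z-rotation, the closed form beats (or ties)
    a fine brute-force grid search over z-rotation + optimal translation."""
    rng = np.random.default_rng(42)
    pts = rng.uniform(-10, 10, size=(10, 3))
    true_angle = 25.0
    moved = pts @ rot_z(true_angle).T + np.array([3.0, -1.0, 2.0])
    noisy = moved + rng.normal(0, 0.1, moved.shape)

    def rss(rotated):
        # optimal translation for a fixed rotation is the centroid difference
        t = pts.mean(axis=0) - rotated.mean(axis=0)
        return np.sum((rotated + t - pts) ** 2)

    grid = np.linspace(-180, 180, 14401)
    brute = min(rss(noisy @ rot_z(-a).T) for a in grid)

    # run the closed form through HexMesh machinery
    elements = np.arange(8, dtype=np.int64)[None, :]
    ref_mesh = HexMesh(nodes=pts, elements=elements, surface_node_ids=np.arange(10))
    mov_mesh = HexMesh(nodes=noisy, elements=elements, surface_node_ids=np.arange(10))
    _, aligned = procrustes_align(mov_mesh, ref_mesh)
    closed = np.sum((aligned.nodes - pts) ** 2)
    assert closed <= brute + 1e-9
    # residual RMS consistent with the injected noise level
    rms = np.sqrt(closed / pts.size)
    assert 0.05 < rms < 0.15


def test_align_degenerate_surface_errors():
    nodes = np.zeros((8, 3))
    nodes[:, 0] = np.arange(8)  # collinear
    mesh = HexMesh(nodes=nodes, elements=np.arange(8, dtype=np.int64)[None, :],
                   surface_node_ids=np.arange(8))
    with pytest.raises(AlignmentError):
        procrustes_align(mesh, mesh)


def test_align_topology_mismatch():
    a = make_box_mesh()
    permuted = a.elements.copy()[:, ::-1]
    b = HexMesh(nodes=a.nodes, elements=permuted, surface_node_ids=a.surface_node_ids)
    with pytest.raises(CorrespondenceError):
        procrustes_align(a, b)


# ---------------------------------------------------------------------------
# align_cohort
# ---------------------------------------------------------------------------

def test_align_cohort_posed_copies_converge(small_template):
    rng = np.random.default_rng(3)
    base = small_template.mesh
    samples = []
    for i in range(4):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        tr = RigidTransform(R, rng.uniform(-30, 30, 3))
        samples.append(make_sample(base.with_nodes(tr.apply(base.nodes)),
                                   subject_id=f"s{i}"))
    aligned = align_cohort(samples, 0)
    for s in aligned[1:]:
        np.testing.assert_allclose(s.mesh.nodes, aligned[0].mesh.nodes, atol=1e-8)


def test_align_cohort_reference_untouched_density_untouched(small_cohort):
    samples, _ = small_cohort
    aligned = align_cohort(samples, 1)
    assert aligned[1] is samples[1]
    for a, b in zip(aligned, samples):
        assert a.density is b.density


def test_align_cohort_is_involution(small_cohort):
    samples, _ = small_cohort
    once = align_cohort(samples, 0)
    twice = align_cohort(once, 0)
    for a, b in zip(once, twice):
        assert np.abs(a.mesh.nodes - b.mesh.nodes).max() < 1e-8


def test_align_cohort_index_error(small_cohort):
    samples, _ = small_cohort
    with pytest.raises(IndexError):
        align_cohort(samples, len(samples))
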