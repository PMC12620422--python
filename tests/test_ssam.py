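"""PCA model construction, projection/reconstruction, compactness, mode
variation and pv-anthropometry correlations."""

import numpy as np
import pytest

from parafemur.mesh import AnthropometricRecord, CorrespondenceError, DensityField
from parafemur.ssam import (
    build_model,
    compactness,
    devectorize,
    load_model,
    mode_variation,
    project,
    pv_anthro_correlations,
    reconstruct,
    save_model,
    vectorize,
)

from conftest import make_box_mesh, make_sample


def dense_covariance_oracle(X: np.ndarray):
    """Eigendecomposition of the 1/N covariance, sign-canonicalized."""
    N = X.shape[0]
    Xc = X - X.mean(axis=0)
    D = Xc.T @ Xc / N
    w, V = np.linalg.eigh(D)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    for j in range(V.shape[1]):
        idx = int(np.argmax(np.abs(V[:, j])))
        if V[idx, j] < 0:
            V[:, j] = -V[:, j]
    return w, V


# ---------------------------------------------------------------------------
# vectorize / devectorize
# ---------------------------------------------------------------------------

def test_vectorize_shape_interleaves_xyz():
    sample = make_sample(make_box_mesh())
    v = vectorize(sample, "shape")
    np.testing.assert_allclose(v[:6], [0, 0, 0, 1, 0, 0])
    assert v.shape == (24,)


def test_vectorize_appearance_and_roundtrips():
    sample = make_sample(make_box_mesh(), DensityField(values=np.array([0.5])))
    np.testing.assert_allclose(vectorize(sample, "appearance"), [0.5])
    for channel in ("shape", "appearance"):
        v = vectorize(sample, channel)
        back = devectorize(v, sample, channel)
        np.testing.assert_array_equal(vectorize(back, channel), v)
    with pytest.raises(ValueError):
        vectorize(sample, "intensity")


# ---------------------------------------------------------------------------
# build_model
# ---------------------------------------------------------------------------

def test_two_vector_cohort_hand_computed():
    """Cohort {(0,0), (2,2)}: mean (1,1), single PC along (1,1)/sqrt(2),
    pvs -/+ sqrt(2), and the 1/N covariance eigenvalue is 2."""
    model = build_model([np.array([0.0, 0.0]), np.array([2.0, 2.0])])
    np.testing.assert_allclose(model.mean_vector, [1.0, 1.0])
    assert model.n_modes == 1
    np.testing.assert_allclose(np.abs(model.components[:, 0]),
                               [1 / np.sqrt(2)] * 2, atol=1e-12)
    assert model.components[:, 0].max() > 0  # sign canonicalization
    np.testing.assert_allclose(np.sort(model.pv_matrix[:, 0]),
                               [-np.sqrt(2), np.sqrt(2)], atol=1e-12)
    assert model.singular_values[0] == pytest.approx(2.0, abs=1e-12)
    assert model.pv_sd[0] == pytest.approx(np.sqrt(2.0), abs=1e-12)


def test_identical_cohort_degenerates_to_mean():
    vecs = [np.array([3.0, 1.0, 4.0])] * 4
    model = build_model(vecs)
    assert model.n_modes == 0
    assert project(vecs[0], model).size == 0
    np.testing.assert_allclose(reconstruct(np.array([]), model), vecs[0])


def test_build_model_matches_dense_covariance_oracle():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(6, 40))
    model = build_model(list(X))
    w, V = dense_covariance_oracle(X)
    K = model.n_modes
    assert K == 5
    np.testing.assert_allclose(model.singular_values, w[:K], atol=1e-8)
    np.testing.assert_allclose(model.components, V[:, :K], atol=1e-8)


def test_build_model_input_validation():
    with pytest.raises(CorrespondenceError):
        build_model([np.zeros(3), np.zeros(4)])
    with pytest.raises(ValueError):
        build_model([np.zeros(3)])


def test_pv_columns_centered_and_orthonormal_components():
    rng = np.random.default_rng(7)
    model = build_model(list(rng.normal(size=(8, 30))))
    U = model.components
    np.testing.assert_allclose(U.T @ U, np.eye(model.n_modes), atol=1e-10)
    np.testing.assert_allclose(model.pv_matrix.mean(axis=0), 0.0, atol=1e-8)


def test_energy_conservation():
    """Sum of retained eigenvalues equals the covariance trace."""
    rng = np.random.default_rng(8)
    X = rng.normal(size=(7, 25))
    model = build_model(list(X))
    Xc = X - X.mean(axis=0)
    trace = np.trace(Xc.T @ Xc / X.shape[0])
    assert model.singular_values.sum() == pytest.approx(trace, rel=1e-6)


# ---------------------------------------------------------------------------
# project / reconstruct
# ---------------------------------------------------------------------------

def test_projection_special_cases():
    rng = np.random.default_rng(9)
    model = build_model(list(rng.normal(size=(6, 20))))
    np.testing.assert_allclose(project(model.mean_vector, model), 0.0, atol=1e-12)
    s = model.mean_vector + 3.0 * model.components[:, 0]
    pv = project(s, model)
    assert pv[0] == pytest.approx(3.0, abs=1e-10)
    np.testing.assert_allclose(pv[1:], 0.0, atol=1e-10)
    with pytest.raises(ValueError):
        project(np.zeros(21), model)


def test_training_member_projection_matches_pv_matrix():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(6, 20))
    model = build_model(list(X))
    for i in range(6):
        np.testing.assert_allclose(project(X[i], model), model.pv_matrix[i], atol=1e-10)


def test_full_rank_roundtrip_and_truncation_parseval():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(6, 20))
    model = build_model(list(X))
    for i in range(6):
        pv = project(X[i], model)
        np.testing.assert_allclose(reconstruct(pv, model), X[i], atol=1e-6)
        # Parseval: k=1 truncation error norm equals the discarded pv norm
        recon1 = reconstruct(pv, model, k=1)
        err = np.linalg.norm(X[i] - recon1)
        assert err == pytest.approx(np.linalg.norm(pv[1:]), rel=1e-9)
    with pytest.raises(ValueError):
        reconstruct(np.zeros(model.n_modes), model, k=model.n_modes + 1)


def test_reconstruct_zero_b_gives_mean():
    rng = np.random.default_rng(12)
    model = build_model(list(rng.normal(size=(5, 12))))
    np.testing.assert_allclose(reconstruct(np.zeros(model.n_modes), model),
                               model.mean_vector)


# ---------------------------------------------------------------------------
# compactness
# ---------------------------------------------------------------------------

def test_compactness_rank2_cohort_hits_zero_at_two_modes():
    rng = np.random.default_rng(13)
    base = rng.normal(size=(2, 30))
    coeffs = rng.normal(size=(7, 2))
    X = coeffs @ base
    model = build_model(list(X))
    curve = compactness(model, list(X))
    assert curve.errors[1] < 1e-10
    assert np.all(np.diff(curve.errors) <= 1e-12)  # monotone non-increasing
    assert curve.errors[-1] < 1e-6


def test_compactness_matches_naive_loop_oracle():
    rng = np.random.default_rng(14)
    X = rng.normal(size=(5, 16))
    model = build_model(list(X))
    curve = compactness(model, list(X))
    for k in range(1, model.n_modes + 1):
        errs = []
        for i in range(5):
            pv = model.components.T @ (X[i] - model.mean_vector)
            recon = model.mean_vector.copy()
            for j in range(k):
                recon = recon + pv[j] * model.components[:, j]
            errs.append(np.abs(X[i] - recon).mean())
        assert curve.errors[k - 1] == pytest.approx(np.mean(errs), rel=1e-10)


def test_compactness_per_node_metric_smaller_dimension():
    rng = np.random.default_rng(15)
    X = rng.normal(size=(4, 12))  # 4 nodes worth of shape entries
    model = build_model(list(X), channel="shape")
    per_coord = compactness(model, list(X)).errors
    per_node = compactness(model, list(X), per_node=True).errors
    # per-node Euclidean error is >= per-coordinate absolute error
    assert np.all(per_node >= per_coord - 1e-12)


# ---------------------------------------------------------------------------
# mode variation
# ---------------------------------------------------------------------------

def test_mode_variation_conventions():
    rng = np.random.default_rng(16)
    model = build_model(list(rng.normal(size=(6, 18))))
    np.testing.assert_allclose(mode_variation(model, 1, 0.0, include_mean=True),
                               model.mean_vector)
    plus = mode_variation(model, 1, +1.0)
    minus = mode_variation(model, 1, -1.0)
    np.testing.assert_allclose((plus + minus) / 2.0, model.mean_vector, atol=1e-12)
    delta = mode_variation(model, 2, +1.0, include_mean=False)
    assert np.linalg.norm(delta) == pytest.approx(model.pv_sd[1], rel=1e-10)
    with pytest.raises(ValueError):
        mode_variation(model, model.n_modes + 1)


# ---------------------------------------------------------------------------
# pv-anthropometry correlations
# ---------------------------------------------------------------------------

def _records(stature, bmi, age):
    return [AnthropometricRecord(subject_id=f"s{i}", stature=s, bmi=b, age=a)
            for i, (s, b, a) in enumerate(zip(stature, bmi, age))]


def test_correlation_exact_linear_pv():
    rng = np.random.default_rng(17)
    age = rng.uniform(50, 70, size=10)
    # a rank-2 cohort whose first pv is an exact linear function of age
    X = np.outer(2 * age + 1, np.ones(12))
    X[:, 6:] += rng.normal(size=(10, 6)) * 1e-6
    model = build_model(list(X))
    recs = _records(rng.uniform(150, 175, 10), rng.uniform(20, 35, 10), age)
    table = pv_anthro_correlations(model, recs)
    row = table[(table["mode"] == 1) & (table["predictor"] == "age")].iloc[0]
    assert abs(row.r) > 0.999999
    assert row.p < 1e-10


def test_correlation_matches_two_pass_pearson_oracle():
    rng = np.random.default_rng(18)
    X = rng.normal(size=(12, 9))
    model = build_model(list(X))
    recs = _records(rng.uniform(150, 175, 12), rng.uniform(20, 35, 12),
                    rng.uniform(50, 70, 12))
    table = pv_anthro_correlations(model, recs)
    age = np.array([r.age for r in recs])
    pv0 = model.pv_matrix[:, 0]
    r_oracle = (np.sum((age - age.mean()) * (pv0 - pv0.mean()))
                / np.sqrt(np.sum((age - age.mean()) ** 2) * np.sum((pv0 - pv0.mean()) ** 2)))
    row = table[(table["mode"] == 1) & (table["predictor"] == "age")].iloc[0]
    assert row.r == pytest.approx(r_oracle, rel=1e-10)


def test_correlation_shuffled_predictor_is_weak():
    rng = np.random.default_rng(19)
    n = 60
    X = rng.normal(size=(n, 10))
    model = build_model(list(X))
    recs = _records(rng.uniform(150, 175, n), rng.uniform(20, 35, n),
                    rng.permutation(np.linspace(50, 70, n)))
    table = pv_anthro_correlations(model, recs)
    assert np.abs(table["r"].to_numpy()).max() < 0.5


def test_correlation_zero_variance_predictor_flagged():
    rng = np.random.default_rng(20)
    X = rng.normal(size=(6, 8))
    model = build_model(list(X))
    recs = _records([160.0] * 6, rng.uniform(20, 35, 6), rng.uniform(50, 70, 6))
    table = pv_anthro_correlations(model, recs)
    stature_rows = table[table["predictor"] == "stature"]
    assert not stature_rows["defined"].any()
    assert table[table["predictor"] == "age"]["defined"].all()


# ---------------------------------------------------------------------------
# archive round trip
# ---------------------------------------------------------------------------

def test_model_archive_roundtrip(tmp_path):
    rng = np.random.default_rng(21)
    model = build_model(list(rng.normal(size=(5, 14))), channel="appearance",
                        topology_hash="abc123")
    path = tmp_path / "model.npz"
    save_model(path, model)
    loaded = load_model(path)
    assert loaded.channel == "appearance"
    assert loaded.topology_hash == "abc123"
    assert loaded.cohort_size == 5
    np.testing.assert_array_equal(loaded.components, model.components)
    np.testing.assert_array_equal(loaded.pv_matrix, model.pv_matrix)
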