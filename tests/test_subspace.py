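"""Window construction, projection classifier, Grassmannian distances."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from ca2sse.features import N_FEATURES, compute_feature_matrix
from ca2sse.geometry import random_rotation
from ca2sse.subspace import (
    LocalSubspaceClassifier,
    Model2Config,
    SSESubspaceModel,
    SubspaceProjectionClassifier,
    WindowConfig,
    build_windows,
    chordal_distance,
    classify_model1,
    classify_model2,
    fit_sse_subspaces,
    load_model,
    principal_angles,
    projection_distance,
    save_model,
    window_vectors,
)
from ca2sse.synthetic import make_helix
from ca2sse.trace import LabelSequence


# -- window bookkeeping ------------------------------------------------------

@pytest.mark.parametrize("n", list(range(10, 31)))
def test_window_count_formula(n):
    """q=7 plus the i+-3 feature context yields max(0, N-12) windows."""
    trace, labels = make_helix(n)
    F = compute_feature_matrix(trace)
    wm = build_windows(F, labels, WindowConfig())
    total = sum(W.shape[1] for W in wm.by_class.values())
    assert total == max(0, n - 12)
    assert wm.by_class["H"].shape == (7 * N_FEATURES, total)


def test_window_slide_halves_count():
    trace, labels = make_helix(26)  # 14 windows at z=1
    F = compute_feature_matrix(trace)
    n1 = sum(w.shape[1] for w in
             build_windows(F, labels, WindowConfig(z=1)).by_class.values())
    n2 = sum(w.shape[1] for w in
             build_windows(F, labels, WindowConfig(z=2)).by_class.values())
    assert n1 == 14 and n2 == (n1 + 1) // 2


def test_windows_grouped_by_center_label():
    trace, _ = make_helix(20)
    labels = LabelSequence(["H"] * 10 + ["E"] * 10, "truth")
    wm = build_windows(compute_feature_matrix(trace), labels, WindowConfig())
    assert wm.by_class["H"].shape[1] == 4   # centers 6..9
    assert wm.by_class["E"].shape[1] == 4   # centers 10..13
    assert wm.by_class["L"].shape[1] == 0


# -- projection distance -----------------------------------------------------

def test_projection_distance_residual():
    basis = np.eye(3)[:, :2]
    assert projection_distance(np.array([1.0, 2.0, 2.0]), basis) == \
        pytest.approx(2.0, abs=1e-12)
    assert projection_distance(np.array([3.0, -1.0, 0.0]), basis) == \
        pytest.approx(0.0, abs=1e-12)


def test_projection_distance_equals_least_squares():
    """Brute-force oracle: min_x ||w - Bx|| over 1000 random pairs."""
    rng = np.random.default_rng(7)
    for _ in range(1000):
        d = int(rng.integers(3, 12))
        r = int(rng.integers(1, d))
        B = np.linalg.qr(rng.normal(size=(d, r)))[0]
        w = rng.normal(size=d)
        ref = np.linalg.norm(w - B @ np.linalg.lstsq(B, w, rcond=None)[0])
        assert projection_distance(w, B) == pytest.approx(ref, abs=1e-10)


def test_projection_distance_bounded_by_norm():
    rng = np.random.default_rng(11)
    B = np.linalg.qr(rng.normal(size=(6, 2)))[0]
    for _ in range(50):
        w = rng.normal(size=6)
        assert projection_distance(w, B) <= np.linalg.norm(w) + 1e-12


def test_projection_distance_shape_mismatch():
    with pytest.raises(ValueError):
        projection_distance(np.ones(4), np.eye(3)[:, :2])


# -- principal angles / chordal distance -------------------------------------

def test_principal_angles_closed_forms():
    e = np.eye(3)
    assert np.allclose(principal_angles(e[:, :2], e[:, :2]), [0, 0], atol=1e-10)
    assert np.allclose(principal_angles(e[:, :1], e[:, 1:2]), [90], atol=1e-10)
    B = np.column_stack([e[:, 0], (e[:, 1] + e[:, 2]) / np.sqrt(2)])
    assert np.allclose(principal_angles(e[:, :2], B), [0, 45], atol=1e-10)
    assert chordal_distance(e[:, :2], B) == pytest.approx(0.70711, abs=1e-5)
    assert chordal_distance(e[:, :1], e[:, 1:2]) == pytest.approx(1.0, abs=1e-12)


def test_principal_angles_match_scipy():
    rng = np.random.default_rng(0)
    for _ in range(20):
        A = rng.normal(size=(8, 3))
        B = rng.normal(size=(8, 2))
        ours = principal_angles(A, B)
        ref = np.sort(np.degrees(subspace_angles(A, B)))
        assert np.allclose(ours, ref, atol=1e-8)


def test_chordal_distance_metric_properties():
    rng = np.random.default_rng(3)
    A = rng.normal(size=(10, 3))
    B = rng.normal(size=(10, 3))
    assert chordal_distance(A, B) == pytest.approx(chordal_distance(B, A),
                                                   abs=1e-10)
    assert chordal_distance(A, A) == pytest.approx(0.0, abs=1e-7)
    # invariance to basis choice: mixing columns changes nothing
    M = rng.normal(size=(3, 3))  # invertible w.h.p.
    assert chordal_distance(A @ M, B) == pytest.approx(
        chordal_distance(A, B), abs=1e-10)


def test_empty_basis_errors():
    with pytest.raises(ValueError):
        principal_angles(np.empty((4, 0)), np.eye(4)[:, :1])


# -- subspace fitting --------------------------------------------------------

def _planted_windows(rng, dim, rank, n, noise=1e-6):
    basis = np.linalg.qr(rng.normal(size=(dim, rank)))[0]
    X = rng.normal(size=(n, rank)) @ basis.T + noise * rng.normal(size=(n, dim))
    return basis, X


def test_fit_recovers_planted_subspace():
    rng = np.random.default_rng(5)
    basis, X = _planted_windows(rng, 30, 3, 200)
    clf = SubspaceProjectionClassifier(rank_strategy="gap").fit(
        X, np.array(["H"] * 200))
    assert clf.ranks_["H"] == 3
    assert chordal_distance(clf.bases_["H"], basis) < 1e-3


def test_fit_identical_columns_rank_one():
    w = np.arange(1.0, 9.0)
    X = np.tile(w, (10, 1))
    clf = SubspaceProjectionClassifier().fit(X, np.array(["L"] * 10))
    assert clf.ranks_["L"] == 1
    assert np.allclose(np.abs(clf.bases_["L"][:, 0]), w / np.linalg.norm(w),
                       atol=1e-10)


def test_orthogonal_planted_classes_stay_orthogonal():
    rng = np.random.default_rng(8)
    e = np.eye(40)
    bH, bE = e[:, :3], e[:, 3:6]
    XH = rng.normal(size=(100, 3)) @ bH.T + 1e-8 * rng.normal(size=(100, 40))
    XE = rng.normal(size=(100, 3)) @ bE.T + 1e-8 * rng.normal(size=(100, 40))
    clf = SubspaceProjectionClassifier(rank_strategy="gap").fit(
        np.vstack([XH, XE]), np.array(["H"] * 100 + ["E"] * 100))
    assert principal_angles(clf.bases_["H"], clf.bases_["E"]).min() > 89.9


def test_classify_planted_corpus_perfectly():
    """Three orthogonal planted class subspaces: training distribution is
    classified without error by the projection rule."""
    rng = np.random.default_rng(13)
    e = np.eye(60)
    X, y = [], []
    for lab, cols in (("H", slice(0, 4)), ("E", slice(4, 8)), ("L", slice(8, 12))):
        Xc = rng.normal(size=(120, 4)) @ e[:, cols].T
        Xc += 1e-7 * rng.normal(size=Xc.shape)
        X.append(Xc)
        y += [lab] * 120
    X, y = np.vstack(X), np.array(y)
    clf = SubspaceProjectionClassifier(rank_strategy="gap").fit(X, y)
    assert (clf.predict(X) == y).all()


def test_exact_tie_prefers_loop():
    e = np.eye(4)
    clf = SubspaceProjectionClassifier()
    clf.classes_ = np.array(["H", "L"])
    clf.bases_ = {"H": e[:, :1], "L": e[:, 1:2]}
    clf.ranks_ = {"H": 1, "L": 1}
    clf.n_features_in_ = 4
    w = e[:, 0] + e[:, 1]  # equidistant from both axes
    assert clf.predict(w[None])[0] == "L"


def test_empty_class_errors():
    X = np.random.default_rng(0).normal(size=(5, 8))
    clf = SubspaceProjectionClassifier()
    with pytest.raises(ValueError):
        fit_sse_subspaces([make_helix(20)[0]],
                          [LabelSequence(["H"] * 20, "truth")])
    clf.fit(X, np.array(["H"] * 5))  # single class at the estimator level is fine


def test_local_classifier_two_window_smoke():
    rng = np.random.default_rng(2)
    basis, X = _planted_windows(rng, 20, 2, 50)
    clf = LocalSubspaceClassifier(n_local=2, local_rank="estimate",
                                  center_weight=1.0).fit(
        X, np.array(["E"] * 50))
    pred = clf.predict(X[:4])
    assert list(pred) == ["E"] * 4


def test_local_windows_in_class_subspace_give_zero_distance():
    rng = np.random.default_rng(4)
    basis, X = _planted_windows(rng, 24, 3, 80, noise=0.0)
    clf = LocalSubspaceClassifier(rank_strategy="gap").fit(
        X, np.array(["E"] * 80))
    local = clf._local_basis(X[:5], 2)
    assert chordal_distance(local, clf.bases_["E"]) < 1e-6


# -- trace-level classification ----------------------------------------------

def test_classify_model1_rigid_motion_invariant(benchmark):
    model = benchmark["model"]
    trace, _ = benchmark["test"][0]
    rng = np.random.default_rng(21)
    moved = trace.transformed(random_rotation(rng), rng.normal(size=3))
    assert list(classify_model1(trace, model)) == \
        list(classify_model1(moved, model))


def test_classify_model2_runs_and_marks_short_chfar(benchmark):
    model = benchmark["model"]
    trace, _ = make_helix(30, jitter_sd=0.1, seed=3)
    labels = classify_model2(trace, model)
    inner = list(labels)[6:-6]
    assert set(inner) <= {"H", "E", "L"}
    # ends have no valid window
    assert list(labels)[:6] == ["U"] * 6


def test_model_version_and_dimension_guard(benchmark, tmp_path):
    model = benchmark["model"]
    path = tmp_path / "m.json"
    save_model(model, path)
    loaded = load_model(path)
    bad = SSESubspaceModel(loaded.classifier, loaded.means, loaded.scales,
                           WindowConfig(q=5))
    with pytest.raises(ValueError, match="dimension"):
        classify_model1(make_helix(20, jitter_sd=0.05, seed=1)[0], bad)


def test_model_json_round_trip(benchmark, tmp_path):
    model = benchmark["model"]
    path = tmp_path / "model.json"
    save_model(model, path)
    loaded = load_model(path)
    trace, _ = benchmark["test"][1]
    assert list(classify_model1(trace, model)) == \
        list(classify_model1(trace, loaded))
    for lab, B in model.classifier.bases_.items():
        assert np.allclose(loaded.classifier.bases_[lab], B, atol=0)
        # orthonormality is preserved
        assert np.allclose(B.T @ B, np.eye(B.shape[1]), atol=1e-10)
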