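"""Union-of-subspaces secondary-structure classification.

Training stacks the standardized 39-feature descriptors of q
consecutive residues into one (q*d)-dimensional window vector, groups
windows by the truth label of the center residue, and fits one low-rank
subspace per class from the leading left singular vectors of each class
matrix.

Two classifiers share the fitted class subspaces:

* the projection classifier labels a window by the smallest residual
  norm ``||(I - U U^T) w||`` over the class bases (Model 1);
* the local-subspace classifier fits a small subspace to the windows of
  the sequence-nearest residues and labels by the smallest chordal
  distance on the Grassmannian between that local subspace and each
  class subspace (Model 2).

Both are exposed as scikit-learn estimators operating on window
vectors, with trace-level convenience functions on top.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .features import FeatureMatrix, N_FEATURES, compute_feature_matrix, estimate_rank
from .trace import CaTrace, LabelSequence, LABELS, UNRESOLVED

__all__ = [
    "WindowConfig",
    "Model2Config",
    "WindowMatrix",
    "build_windows",
    "projection_distance",
    "principal_angles",
    "chordal_distance",
    "SubspaceProjectionClassifier",
    "LocalSubspaceClassifier",
    "SSESubspaceModel",
    "fit_sse_subspaces",
    "classify_model1",
    "classify_model2",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

#: argmin tie preference: loop is the "neither helix nor sheet" class.
TIE_ORDER = ("L", "E", "H")


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window and rank-estimation settings."""

    q: int = 7            # residues per window (odd)
    z: int = 1            # window slide
    standardize: bool = True
    rank_strategy: str = "energy"
    tau: float = 0.95

    def __post_init__(self):
        if self.q < 3 or self.q % 2 == 0:
            raise ValueError("window size q must be odd and >= 3")
        if self.z < 1:
            raise ValueError("window slide z must be >= 1")


@dataclass(frozen=True)
class Model2Config:
    """Local-subspace (Model 2) settings.

    ``n_local`` windows centered on the query residue form the local
    matrix; the center column is up-weighted by ``center_weight``
    (a triangular kernel) so the local subspace describes the query
    window with contextual support instead of a flat average, which
    blurs segment boundaries.  ``local_rank`` is either a fixed
    truncation (default 1: the consensus direction) or ``"estimate"``
    to truncate at the effective rank of the local matrix.
    """

    n_local: int = 3      # windows per local neighborhood
    local_rank: int | str = 1
    center_weight: float = 2.0
    rank_strategy: str = "energy"
    tau: float = 0.95

    def __post_init__(self):
        if self.n_local < 2:
            raise ValueError("n_local must be >= 2")
        if isinstance(self.local_rank, str) and self.local_rank != "estimate":
            raise ValueError("local_rank must be an integer or 'estimate'")
        if self.center_weight <= 0:
            raise ValueError("center_weight must be positive")


@dataclass
class WindowMatrix:
    """Per-class (q*d) x n window matrices plus center bookkeeping."""

    by_class: dict
    centers: dict
    n_skipped: int = 0

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All windows as (n_samples, q*d) with their labels."""
        Xs, ys = [], []
        for lab, W in self.by_class.items():
            if W.shape[1]:
                Xs.append(W.T)
                ys.extend([lab] * W.shape[1])
        if not Xs:
            return np.empty((0, 0)), np.array([], dtype=object)
        return np.vstack(Xs), np.array(ys)


def window_vectors(F: FeatureMatrix, cfg: WindowConfig,
                   means: np.ndarray | None = None,
                   scales: np.ndarray | None = None):
    """Valid window vectors of one chain.

    Returns ``(X, centers)`` where row k of X is the stacked descriptor
    of the window centered on residue ``centers[k]``.  A window is valid
    only when all q member columns are fully valid.  Standardization
    (per-feature z-score) is applied before stacking when means/scales
    are given.
    """
    q, z = cfg.q, cfg.z
    half = q // 2
    vals = F.values
    if means is not None:
        vals = (vals - means[:, None]) / scales[:, None]
    colok = F.column_valid()
    rows, centers = [], []
    for center in range(half, F.n_residues - half, z):
        if colok[center - half:center + half + 1].all():
            rows.append(vals[:, center - half:center + half + 1].T.ravel())
            centers.append(center)
    X = np.array(rows) if rows else np.empty((0, q * N_FEATURES))
    return X, np.array(centers, dtype=int)


def build_windows(F: FeatureMatrix, truth: LabelSequence, cfg: WindowConfig,
                  means: np.ndarray | None = None,
                  scales: np.ndarray | None = None) -> WindowMatrix:
    """Assign each valid window to the class of its center residue."""
    if F.n_residues != len(truth):
        raise ValueError("features and labels are not aligned")
    X, centers = window_vectors(F, cfg, means, scales)
    qd = cfg.q * N_FEATURES
    by_class = {lab: [] for lab in LABELS}
    ctrs = {lab: [] for lab in LABELS}
    for row, c in zip(X, centers):
        lab = truth[c]
        if lab in by_class:
            by_class[lab].append(row)
            ctrs[lab].append(c)
    n_possible = max(0, (F.n_residues - cfg.q + 1 + cfg.z - 1) // cfg.z)
    wm = WindowMatrix(
        {lab: (np.array(v).T if v else np.empty((qd, 0))) for lab, v in by_class.items()},
        {lab: np.array(v, dtype=int) for lab, v in ctrs.items()},
        n_skipped=n_possible - len(centers),
    )
    return wm


def projection_distance(w: np.ndarray, basis: np.ndarray) -> float | np.ndarray:
    """Residual norm of ``w`` after orthogonal projection onto span(basis).

    ``w`` may be a single vector or an (n, dim) array of rows.
    """
    basis = np.asarray(basis, dtype=float)
    w = np.asarray(w, dtype=float)
    single = w.ndim == 1
    W = np.atleast_2d(w)
    if W.shape[1] != basis.shape[0]:
        raise ValueError(
            f"dimension mismatch: vectors in R^{W.shape[1]}, basis in "
            f"R^{basis.shape[0]}")
    resid = W - (W @ basis) @ basis.T
    d = np.linalg.norm(resid, axis=1)
    return float(d[0]) if single else d


def _orthonormalize(A: np.ndarray) -> np.ndarray:
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.shape[1] == 0 or A.size == 0:
        raise ValueError("empty basis")
    Q, _ = np.linalg.qr(A)
    return Q


def principal_angles(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Principal angles between span(A) and span(B), degrees, ascending.

    Cosines are the singular values of Qa^T Qb (clipped to [0, 1]).
    """
    Qa, Qb = _orthonormalize(A), _orthonormalize(B)
    if Qa.shape[0] != Qb.shape[0]:
        raise ValueError("bases live in different ambient dimensions")
    sv = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    p = min(Qa.shape[1], Qb.shape[1])
    sv = np.clip(sv[:p], 0.0, 1.0)
    return np.sort(np.degrees(np.arccos(sv)))  # ascending angles


def chordal_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Chordal Grassmannian distance sqrt(sum sin^2 theta_j)."""
    theta = np.radians(principal_angles(A, B))
    return float(np.sqrt(np.sum(np.sin(theta) ** 2)))


class SubspaceProjectionClassifier(ClassifierMixin, BaseEstimator):
    """Classify window vectors by projection distance to class subspaces.

    Parameters
    ----------
    rank_strategy, tau:
        Effective-rank criterion used to truncate each class SVD.
    tie_order:
        Preference order when distances tie exactly.
    """

    def __init__(self, rank_strategy: str = "energy", tau: float = 0.95,
                 tie_order: tuple = TIE_ORDER):
        self.rank_strategy = rank_strategy
        self.tau = tau
        self.tie_order = tie_order

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        self.classes_ = np.unique(y)
        self.bases_ = {}
        self.ranks_ = {}
        for lab in self.classes_:
            W = X[y == lab].T  # (qd, n_c)
            if W.shape[1] == 0:
                raise ValueError(f"class {lab!r} has no training windows")
            U, sv, _ = np.linalg.svd(W, full_matrices=False)
            r = max(1, estimate_rank(W, self.rank_strategy, self.tau))
            self.bases_[lab] = U[:, :r]
            self.ranks_[lab] = r
        self.n_features_in_ = X.shape[1]
        return self

    def decision_distances(self, X) -> np.ndarray:
        """(n_samples, n_classes) matrix of projection distances."""
        check_is_fitted(self, "bases_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([
            projection_distance(X, self.bases_[lab]) for lab in self.classes_
        ])

    def _argmin_labels(self, D: np.ndarray) -> np.ndarray:
        pref = {lab: self.tie_order.index(lab) if lab in self.tie_order else 99
                for lab in self.classes_}
        out = []
        for row in D:
            m = row.min()
            tied = [lab for lab, d in zip(self.classes_, row) if d <= m + 1e-12]
            out.append(min(tied, key=lambda lab: pref[lab]))
        return np.array(out)

    def predict(self, X) -> np.ndarray:
        return self._argmin_labels(self.decision_distances(X))


class LocalSubspaceClassifier(SubspaceProjectionClassifier):
    """Model 2: label via chordal distance of a local window subspace.

    ``predict`` treats the rows of X as the valid windows of one chain
    in sequence order: for each row the ``n_local`` sequence-nearest
    windows (the row itself centered, clipped at the chain ends) form a
    local matrix -- center column up-weighted by ``center_weight`` --
    whose truncated left singular vectors define the local subspace;
    the predicted class minimizes the chordal distance between that
    subspace and the class subspace.
    """

    def __init__(self, rank_strategy: str = "energy", tau: float = 0.95,
                 tie_order: tuple = TIE_ORDER, n_local: int = 3,
                 local_rank: int | str = 1, center_weight: float = 2.0):
        super().__init__(rank_strategy, tau, tie_order)
        self.n_local = n_local
        self.local_rank = local_rank
        self.center_weight = center_weight

    def _local_basis(self, X: np.ndarray, k: int) -> np.ndarray:
        take = min(2 * (self.n_local // 2) + 1, len(X))
        lo = max(0, min(k - take // 2, len(X) - take))
        L = X[lo:lo + take].T.copy()  # (qd, n_local)
        L[:, k - lo] *= self.center_weight
        U, _, _ = np.linalg.svd(L, full_matrices=False)
        if self.local_rank == "estimate":
            r = max(1, estimate_rank(L, self.rank_strategy, self.tau))
        else:
            r = min(int(self.local_rank), U.shape[1])
        return U[:, :r]

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "bases_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if len(X) < self.n_local:
            raise ValueError(
                f"need at least n_local={self.n_local} valid windows, got {len(X)}")
        D = np.empty((len(X), len(self.classes_)))
        for k in range(len(X)):
            local = self._local_basis(X, k)
            D[k] = [chordal_distance(local, self.bases_[lab])
                    for lab in self.classes_]
        return self._argmin_labels(D)


@dataclass
class SSESubspaceModel:
    """Fitted class subspaces plus the standardization that produced them."""

    classifier: SubspaceProjectionClassifier
    means: np.ndarray           # (39,)
    scales: np.ndarray          # (39,)
    config: WindowConfig = field(default_factory=WindowConfig)
    version: int = MODEL_FORMAT_VERSION

    @property
    def qd(self) -> int:
        return self.config.q * N_FEATURES


def _training_standardization(fms: list[FeatureMatrix]):
    cols = np.hstack([fm.values[:, fm.column_valid()] for fm in fms])
    if cols.shape[1] == 0:
        raise ValueError("no fully valid residues in the training set")
    means = cols.mean(axis=1)
    scales = cols.std(axis=1)
    scales[scales < 1e-9] = 1.0
    return means, scales


def fit_sse_subspaces(traces: list[CaTrace], truths: list[LabelSequence],
                      cfg: WindowConfig = WindowConfig()) -> SSESubspaceModel:
    """Train one subspace per SSE class from labeled traces."""
    fms = [compute_feature_matrix(t) for t in traces]
    if cfg.standardize:
        means, scales = _training_standardization(fms)
    else:
        means, scales = np.zeros(N_FEATURES), np.ones(N_FEATURES)
    Xs, ys = [], []
    for fm, truth in zip(fms, truths):
        wm = build_windows(fm, truth, cfg, means, scales)
        X, y = wm.stacked()
        if len(y):
            Xs.append(X)
            ys.append(y)
    if not Xs:
        raise ValueError("no valid training windows")
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    for lab in LABELS:
        if lab not in set(y):
            raise ValueError(f"class {lab!r} has no training windows")
    clf = SubspaceProjectionClassifier(cfg.rank_strategy, cfg.tau).fit(X, y)
    return SSESubspaceModel(clf, means, scales, cfg)


def _check_model(trace_dim: int, model: SSESubspaceModel):
    if model.version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {model.version} != {MODEL_FORMAT_VERSION}")
    if trace_dim != model.qd:
        raise ValueError(
            f"window dimension mismatch: model expects {model.qd}, got {trace_dim}")


def classify_model1(trace: CaTrace, model: SSESubspaceModel) -> LabelSequence:
    """Projection-distance classification of one trace (Model 1).

    Residues without a fully valid window are labeled U (unresolved);
    post-processing resolves them from their neighbors.
    """
    fm = compute_feature_matrix(trace)
    X, centers = window_vectors(fm, model.config, model.means, model.scales)
    labels = [UNRESOLVED] * len(trace)
    if len(X):
        _check_model(X.shape[1], model)
        for c, lab in zip(centers, model.classifier.predict(X)):
            labels[c] = str(lab)
    return LabelSequence(labels, provenance="model1")


def classify_model2(trace: CaTrace, model: SSESubspaceModel,
                    cfg: Model2Config = Model2Config()) -> LabelSequence:
    """Local-subspace / chordal-distance classification (Model 2)."""
    fm = compute_feature_matrix(trace)
    X, centers = window_vectors(fm, model.config, model.means, model.scales)
    labels = [UNRESOLVED] * len(trace)
    if len(X) >= cfg.n_local:
        _check_model(X.shape[1], model)
        local = LocalSubspaceClassifier(cfg.rank_strategy, cfg.tau,
                                        n_local=cfg.n_local,
                                        local_rank=cfg.local_rank,
                                        center_weight=cfg.center_weight)
        local.classes_ = model.classifier.classes_
        local.bases_ = model.classifier.bases_
        local.ranks_ = model.classifier.ranks_
        local.n_features_in_ = model.qd
        for c, lab in zip(centers, local.predict(X)):
            labels[c] = str(lab)
    return LabelSequence(labels, provenance="model2")


# -- model persistence -------------------------------------------------------

def _encode(a: np.ndarray) -> dict:
    return {"shape": list(a.shape),
            "data": base64.b64encode(np.ascontiguousarray(a, dtype="<f8").tobytes()).decode()}


def _decode(d: dict) -> np.ndarray:
    a = np.frombuffer(base64.b64decode(d["data"]), dtype="<f8")
    return a.reshape(d["shape"]).copy()


def save_model(model: SSESubspaceModel, path) -> None:
    """Write the model as versioned JSON."""
    clf = model.classifier
    doc = {
        "format_version": model.version,
        "config": asdict(model.config),
        "means": _encode(model.means),
        "scales": _encode(model.scales),
        "classes": [str(c) for c in clf.classes_],
        "ranks": {str(k): int(v) for k, v in clf.ranks_.items()},
        "bases": {str(k): _encode(v) for k, v in clf.bases_.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> SSESubspaceModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {doc.get('format_version')}")
    cfg = WindowConfig(**doc["config"])
    clf = SubspaceProjectionClassifier(cfg.rank_strategy, cfg.tau)
    clf.classes_ = np.array(doc["classes"])
    clf.bases_ = {k: _decode(v) for k, v in doc["bases"].items()}
    clf.ranks_ = {k: int(v) for k, v in doc["ranks"].items()}
    clf.n_features_in_ = cfg.q * N_FEATURES
    for k, B in clf.bases_.items():
        if B.shape[0] != clf.n_features_in_:
            raise ValueError("basis dimension does not match window config")
    return SSESubspaceModel(clf, _decode(doc["means"]), _decode(doc["scales"]), cfg)
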