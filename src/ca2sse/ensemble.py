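"""Stacked machine-learning ensemble over the 39 geometric features.

The pipeline quantile-standardizes every feature to an approximately
Gaussian shape (several raw features are heavily skewed), optionally
keeps the k features with the largest one-way ANOVA F statistic, and
stacks four base classifiers -- random forest, k-nearest-neighbor, a
one-hidden-layer perceptron and gradient-boosted trees -- under a
logistic-regression meta-learner fed with their class probabilities.
A plain logistic regression is also available as a fifth base model but
is dropped by default, the four tree/neighbor/network models being the
stronger ones.

Defaults mirror a corpus-scale configuration (1500-tree forest,
300-round boosting, 200 quantile bins); :meth:`EMLConfig.scaled` is a
lighter preset for small synthetic corpora.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier, StackingClassifier
from sklearn.feature_selection import SelectKBest, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import LabelEncoder, QuantileTransformer
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .features import N_FEATURES, FeatureMatrix
from .trace import LabelSequence

logger = logging.getLogger(__name__)

__all__ = [
    "EMLConfig",
    "EMLClassifier",
    "fit_quantile_standardizer",
    "select_k_best_anova",
    "balance_classes",
    "residue_dataset",
    "train_eml",
]


@dataclass(frozen=True)
class EMLConfig:
    """Hyper-parameters of the stacked ensemble."""

    n_quantile_bins: int = 200
    k_features: int = 39
    rf_trees: int = 1500
    rf_max_features: int = 5
    knn_neighbors: int = 5
    mlp_hidden: int = 50
    xgb_eta: float = 0.2
    xgb_max_depth: int = 6
    xgb_trees: int = 300
    cv_folds: int = 10
    keep_lr: bool = False

    def __post_init__(self):
        if not 1 <= self.k_features <= N_FEATURES:
            raise ValueError(f"k_features must be in [1, {N_FEATURES}]")

    @classmethod
    def scaled(cls) -> "EMLConfig":
        """Reduced preset sized for a few thousand training residues."""
        return cls(rf_trees=200, xgb_trees=100, cv_folds=5)


def fit_quantile_standardizer(X: np.ndarray, n_bins: int = 200,
                              seed: int = 0) -> QuantileTransformer:
    """Quantile transform mapping each feature to a standard normal.

    Constant features pass through unchanged (with a warning), matching
    the transformer's rank-based behavior.
    """
    X = np.asarray(X, dtype=float)
    for jc in np.where(X.std(axis=0) < 1e-12)[0]:
        logger.warning("feature %d is constant; quantile transform passes it "
                       "through unchanged", jc)
    qt = QuantileTransformer(n_quantiles=min(n_bins, len(X)),
                             output_distribution="normal", random_state=seed)
    return qt.fit(X)


def select_k_best_anova(X: np.ndarray, y, k: int) -> np.ndarray:
    """Indices of the k features with the largest ANOVA F statistic."""
    X = np.asarray(X, dtype=float)
    if not 1 <= k <= X.shape[1]:
        raise ValueError(f"k must be in [1, {X.shape[1]}]")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features yield F = nan
        sel = SelectKBest(f_classif, k=k).fit(X, y)
    return np.sort(np.where(sel.get_support())[0])


def balance_classes(X: np.ndarray, y, seed: int = 0):
    """Downsample every class to the minority class size."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    m = counts.min()
    keep = np.concatenate([
        rng.choice(np.where(y == c)[0], size=m, replace=False) for c in classes
    ])
    keep.sort()
    return X[keep], y[keep]


class EMLClassifier(ClassifierMixin, BaseEstimator):
    """Quantile transform -> ANOVA top-k -> stacked 4-model ensemble."""

    def __init__(self, n_quantile_bins: int = 200, k_features: int = 39,
                 rf_trees: int = 1500, rf_max_features: int = 5,
                 knn_neighbors: int = 5, mlp_hidden: int = 50,
                 xgb_eta: float = 0.2, xgb_max_depth: int = 6,
                 xgb_trees: int = 300, cv_folds: int = 10,
                 keep_lr: bool = False, random_state: int = 0):
        self.n_quantile_bins = n_quantile_bins
        self.k_features = k_features
        self.rf_trees = rf_trees
        self.rf_max_features = rf_max_features
        self.knn_neighbors = knn_neighbors
        self.mlp_hidden = mlp_hidden
        self.xgb_eta = xgb_eta
        self.xgb_max_depth = xgb_max_depth
        self.xgb_trees = xgb_trees
        self.cv_folds = cv_folds
        self.keep_lr = keep_lr
        self.random_state = random_state

    @classmethod
    def from_config(cls, cfg: EMLConfig, random_state: int = 0) -> "EMLClassifier":
        return cls(cfg.n_quantile_bins, cfg.k_features, cfg.rf_trees,
                   cfg.rf_max_features, cfg.knn_neighbors, cfg.mlp_hidden,
                   cfg.xgb_eta, cfg.xgb_max_depth, cfg.xgb_trees,
                   cfg.cv_folds, cfg.keep_lr, random_state)

    def _base_models(self):
        rs = self.random_state
        models = [
            ("rf", RandomForestClassifier(
                n_estimators=self.rf_trees,
                max_features=min(self.rf_max_features, self.k_features),
                random_state=rs, n_jobs=1)),
            ("knn", KNeighborsClassifier(n_neighbors=self.knn_neighbors)),
            ("mlp", MLPClassifier(hidden_layer_sizes=(self.mlp_hidden,),
                                  max_iter=500, random_state=rs)),
            ("xgb", XGBClassifier(learning_rate=self.xgb_eta,
                                  max_depth=self.xgb_max_depth,
                                  n_estimators=self.xgb_trees,
                                  random_state=rs, n_jobs=1,
                                  eval_metric="mlogloss")),
        ]
        if self.keep_lr:
            models.append(("lr", LogisticRegression(max_iter=1000,
                                                    random_state=rs)))
        return models

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least two classes to train")
        self._le = LabelEncoder().fit(y)
        yi = self._le.transform(y)
        self.classes_ = self._le.classes_
        stack = StackingClassifier(
            estimators=self._base_models(),
            final_estimator=LogisticRegression(max_iter=1000,
                                               random_state=self.random_state),
            stack_method="predict_proba",
            cv=self.cv_folds, n_jobs=1)
        self.pipeline_ = Pipeline([
            ("quantile", QuantileTransformer(
                n_quantiles=min(self.n_quantile_bins, len(X)),
                output_distribution="normal",
                random_state=self.random_state)),
            ("select", SelectKBest(f_classif, k=self.k_features)),
            ("stack", stack),
        ])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.pipeline_.fit(X, yi)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self._le.inverse_transform(
            self.pipeline_.predict(np.asarray(X, dtype=float)))

    def predict_proba(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict_proba(np.asarray(X, dtype=float))


def residue_dataset(fms: list[FeatureMatrix], truths: list[LabelSequence]):
    """Per-residue (X, y) from feature matrices; invalid residues dropped.

    Only residues whose full 39-vector is valid enter the dataset, so
    the ensemble sees exactly the descriptor the subspace models see.
    """
    Xs, ys = [], []
    for fm, truth in zip(fms, truths):
        if fm.n_residues != len(truth):
            raise ValueError("features and labels are not aligned")
        ok = fm.column_valid()
        Xs.append(fm.values[:, ok].T)
        ys.extend(lab for lab, good in zip(truth, ok) if good)
    X = np.vstack([x for x in Xs if len(x)]) if Xs else np.empty((0, N_FEATURES))
    return X, np.array(ys)


def train_eml(X, y, cfg: EMLConfig = EMLConfig(), seed: int = 0,
              balance: bool = True, max_samples: int | None = None) -> EMLClassifier:
    """Balance classes, optionally subsample, and fit the stack."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if balance:
        X, y = balance_classes(X, y, seed)
    if max_samples is not None and len(y) > max_samples:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(y), size=max_samples, replace=False))
        X, y = X[keep], y[keep]
    return EMLClassifier.from_config(cfg, random_state=seed).fit(X, y)
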