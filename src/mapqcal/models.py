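"""Misalignment classifiers under seven class-imbalance schemes.

Misaligned reads are a tiny minority (roughly 0.1-2% of alignments), so
plain training collapses to the majority class.  The schemes:

========  =====================  ==========================================
scheme    base algorithm         sampling strategy
========  =====================  ==========================================
RUSVM     SVM (RBF kernel)       all balanced random under-sampled subsets;
                                 keep the best model
RULR      logistic regression    as RUSVM
RUSVMS    SVM (RBF kernel)       as RUSVM, then per subset retrain on all
                                 false positives + equal true positives
RULRS     logistic regression    as RUSVMS
DTBAG     decision tree          one tree per balanced subset, probabilities
                                 averaged (balanced bagging)
ADABST    decision stump         classic AdaBoost on the full imbalanced set
RUBST     decision stump         AdaBoost with a fresh balanced under-sample
                                 each round (RUSBoost)
========  =====================  ==========================================

Every grid-search uses stratified five-fold cross-validation with the
F1 score of the misaligned class as the selection metric.  The
statsmodels-style facade — :class:`MisalignmentModel` /
:class:`MisalignmentResults` — wraps splitting, scaling, scheme
training, isotonic calibration and test-set evaluation into a single
``fit()``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold, train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import calibration as C
from .features import ScalingParams, apply_scaler, fit_scaler

__all__ = [
    "SCHEMES",
    "ModelConfig",
    "TrainedModel",
    "split_train_test",
    "rus_subsets",
    "grid_search_cv",
    "train_rus_best",
    "train_rus_tpfp",
    "train_balanced_bagging",
    "train_adaboost",
    "train_rusboost",
    "train_scheme",
    "predict_scores",
    "classify",
    "MisalignmentModel",
    "MisalignmentResults",
]

SCHEMES = ("RUSVM", "RULR", "RUSVMS", "RULRS", "DTBAG", "ADABST", "RUBST")

_BASE_ALGORITHM = {
    "RUSVM": "svm-rbf", "RUSVMS": "svm-rbf",
    "RULR": "logistic", "RULRS": "logistic",
    "DTBAG": "decision-tree",
    "ADABST": "decision-stump", "RUBST": "decision-stump",
}

# grids mirroring the reported optima: SVM peaks at C=10 with
# gamma = 1 / (n_features * Var(X)); AdaBoost at 2000 stumps, lr 1.0
DEFAULT_GRIDS = {
    "svm-rbf": {"C": [1, 10, 100]},
    "logistic": {"C": [0.01, 0.1, 1, 10]},
    "decision-tree": {"max_depth": [1, 3, 5, None]},
    "decision-stump": {"n_estimators": [500, 1000, 2000],
                       "learning_rate": [0.5, 1.0]},
}


@dataclass
class ModelConfig:
    scheme_id: str
    grid: Optional[Dict[str, list]] = None
    cv_folds: int = 5
    seed: int = 0
    max_subsets: Optional[int] = None

    def __post_init__(self) -> None:
        if self.scheme_id not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme_id!r}")
        self.base_algorithm = _BASE_ALGORITHM[self.scheme_id]
        if self.grid is None:
            self.grid = {k: list(v) for k, v in
                         DEFAULT_GRIDS[self.base_algorithm].items()}


def _make_estimator(base_algorithm: str, params: Dict, seed: int):
    if base_algorithm == "svm-rbf":
        return SVC(kernel="rbf", gamma="scale", random_state=seed, **params)
    if base_algorithm == "logistic":
        return LogisticRegression(max_iter=1000, **params)
    if base_algorithm == "decision-tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if base_algorithm == "decision-stump":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            random_state=seed, **params)
    raise ValueError(f"unknown base algorithm {base_algorithm!r}")


# ----------------------------------------------------------------------
# splitting and under-sampling

def split_train_test(X: pd.DataFrame, y: np.ndarray, train_fraction: float,
                     seed: int) -> Tuple[pd.DataFrame, np.ndarray, pd.DataFrame, np.ndarray]:
    """Disjoint, exhaustive, label-stratified split."""
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    y = np.asarray(y)
    try:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=train_fraction, stratify=y, random_state=seed)
    except ValueError as exc:
        raise ValueError(f"stratified split failed: {exc}") from exc
    return X_tr, y_tr, X_te, y_te


def rus_subsets(y: np.ndarray, seed: int,
                max_subsets: Optional[int] = None) -> List[np.ndarray]:
    """Balanced random under-sampled subsets (row indices).

    Each subset = all minority rows + an equal-count majority sample
    drawn without replacement.  The subset count defaults to
    ``ceil(N_majority / N_minority)`` so majority rows are covered in
    expectation; cap it with ``max_subsets``.
    """
    y = np.asarray(y)
    minority = np.flatnonzero(y == 1)
    majority = np.flatnonzero(y == 0)
    if minority.size == 0:
        raise ValueError("minority class is empty")
    if minority.size > majority.size:
        raise ValueError("minority class larger than majority")
    count = math.ceil(majority.size / minority.size)
    if max_subsets is not None:
        count = min(count, max_subsets)
    rng = np.random.Generator(np.random.PCG64(seed))
    subsets = []
    for _ in range(count):
        maj = rng.choice(majority, size=minority.size, replace=False)
        idx = np.concatenate([minority, maj])
        idx.sort()
        subsets.append(idx)
    return subsets


# ----------------------------------------------------------------------
# grid search

def grid_search_cv(base_algorithm: str, grid: Dict[str, list], folds: int,
                   X: np.ndarray, y: np.ndarray, seed: int
                   ) -> Tuple[Dict, List[Tuple[Dict, float]]]:
    """Stratified k-fold grid search maximising the F1 score of class 1.

    Ties break deterministically by grid order; folds whose validation
    part lacks positives are skipped with a warning.  Degenerate data
    (too few per-class rows for 2 folds) falls back to the first grid
    point.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not grid:
        raise ValueError("grid must be nonempty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    points = list(ParameterGrid(grid))
    if not points:
        raise ValueError("grid must be nonempty")
    min_class = int(np.bincount(y.astype(int)).min())
    usable_folds = min(folds, min_class)
    if len(points) == 1 or usable_folds < 2:
        return points[0], [(points[0], float("nan"))]
    skf = StratifiedKFold(n_splits=usable_folds, shuffle=True, random_state=seed)
    table: List[Tuple[Dict, float]] = []
    best, best_score = None, -np.inf
    for params in points:
        scores = []
        for tr, va in skf.split(X, y):
            if y[va].sum() == 0:
                warnings.warn("validation fold without positives; skipped")
                continue
            est = _make_estimator(base_algorithm, params, seed)
            est.fit(X[tr], y[tr])
            scores.append(f1_score(y[va], est.predict(X[va]), zero_division=0))
        mean = float(np.mean(scores)) if scores else 0.0
        table.append((params, mean))
        if mean > best_score:  # strict: earlier grid point wins ties
            best, best_score = params, mean
    return best, table


def _grid_fit(base_algorithm: str, grid: Dict[str, list], folds: int,
              X: np.ndarray, y: np.ndarray, seed: int):
    """Grid-search-CV then refit the best point on all given rows."""
    best, table = grid_search_cv(base_algorithm, grid, folds, X, y, seed)
    est = _make_estimator(base_algorithm, best, seed)
    est.fit(np.asarray(X, dtype=float), np.asarray(y))
    return est, best, table


# ----------------------------------------------------------------------
# trained-model container

def _raw_scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(np.asarray(X, dtype=float))[:, 1]
    return clf.decision_function(np.asarray(X, dtype=float))


@dataclass
class TrainedModel:
    """A fitted misalignment classifier with its scaler, scheme
    metadata and (optionally) an isotonic calibrator."""

    clf: object
    scheme_id: str
    scaler: Optional[ScalingParams] = None
    calibrator: Optional[C.IsotonicModel] = None
    produces_probabilities: bool = True
    metadata: Dict = field(default_factory=dict)

    def _scale(self, X) -> np.ndarray:
        if self.scaler is not None and isinstance(X, pd.DataFrame):
            X = apply_scaler(self.scaler, X)
        return np.asarray(X, dtype=float)

    def raw_scores(self, X) -> np.ndarray:
        """Probability of class 1 if available, else SVM decision
        distances.  DataFrames are scaled with the model's scaler."""
        return _raw_scores(self.clf, self._scale(X))

    def fit_calibrator(self, X, y) -> None:
        """Isotonic calibration of raw scores against outcomes (the
        paper trains this on the model's own training predictions)."""
        scores = self.raw_scores(X)
        self.calibrator = C.pava_fit(scores, np.asarray(y, dtype=float))

    def predict_calibrated(self, X) -> np.ndarray:
        """Calibrated misalignment probabilities."""
        scores = self.raw_scores(X)
        if self.calibrator is not None:
            return C.pava_apply(self.calibrator, scores)
        if not self.produces_probabilities:
            raise ValueError("SVM scores need an isotonic calibrator")
        return scores

    def predict_labels(self, X, threshold: float = 0.5) -> np.ndarray:
        return classify(self.predict_calibrated(X), threshold)


def predict_scores(model: TrainedModel, matrix) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """(raw scores, probabilities or None) for a pre-scaled matrix."""
    X = np.asarray(matrix, dtype=float)
    if X.size and (X.min() < -1e-6 or X.max() > 1 + 1e-6):
        warnings.warn("matrix appears unscaled (values outside [0, 1])")
    raw = _raw_scores(model.clf, X)
    prob = raw if model.produces_probabilities else None
    return raw, prob


def classify(probabilities, threshold: float = 0.5) -> np.ndarray:
    """Label 1 iff p > threshold (strict)."""
    return (np.asarray(probabilities, dtype=float) > threshold).astype(int)


# ----------------------------------------------------------------------
# scheme trainers

def _eval_f1(clf, X_eval: np.ndarray, y_eval: np.ndarray) -> float:
    return f1_score(y_eval, clf.predict(np.asarray(X_eval, dtype=float)),
                    zero_division=0)


def train_rus_best(config: ModelConfig, X_tr, y_tr, X_eval, y_eval
                   ) -> TrainedModel:
    """RUSVM / RULR: grid-search fit on every balanced subset, retain
    the model with the best F1 on the evaluation set."""
    if config.scheme_id not in ("RUSVM", "RULR"):
        raise ValueError("scheme must be RUSVM or RULR")
    X_tr = np.asarray(X_tr, dtype=float)
    y_tr = np.asarray(y_tr)
    subsets = rus_subsets(y_tr, config.seed, config.max_subsets)
    best_clf, best_f1, best_meta = None, -np.inf, {}
    for i, idx in enumerate(subsets):
        clf, params, _ = _grid_fit(config.base_algorithm, config.grid,
                                   config.cv_folds, X_tr[idx], y_tr[idx],
                                   config.seed)
        score = _eval_f1(clf, X_eval, y_eval)
        if score > best_f1:
            best_clf, best_f1 = clf, score
            best_meta = {"subset_index": i, "grid_point": params,
                         "eval_f1": score}
    return TrainedModel(
        clf=best_clf, scheme_id=config.scheme_id,
        produces_probabilities=config.base_algorithm != "svm-rbf",
        metadata={"subset_count": len(subsets), "seed": config.seed,
                  **best_meta})


def train_rus_tpfp(config: ModelConfig, X_tr, y_tr, X_eval, y_eval
                   ) -> TrainedModel:
    """RUSVMS / RULRS: per balanced subset, fit, predict on the whole
    training split, then retrain on all false positives + an
    equal-count sample of true positives; retain the best refit."""
    if config.scheme_id not in ("RUSVMS", "RULRS"):
        raise ValueError("scheme must be RUSVMS or RULRS")
    X_tr = np.asarray(X_tr, dtype=float)
    y_tr = np.asarray(y_tr)
    rng = np.random.Generator(np.random.PCG64(config.seed))
    subsets = rus_subsets(y_tr, config.seed, config.max_subsets)
    best_clf, best_f1, best_meta = None, -np.inf, {}
    n_skipped = 0
    for i, idx in enumerate(subsets):
        stage1, params1, _ = _grid_fit(config.base_algorithm, config.grid,
                                       config.cv_folds, X_tr[idx], y_tr[idx],
                                       config.seed)
        pred = stage1.predict(X_tr)
        fp = np.flatnonzero((pred == 1) & (y_tr == 0))
        tp = np.flatnonzero((pred == 1) & (y_tr == 1))
        if fp.size == 0 or tp.size == 0:
            n_skipped += 1
            clf, params = stage1, params1  # keep the first-stage model
        else:
            if tp.size >= fp.size:
                tp_sample = rng.choice(tp, size=fp.size, replace=False)
            else:
                # scarce TPs: keep the refit set balanced by sampling
                # with replacement (all FPs must be retained)
                tp_sample = rng.choice(tp, size=fp.size, replace=True)
            refit_idx = np.concatenate([fp, tp_sample])
            clf, params, _ = _grid_fit(config.base_algorithm, config.grid,
                                       config.cv_folds, X_tr[refit_idx],
                                       y_tr[refit_idx], config.seed)
        score = _eval_f1(clf, X_eval, y_eval)
        if score > best_f1:
            best_clf, best_f1 = clf, score
            best_meta = {"subset_index": i, "grid_point": params,
                         "eval_f1": score}
    return TrainedModel(
        clf=best_clf, scheme_id=config.scheme_id,
        produces_probabilities=config.base_algorithm != "svm-rbf",
        metadata={"subset_count": len(subsets), "refits_skipped": n_skipped,
                  "seed": config.seed, **best_meta})


class BalancedBaggingEnsemble:
    """Mean of per-subset decision-tree probabilities."""

    def __init__(self, trees: List[DecisionTreeClassifier]):
        if not trees:
            raise ValueError("empty ensemble")
        self.trees = trees

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p1 = np.mean([self._member_p1(t, X) for t in self.trees], axis=0)
        return np.column_stack([1 - p1, p1])

    @staticmethod
    def _member_p1(tree, X) -> np.ndarray:
        proba = tree.predict_proba(X)
        if proba.shape[1] == 1:  # degenerate single-class tree
            return np.full(len(X), float(tree.classes_[0]))
        return proba[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


def train_balanced_bagging(config: ModelConfig, X_tr, y_tr) -> TrainedModel:
    """DTBAG: one decision tree per balanced subset; ensemble
    probability is the mean of member class-1 probabilities."""
    if config.scheme_id != "DTBAG":
        raise ValueError("scheme must be DTBAG")
    X_tr = np.asarray(X_tr, dtype=float)
    y_tr = np.asarray(y_tr)
    subsets = rus_subsets(y_tr, config.seed, config.max_subsets)
    # choose tree parameters once, by CV on the first balanced subset
    params, _ = grid_search_cv("decision-tree", config.grid, config.cv_folds,
                               X_tr[subsets[0]], y_tr[subsets[0]], config.seed)
    trees = []
    for idx in subsets:
        t = DecisionTreeClassifier(random_state=config.seed, **params)
        t.fit(X_tr[idx], y_tr[idx])
        trees.append(t)
    return TrainedModel(
        clf=BalancedBaggingEnsemble(trees), scheme_id="DTBAG",
        produces_probabilities=True,
        metadata={"subset_count": len(subsets), "grid_point": params,
                  "seed": config.seed})


def train_adaboost(config: ModelConfig, X_tr, y_tr) -> TrainedModel:
    """ADABST: classic AdaBoost over decision stumps on the full
    (imbalanced) training matrix."""
    if config.scheme_id != "ADABST":
        raise ValueError("scheme must be ADABST")
    clf, params, _ = _grid_fit("decision-stump", config.grid, config.cv_folds,
                               X_tr, y_tr, config.seed)
    return TrainedModel(
        clf=clf, scheme_id="ADABST", produces_probabilities=True,
        metadata={"grid_point": params, "seed": config.seed})


class RUSBoostClassifier:
    """AdaBoost (SAMME) whose stump each round is fitted on a freshly
    under-sampled class-balanced set, while the boosting weights live
    on the full training set."""

    def __init__(self, n_estimators: int = 200, learning_rate: float = 1.0,
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.estimators_: List[DecisionTreeClassifier] = []
        self.alphas_: List[float] = []

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        n = len(y)
        minority = np.flatnonzero(y == 1)
        majority = np.flatnonzero(y == 0)
        if minority.size == 0 or majority.size == 0:
            raise ValueError("both classes required")
        rng = np.random.Generator(np.random.PCG64(self.random_state))
        w = np.full(n, 1.0 / n)
        self.estimators_, self.alphas_ = [], []
        k = min(minority.size, majority.size)
        for _ in range(self.n_estimators):
            stump = pred = None
            err = 1.0
            for _retry in range(10):  # resample if the round is unusable
                maj = rng.choice(majority, size=k, replace=False)
                mino = minority if minority.size <= majority.size else \
                    rng.choice(minority, size=k, replace=False)
                idx = np.concatenate([mino, maj])
                stump = DecisionTreeClassifier(max_depth=1)
                stump.fit(X[idx], y[idx], sample_weight=w[idx] / w[idx].sum())
                pred = stump.predict(X)
                err = float(w[pred != y].sum() / w.sum())
                if err < 0.5:
                    break
            if err >= 0.5:
                if not self.estimators_:
                    # keep one stump so the model is usable, then stop
                    self.estimators_.append(stump)
                    self.alphas_.append(1e-3)
                warnings.warn("weighted error >= 0.5; boosting stopped early")
                break
            err = max(err, 1e-12)
            alpha = self.learning_rate * 0.5 * np.log((1 - err) / err)
            self.estimators_.append(stump)
            self.alphas_.append(alpha)
            w = w * np.exp(alpha * (pred != y))
            w /= w.sum()
            if err < 1e-10:
                break
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        a = np.asarray(self.alphas_)
        votes = np.zeros(len(X))
        for alpha, est in zip(a, self.estimators_):
            votes += alpha * (2 * est.predict(X) - 1)
        return votes / a.sum()

    def predict_proba(self, X) -> np.ndarray:
        p1 = (self.decision_function(X) + 1) / 2
        p1 = np.clip(p1, 0, 1)
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def train_rusboost(config: ModelConfig, X_tr, y_tr) -> TrainedModel:
    """RUBST: random under-sampling inside every boosting round."""
    if config.scheme_id != "RUBST":
        raise ValueError("scheme must be RUBST")
    X_tr = np.asarray(X_tr, dtype=float)
    y_tr = np.asarray(y_tr)
    points = list(ParameterGrid(config.grid))
    best_params, best_cv = points[0], -np.inf
    if len(points) > 1:
        min_class = int(np.bincount(y_tr.astype(int)).min())
        folds = min(config.cv_folds, min_class)
        if folds >= 2:
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=config.seed)
            for params in points:
                scores = []
                for tr, va in skf.split(X_tr, y_tr):
                    m = RUSBoostClassifier(random_state=config.seed, **params)
                    m.fit(X_tr[tr], y_tr[tr])
                    scores.append(f1_score(y_tr[va], m.predict(X_tr[va]),
                                           zero_division=0))
                mean = float(np.mean(scores))
                if mean > best_cv:
                    best_params, best_cv = params, mean
    clf = RUSBoostClassifier(random_state=config.seed, **best_params)
    clf.fit(X_tr, y_tr)
    return TrainedModel(
        clf=clf, scheme_id="RUBST", produces_probabilities=True,
        metadata={"grid_point": best_params, "rounds": len(clf.estimators_),
                  "seed": config.seed})


def train_scheme(config: ModelConfig, X_tr, y_tr, X_eval=None, y_eval=None
                 ) -> TrainedModel:
    """Dispatch to the scheme's trainer."""
    if config.scheme_id in ("RUSVM", "RULR"):
        return train_rus_best(config, X_tr, y_tr, X_eval, y_eval)
    if config.scheme_id in ("RUSVMS", "RULRS"):
        return train_rus_tpfp(config, X_tr, y_tr, X_eval, y_eval)
    if config.scheme_id == "DTBAG":
        return train_balanced_bagging(config, X_tr, y_tr)
    if config.scheme_id == "ADABST":
        return train_adaboost(config, X_tr, y_tr)
    return train_rusboost(config, X_tr, y_tr)


# ----------------------------------------------------------------------
# statsmodels-style facade

class MisalignmentModel:
    """Misalignment-classification model built from a feature matrix.

    Parameters
    ----------
    X : DataFrame of raw (unscaled) feature values
    y : 0/1 labels (1 = misaligned)
    scheme : one of :data:`SCHEMES`
    train_fraction : fraction used for training (the remainder is the
        test set; the published protocol used 0.2)
    eval_fraction : fraction of the training split carved out for
        best-subset-model selection; with ``paper_faithful=True`` the
        test set is used instead (the published, leaky protocol)
    """

    def __init__(self, X: pd.DataFrame, y, scheme: str = "ADABST",
                 grid: Optional[Dict[str, list]] = None,
                 train_fraction: float = 0.2, eval_fraction: float = 0.5,
                 cv_folds: int = 5, seed: int = 0,
                 max_subsets: Optional[int] = None,
                 paper_faithful: bool = False):
        self.X = X.reset_index(drop=True)
        self.y = np.asarray(y)
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError("labels must be 0/1")
        self.config = ModelConfig(scheme_id=scheme, grid=grid,
                                  cv_folds=cv_folds, seed=seed,
                                  max_subsets=max_subsets)
        self.train_fraction = train_fraction
        self.eval_fraction = eval_fraction
        self.paper_faithful = paper_faithful

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "LABEL",
                       **kwargs) -> "MisalignmentModel":
        from .features import FEATURE_NAMES
        known = df[df[label_col] >= 0]
        return cls(known[FEATURE_NAMES], known[label_col].to_numpy(), **kwargs)

    def fit(self, threshold: float = 0.5) -> "MisalignmentResults":
        cfg = self.config
        X_tr, y_tr, X_te, y_te = split_train_test(
            self.X, self.y, self.train_fraction, cfg.seed)
        scaler = fit_scaler(X_tr)
        Xs_tr = apply_scaler(scaler, X_tr).to_numpy()
        Xs_te = apply_scaler(scaler, X_te).to_numpy()
        if cfg.scheme_id in ("RUSVM", "RULR", "RUSVMS", "RULRS"):
            if self.paper_faithful:
                X_core, y_core = Xs_tr, y_tr
                X_eval, y_eval = Xs_te, y_te
            else:
                X_core, X_eval, y_core, y_eval = train_test_split(
                    Xs_tr, y_tr, test_size=self.eval_fraction,
                    stratify=y_tr, random_state=cfg.seed)
            model = train_scheme(cfg, X_core, y_core, X_eval, y_eval)
            X_calib, y_calib = X_core, y_core
        else:
            model = train_scheme(cfg, Xs_tr, y_tr)
            X_calib, y_calib = Xs_tr, y_tr
        model.scaler = scaler
        # isotonic calibrator trained on the model's training predictions
        model.fit_calibrator(X_calib, y_calib)
        return MisalignmentResults(self, model, Xs_te, y_te,
                                   threshold=threshold)


class MisalignmentResults:
    """Fit results: the trained model, its calibrator and test-set
    performance before and after isotonic calibration."""

    def __init__(self, model_spec: MisalignmentModel, model: TrainedModel,
                 Xs_test: np.ndarray, y_test: np.ndarray,
                 threshold: float = 0.5):
        self.model_spec = model_spec
        self.model = model
        self.Xs_test = Xs_test
        self.y_test = np.asarray(y_test)
        self.threshold = threshold
        raw, prob = predict_scores(model, Xs_test)
        self.raw_scores = raw
        self.prob_iso = C.pava_apply(model.calibrator, raw)
        pred_iso = classify(self.prob_iso, threshold)
        if prob is not None:
            pred = classify(prob, threshold)
            self.metrics = C.metrics_report(self.y_test, pred,
                                            probabilities=prob)
        else:
            # SVM: no raw probabilities; threshold the decision distance at 0
            pred = (raw > 0).astype(int)
            self.metrics = C.metrics_report(self.y_test, pred, scores=raw)
        self.metrics_iso = C.metrics_report(self.y_test, pred_iso,
                                            probabilities=self.prob_iso)

    @property
    def f1(self) -> float:
        return self.metrics_iso.f1

    @property
    def brier(self) -> Optional[float]:
        return self.metrics_iso.brier

    @property
    def average_precision(self) -> Optional[float]:
        return self.metrics_iso.average_precision

    def predict_proba(self, X) -> np.ndarray:
        """Calibrated misalignment probabilities for raw features."""
        return self.model.predict_calibrated(X)

    def recalibrate(self, records, reference, cap: int = C.DEFAULT_MAPQ_CAP):
        """Per-read MAPQ recalibration; see
        :func:`mapqcal.calibration.recalibrate`."""
        return C.recalibrate(self.model, records, reference, cap=cap)

    def summary(self) -> str:
        md = self.model.metadata
        lines = [
            "Misalignment classification results",
            "===================================",
            f"scheme:            {self.model.scheme_id}",
            f"grid point:        {md.get('grid_point')}",
            f"subset count:      {md.get('subset_count', '-')}",
            f"test size:         {len(self.y_test)}"
            f" ({int(self.y_test.sum())} misaligned)",
            f"threshold:         p > {self.threshold}",
            "",
            "               raw        isotonic",
            f"F1           {self.metrics.f1:8.4f}   {self.metrics_iso.f1:8.4f}",
            f"precision    {self.metrics.precision:8.4f}   "
            f"{self.metrics_iso.precision:8.4f}",
            f"recall       {self.metrics.recall:8.4f}   "
            f"{self.metrics_iso.recall:8.4f}",
        ]
        ap_raw = ("   NA   " if self.metrics.average_precision is None
                  else f"{self.metrics.average_precision:8.4f}")
        bs_raw = ("   NA   " if self.metrics.brier is None
                  else f"{self.metrics.brier:8.4f}")
        lines.append(f"avg precision{ap_raw}   "
                     f"{self.metrics_iso.average_precision:8.4f}")
        lines.append(f"Brier score  {bs_raw}   {self.metrics_iso.brier:8.4f}")
        return "\n".join(lines)
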