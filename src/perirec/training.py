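"""Class balancing and the four voxel classifiers.

The recurrence class is a small minority of peritumoral voxels, so the
majority (nonrecurrence) class is randomly undersampled to the minority size
before fitting.  Four gradient-ensemble backends are supported:
``gradient_boosting`` (sklearn histogram gradient boosting), ``xgboost``,
``random_forest`` and ``lightgbm``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

ALGORITHMS = ("gradient_boosting", "xgboost", "random_forest", "lightgbm")


def undersample(labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Indices balancing the classes: all minority rows plus a seed-deterministic
    uniform subset of majority rows of the same size (sorted, so the result is
    order-canonical).  An already balanced input returns every row."""
    labels = np.asarray(labels)
    idx0 = np.nonzero(labels == 0)[0]
    idx1 = np.nonzero(labels == 1)[0]
    if len(idx0) == 0 or len(idx1) == 0:
        raise ValueError("both classes must be nonempty for undersampling")
    minority, majority = (idx1, idx0) if len(idx1) <= len(idx0) else (idx0, idx1)
    if len(minority) == len(majority):
        return np.arange(len(labels))
    rng = np.random.default_rng(seed)
    kept = rng.choice(majority, size=len(minority), replace=False)
    return np.sort(np.concatenate([minority, kept]))


def _make_backend(algorithm: str, seed: int, n_estimators: int, max_depth):
    if algorithm == "gradient_boosting":
        return HistGradientBoostingClassifier(max_iter=n_estimators,
                                              max_depth=max_depth,
                                              random_state=seed)
    if algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=n_estimators,
                                      max_depth=max_depth, n_jobs=1,
                                      random_state=seed)
    if algorithm == "xgboost":
        from xgboost import XGBClassifier
        return XGBClassifier(n_estimators=n_estimators,
                             max_depth=max_depth or 6, n_jobs=1,
                             random_state=seed, verbosity=0,
                             eval_metric="logloss", tree_method="hist")
    if algorithm == "lightgbm":
        from lightgbm import LGBMClassifier
        return LGBMClassifier(n_estimators=n_estimators,
                              max_depth=max_depth or -1, n_jobs=1,
                              random_state=seed, verbose=-1,
                              deterministic=True, force_row_wise=True)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


class RecurrenceVoxelClassifier(BaseEstimator, ClassifierMixin):
    """Voxelwise recurrence classifier with built-in majority undersampling.

    Parameters
    ----------
    algorithm : str
        One of :data:`ALGORITHMS`.
    n_estimators : int
        Iteration/tree cap of the backend (reproducibility over tuning).
    balance : bool
        Undersample the majority class before fitting.
    random_state : int
        Seeds both the undersampling and the backend.

    Attributes (after fit)
    ----------------------
    model_ : fitted backend estimator
    classes_ : ndarray of the two class labels
    n_before_, n_after_ : per-class row counts before/after balancing
    feature_names_ : column names seen during fit (when X is a DataFrame)
    """

    def __init__(self, algorithm: str = "lightgbm", n_estimators: int = 200,
                 max_depth: int | None = None, balance: bool = True,
                 random_state: int = 0):
        self.algorithm = algorithm
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.balance = balance
        self.random_state = random_state

    def fit(self, X, y):
        self.feature_names_ = list(X.columns) if hasattr(X, "columns") else None
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y).astype(int)
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("need exactly two classes")
        self.n_before_ = {int(c): int((y == c).sum()) for c in self.classes_}
        if self.balance:
            keep = undersample(y, seed=self.random_state)
            X, y = X[keep], y[keep]
        self.n_after_ = {int(c): int((y == c).sum()) for c in self.classes_}
        self.model_ = _make_backend(self.algorithm, self.random_state,
                                    self.n_estimators, self.max_depth)
        self.model_.fit(X, y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        import warnings

        with warnings.catch_warnings():
            # lightgbm assigns synthetic column names to ndarray input at fit
            # time, which trips sklearn's name check on predict
            warnings.filterwarnings("ignore",
                                    message="X does not have valid feature names")
            return self.model_.predict_proba(np.asarray(X, dtype=np.float32))

    def predict(self, X) -> np.ndarray:
        # ties broken toward nonrecurrence: positive only if p > 0.5
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def recurrence_probability(self, X) -> np.ndarray:
        """Positive-class (recurrence) probability per row."""
        return self.predict_proba(X)[:, 1]

    def feature_importance(self) -> pd.DataFrame:
        """Normalized importance ranking with the cumulative-importance curve."""
        check_is_fitted(self, "model_")
        model = self.model_
        if hasattr(model, "feature_importances_"):
            imp = np.asarray(model.feature_importances_, dtype=float)
        else:
            raise ValueError(
                f"backend {self.algorithm!r} exposes no feature importances")
        if imp.sum() > 0:
            imp = imp / imp.sum()
        names = (self.feature_names_ if self.feature_names_ is not None
                 else [f"f{i}" for i in range(len(imp))])
        order = np.argsort(-imp, kind="stable")
        df = pd.DataFrame({"feature": np.asarray(names)[order],
                           "importance": imp[order]})
        df["cumulative_importance"] = df["importance"].cumsum()
        return df

    def manifest(self) -> dict:
        check_is_fitted(self, "model_")
        return {"algorithm": self.algorithm, "n_estimators": self.n_estimators,
                "max_depth": self.max_depth, "random_state": self.random_state,
                "balance": self.balance, "n_before": self.n_before_,
                "n_after": self.n_after_,
                "n_features": None if self.feature_names_ is None
                else len(self.feature_names_),
                "features": self.feature_names_}


@dataclass
class TrainingSet:
    """Feature rows with labels and the balancing bookkeeping."""

    X: pd.DataFrame
    y: np.ndarray
    seed: int = 0

    @property
    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.astype(int).tolist(), counts.astype(int).tolist()))


def train_classifier(train: TrainingSet, algorithm: str = "lightgbm",
                     n_estimators: int = 200, max_depth: int | None = None,
                     seed: int | None = None) -> RecurrenceVoxelClassifier:
    clf = RecurrenceVoxelClassifier(algorithm=algorithm, n_estimators=n_estimators,
                                    max_depth=max_depth,
                                    random_state=train.seed if seed is None else seed)
    return clf.fit(train.X, train.y)


def save_model(clf: RecurrenceVoxelClassifier, out_dir) -> Path:
    """Persist the manifest (JSON) beside the backend's native dump."""
    import pickle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(json.dumps(clf.manifest(), indent=2))
    with open(out_dir / "model.pkl", "wb") as fh:
        pickle.dump(clf, fh)
    return out_dir


def load_model(model_dir) -> RecurrenceVoxelClassifier:
    import pickle

    with open(Path(model_dir) / "model.pkl", "rb") as fh:
        return pickle.load(fh)
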