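"""Region-wise classifier stack: correlation-threshold feature
selection plus L1-penalised logistic regression.

Both stages are scikit-learn-style estimators so they compose with
sklearn pipelines and model selection:

* :class:`CorrelationFilter` — drops one feature of every pair whose
  absolute Pearson correlation exceeds a threshold (default 0.9),
  keeping the one more associated with the benign/malignant label.
* :class:`L1LogisticModel` — standardises features with training-set
  statistics and fits an L1-penalised logistic regression, choosing
  the penalty on a small grid by validation-set AUC.

Thin function wrappers (:func:`correlation_filter`,
:func:`fit_l1_logistic`, :func:`predict`) expose the same operations
in a dataframe-in/dataframe-out style.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .evaluation import auc

__all__ = [
    "CorrelationFilter",
    "L1LogisticModel",
    "correlation_filter",
    "fit_l1_logistic",
    "predict",
]

DEFAULT_PENALTY_GRID = (0.01, 0.1, 1.0, 10.0)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _point_biserial(x: np.ndarray, y: np.ndarray) -> float:
    """|Pearson r| between a feature and the binary label; 0 for a
    constant feature (no discriminative information)."""
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


class CorrelationFilter(TransformerMixin, BaseEstimator):
    """Remove redundant features by pairwise-correlation thresholding.

    Pairs with ``|Pearson r| > threshold`` are resolved greedily in
    descending ``|r|`` order (lexicographic tie-break on names): the
    member with the lower relevance — absolute point-biserial
    correlation with the label — is dropped; relevance ties drop the
    lexicographically later name. The procedure is deterministic and
    idempotent: running it on its own output removes nothing.

    Attributes
    ----------
    selected_features_ : list of surviving feature names, input order.
    support_ : boolean mask over input columns.
    relevance_ : pd.Series of the relevance metric per input feature.
    """

    def __init__(self, threshold: float = 0.9):
        self.threshold = threshold

    def fit(self, X, y):
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")
        X = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if X.shape[1] < 1:
            raise ValueError("need at least one feature")
        names = list(X.columns)
        vals = X.to_numpy(dtype=float)
        relevance = {n: _point_biserial(vals[:, i], y)
                     for i, n in enumerate(names)}

        sd = vals.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(vals, rowvar=False)
        corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)

        offending = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = abs(corr[i, j])
                if r > self.threshold and sd[i] > 0 and sd[j] > 0:
                    offending.append((r, names[i], names[j]))
        offending.sort(key=lambda t: (-t[0], t[1], t[2]))

        alive = set(names)
        for _r, a, b in offending:
            if a in alive and b in alive:
                ra, rb = relevance[a], relevance[b]
                if ra < rb:
                    alive.discard(a)
                elif rb < ra:
                    alive.discard(b)
                else:
                    alive.discard(max(a, b))
        self.feature_names_in_ = np.array(names, dtype=object)
        self.selected_features_ = [n for n in names if n in alive]
        self.support_ = np.array([n in alive for n in names])
        self.relevance_ = pd.Series(relevance)
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_features_")
        X = _as_frame(X)
        missing = [n for n in self.selected_features_ if n not in X.columns]
        if missing:
            raise ValueError(f"missing selected feature(s): {missing}")
        return X[self.selected_features_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "selected_features_")
        return np.asarray(self.selected_features_, dtype=object)


class L1LogisticModel(ClassifierMixin, BaseEstimator):
    """Standardised L1-penalised logistic regression.

    Features are z-scored with training-set mean/sd (sd 0 maps to
    scale 1). The inverse penalty ``C`` is picked from ``penalty_grid``
    by AUC on a validation set passed to :meth:`fit` as
    ``X_val``/``y_val``; without one, training-set AUC is used (the
    grid's weakest regulariser wins ties towards smaller C, i.e.
    stronger penalty).

    Attributes: ``feature_names_``, ``mean_``, ``scale_``, ``coef_``,
    ``intercept_``, ``C_``.
    """

    def __init__(self, penalty_grid=DEFAULT_PENALTY_GRID, max_iter: int = 2000):
        self.penalty_grid = penalty_grid
        self.max_iter = max_iter

    def fit(self, X, y, X_val=None, y_val=None):
        X = _as_frame(X)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data contains a single class; "
                             "cannot fit a benign/malignant classifier")
        self.classes_ = classes
        self.feature_names_ = list(X.columns)
        vals = X.to_numpy(dtype=float)
        self.mean_ = vals.mean(axis=0)
        sd = vals.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        z = (vals - self.mean_) / self.scale_

        if X_val is not None and y_val is not None:
            zv = ((_as_frame(X_val)[self.feature_names_].to_numpy(dtype=float)
                   - self.mean_) / self.scale_)
            yv = np.asarray(y_val, dtype=int)
        else:
            zv, yv = z, y

        best = None
        for c in sorted(self.penalty_grid):
            lr = LogisticRegression(l1_ratio=1.0, C=float(c),
                                    solver="liblinear", max_iter=self.max_iter)
            lr.fit(z, y)
            score = auc(lr.predict_proba(zv)[:, 1], yv) \
                if np.unique(yv).size == 2 else 0.5
            if best is None or score > best[0]:
                best = (score, c, lr)
        self.val_auc_, self.C_, lr = best
        self.coef_ = lr.coef_.copy()
        self.intercept_ = lr.intercept_.copy()
        self._lr = lr
        return self

    def _standardize(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = _as_frame(X)
        missing = [n for n in self.feature_names_ if n not in X.columns]
        if missing:
            raise ValueError(f"missing feature(s) at predict time: {missing}")
        vals = X[self.feature_names_].to_numpy(dtype=float)
        return (vals - self.mean_) / self.scale_

    def decision_function(self, X) -> np.ndarray:
        return self._standardize(X) @ self.coef_[0] + self.intercept_[0]

    def predict_proba(self, X) -> np.ndarray:
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # --- JSON round-trip ------------------------------------------------
    def to_json(self) -> str:
        check_is_fitted(self, "coef_")
        return json.dumps({
            "feature_names": self.feature_names_,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "coef": self.coef_[0].tolist(),
            "intercept": float(self.intercept_[0]),
            "C": float(self.C_),
        })

    @classmethod
    def from_json(cls, doc: str) -> "L1LogisticModel":
        d = json.loads(doc)
        model = cls()
        model.classes_ = np.array([0, 1])
        model.feature_names_ = list(d["feature_names"])
        model.mean_ = np.asarray(d["mean"], dtype=float)
        model.scale_ = np.asarray(d["scale"], dtype=float)
        model.coef_ = np.asarray([d["coef"]], dtype=float)
        model.intercept_ = np.asarray([d["intercept"]], dtype=float)
        model.C_ = d["C"]
        return model


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def correlation_filter(table: pd.DataFrame, labels, threshold: float = 0.9):
    """Names of the features surviving the pairwise-correlation filter."""
    f = CorrelationFilter(threshold=threshold).fit(table, labels)
    return f.selected_features_


def fit_l1_logistic(table: pd.DataFrame, labels, selected_names=None,
                    penalty_grid=DEFAULT_PENALTY_GRID,
                    val_table=None, val_labels=None) -> L1LogisticModel:
    if selected_names is not None:
        table = table[list(selected_names)]
        if val_table is not None:
            val_table = val_table[list(selected_names)]
    return L1LogisticModel(penalty_grid=penalty_grid).fit(
        table, labels, X_val=val_table, y_val=val_labels)


def predict(model: L1LogisticModel, features: pd.DataFrame) -> np.ndarray:
    """Malignancy probability in [0, 1] per row."""
    return model.predict_proba(features)[:, 1]
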